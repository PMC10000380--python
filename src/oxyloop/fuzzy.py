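"""Mamdani fuzzy inference for the adaptation gain m = f(e, de).

Both inputs (model-following error e and its increment de, in % SpO2 units)
live on [-100, +100]; the output m lives on [-1, +1].  Each universe carries
five equal-base-width triangular membership functions with 50% overlap,
labelled NB, NM, ZE, PM, PB, peaking at evenly spaced centers.  Inference is
classical Mamdani: min for rule antecedents, min implication, max aggregation,
centroid defuzzification.

One representational choice matters at the universe edges: the edge output
triangles (NB, PB) keep their full symmetric base, so the centroid integral
runs over [-1.5, +1.5] and a single saturated rule can drive m all the way to
+/-1 (the result is clamped to the nominal span afterwards).  Truncating the
edge triangles at the span would cap |m| at 5/6 and the controller could never
command a full-strength adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "FuzzyPartition",
    "RuleBase",
    "FuzzyGainSystem",
    "membership",
    "infer_gain",
    "control_surface",
    "load_rules",
    "default_system",
]

LABELS = ("NB", "NM", "ZE", "PM", "PB")


@dataclass(frozen=True)
class FuzzyPartition:
    """Five triangular membership functions with 50% overlap on [lo, hi]."""

    lo: float
    hi: float
    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("FuzzyPartition requires lo < hi")
        if len(self.labels) != 5:
            raise ValueError("FuzzyPartition uses exactly five labels")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, 5)

    @property
    def half_width(self) -> float:
        """Half-base of each triangle = spacing between adjacent centers."""
        return (self.hi - self.lo) / 4.0

    def membership(self, x: float) -> np.ndarray:
        """Degrees of the five labels at x (clamped to [lo, hi]).

        At most two adjacent labels are active and their degrees sum to 1.
        """
        x = min(max(float(x), self.lo), self.hi)
        h = self.half_width
        deg = 1.0 - np.abs(x - self.centers) / h
        return np.clip(deg, 0.0, 1.0)

    def triangles(self, z: np.ndarray) -> np.ndarray:
        """(5, len(z)) matrix of full (untruncated) triangle memberships."""
        h = self.half_width
        deg = 1.0 - np.abs(z[None, :] - self.centers[:, None]) / h
        return np.clip(deg, 0.0, 1.0)


def membership(x: float, p: FuzzyPartition) -> dict[str, float]:
    """Label -> degree map at x."""
    return dict(zip(p.labels, p.membership(x)))


@dataclass(frozen=True)
class RuleBase:
    """5x5 rule table: table[i, j] = output-label index for (e=labels[i], de=labels[j])."""

    table: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.table)
        if arr.shape != (5, 5):
            raise ValueError("rule base must be a 5x5 table (25 rules)")
        if arr.min() < 0 or arr.max() > 4:
            raise ValueError("rule consequents must be label indices 0..4")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=int)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RuleBase":
        df = df.set_index(df.columns[0]) if df.columns[0] in ("e", "e/de") else df
        idx = {lab: k for k, lab in enumerate(LABELS)}
        rows = []
        for e_lab in LABELS:
            rows.append(tuple(idx[str(df.loc[e_lab, d_lab])] for d_lab in LABELS))
        return cls(tuple(rows))


def load_rules(path: str | Path | None = None) -> RuleBase:
    """Read the packaged (or a user) rule-base CSV: rows = e labels, cols = de labels."""
    if path is None:
        with resources.as_file(resources.files("oxyloop.data") / "fuzzy_rules.csv") as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return RuleBase.from_frame(df)


@dataclass(frozen=True)
class FuzzyGainSystem:
    """Complete (e, de) -> m inference system.

    ``e_gain``/``de_gain`` scale the raw inputs before fuzzification (the
    universes themselves are fixed); with unit gains the system is the bare
    published surface, and a controller embedding it chooses the scaling that
    matches its loop dynamics.
    """

    e_partition: FuzzyPartition
    de_partition: FuzzyPartition
    m_partition: FuzzyPartition
    rules: RuleBase
    e_gain: float = 1.0
    de_gain: float = 1.0
    n_defuzz: int = 601  # centroid quadrature points over the extended output span

    def __post_init__(self) -> None:
        h = self.m_partition.half_width
        z = np.linspace(self.m_partition.lo - h, self.m_partition.hi + h, self.n_defuzz)
        object.__setattr__(self, "_z", z)
        object.__setattr__(self, "_tri", self.m_partition.triangles(z))
        object.__setattr__(self, "_table", self.rules.as_array())

    def infer(self, e: float, de: float) -> float:
        mu_e = self.e_partition.membership(self.e_gain * e)
        mu_de = self.de_partition.membership(self.de_gain * de)
        # firing strength per output label: max over rules mapping to it
        w = np.minimum(mu_e[:, None], mu_de[None, :])  # 5x5 antecedent strengths
        w_out = np.zeros(5)
        np.maximum.at(w_out, self._table.ravel(), w.ravel())
        if not w_out.any():  # unreachable under clamping; keep the guard honest
            warnings.warn("no fuzzy rule fired; returning m=0", RuntimeWarning)
            return 0.0
        agg = np.max(np.minimum(self._tri, w_out[:, None]), axis=0)
        total = agg.sum()
        if total == 0.0:
            warnings.warn("degenerate aggregate; returning m=0", RuntimeWarning)
            return 0.0
        m = float((self._z * agg).sum() / total)
        return min(max(m, self.m_partition.lo), self.m_partition.hi)


def default_system(
    rules: RuleBase | None = None, e_gain: float = 1.0, de_gain: float = 1.0
) -> FuzzyGainSystem:
    """The published configuration: inputs on [-100, 100], output on [-1, 1]."""
    return FuzzyGainSystem(
        e_partition=FuzzyPartition(-100.0, 100.0),
        de_partition=FuzzyPartition(-100.0, 100.0),
        m_partition=FuzzyPartition(-1.0, 1.0),
        rules=rules if rules is not None else load_rules(),
        e_gain=e_gain,
        de_gain=de_gain,
    )


def infer_gain(e: float, de: float, sys: FuzzyGainSystem) -> float:
    """Adaptation gain m in [-1, 1] for the given error pair."""
    return sys.infer(e, de)


def control_surface(sys: FuzzyGainSystem, grid_n: int = 101) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """m over a grid_n x grid_n grid of (e, de); returns (e_grid, de_grid, M)."""
    if grid_n < 3:
        raise ValueError("grid_n must be >= 3")
    e_grid = np.linspace(sys.e_partition.lo, sys.e_partition.hi, grid_n)
    de_grid = np.linspace(sys.de_partition.lo, sys.de_partition.hi, grid_n)
    M = np.empty((grid_n, grid_n))
    for i, e in enumerate(e_grid):
        for j, de in enumerate(de_grid):
            M[i, j] = sys.infer(e, de)
    return e_grid, de_grid, M
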