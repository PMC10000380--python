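"""Linear plant blocks: oxygen-cylinder lag, airway sections, cascade, margins.

Every dynamic block is a :class:`RationalTransferFunction` — a proper rational
transfer function with an optional dead time.  The dead time is kept symbolic
on the type; it is realised only inside the time-domain simulator (as an exact
sample shift) and in the frequency response (as the exact phase term
``exp(-j w d)``).  No Pade approximation is used anywhere.

The four airway sections (nasal cavity, trachea, bronchi, alveoli) are unity-DC
second-order lags ``1/(LC s^2 + RC s + 1)`` whose coefficients come from the
lumped R/L/C analogue of the morphometric model.  Respiratory distress stiffens
the alveolar walls, i.e. reduces alveolar compliance by two to three orders of
magnitude; the "infected" alveolar section carries those reduced coefficients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "RationalTransferFunction",
    "SegmentSpec",
    "Margins",
    "cylinder_tf",
    "segment_tf",
    "healthy_alveoli_tf",
    "infected_alveoli_tf",
    "airway_cascade",
    "stability_margins",
    "canonical_segments",
    "segments_from_table",
    "load_segment_table",
]

SEGMENT_LABELS = ("nasal", "trachea", "bronchi", "alveoli")


@dataclass(frozen=True)
class RationalTransferFunction:
    """Proper rational transfer function with optional transport dead time.

    ``num``/``den`` are polynomial coefficients in descending powers of s.
    """

    num: tuple[float, ...]
    den: tuple[float, ...]
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        num = tuple(float(c) for c in np.trim_zeros(np.atleast_1d(self.num), "f"))
        den = tuple(float(c) for c in np.trim_zeros(np.atleast_1d(self.den), "f"))
        if not num:
            num = (0.0,)
        if not den:
            raise ValueError("denominator must be a nonzero polynomial")
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)
        if len(num) > len(den):
            raise ValueError("transfer function must be proper (deg num <= deg den)")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")

    # -- algebra -----------------------------------------------------------
    def __mul__(self, other: "RationalTransferFunction") -> "RationalTransferFunction":
        return RationalTransferFunction(
            num=tuple(np.convolve(self.num, other.num)),
            den=tuple(np.convolve(self.den, other.den)),
            dead_time=self.dead_time + other.dead_time,
        )

    def with_dead_time(self, dead_time: float) -> "RationalTransferFunction":
        return RationalTransferFunction(self.num, self.den, dead_time)

    def delay_free(self) -> "RationalTransferFunction":
        return RationalTransferFunction(self.num, self.den, 0.0)

    # -- analysis ----------------------------------------------------------
    @property
    def order(self) -> int:
        return len(self.den) - 1

    @property
    def dc_gain(self) -> float:
        if self.den[-1] == 0:
            return math.inf
        return self.num[-1] / self.den[-1]

    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    def is_stable(self) -> bool:
        """BIBO stability of the rational part: all poles strictly in LHP."""
        return bool(np.all(np.real(self.poles()) < 0))

    def freq_response(self, w: np.ndarray) -> np.ndarray:
        """H(jw) including the exact dead-time phase factor."""
        jw = 1j * np.asarray(w, dtype=float)
        h = np.polyval(self.num, jw) / np.polyval(self.den, jw)
        if self.dead_time:
            h = h * np.exp(-jw * self.dead_time)
        return h

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "num": list(self.num),
            "den": list(self.den),
            "dead_time": self.dead_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RationalTransferFunction":
        return cls(tuple(d["num"]), tuple(d["den"]), float(d.get("dead_time", 0.0)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RationalTransferFunction":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SegmentSpec:
    """Second-order airway-section coefficients: 1/(LC s^2 + RC s + 1)."""

    label: str
    LC: float  # s^2 coefficient
    RC: float  # s coefficient

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not (self.LC > 0 and self.RC > 0):
            raise ValueError(f"segment {self.label}: LC and RC must be positive")


# Canonical section coefficients as used in the published equations.  The
# nasal s-coefficient (2.165) differs by 0.4% from the R*C product of the
# printed table factors (2.1559); the equation value is canonical here and the
# table path exists for validation.
CANONICAL_SEGMENTS: dict[str, SegmentSpec] = {
    "nasal": SegmentSpec("nasal", LC=2.7e-3, RC=2.165),
    "trachea": SegmentSpec("trachea", LC=3.7e-4, RC=5.4e-3),
    "bronchi": SegmentSpec("bronchi", LC=1.44e-5, RC=4.02e-4),
    "alveoli": SegmentSpec("alveoli", LC=6.72e-8, RC=5.71e-4),
}

# Printed coefficients of the stiffened (respiratory-distress) alveolar section.
INFECTED_ALVEOLI = (1.0e-10, 1.15e-6, 1.0)


def cylinder_tf(tau: float) -> RationalTransferFunction:
    """Oxygen-cylinder/valve lag 1/(tau s + 1); unity DC gain.

    ``tau = R*C`` of the supply-line analogue; 0.50 s is the study default.
    """
    if not tau > 0:
        raise ValueError(f"cylinder time constant tau={tau} must be > 0")
    return RationalTransferFunction((1.0,), (tau, 1.0))


def segment_tf(spec: SegmentSpec) -> RationalTransferFunction:
    """Second-order unity-DC airway section 1/(LC s^2 + RC s + 1)."""
    return RationalTransferFunction((1.0,), (spec.LC, spec.RC, 1.0))


def healthy_alveoli_tf() -> RationalTransferFunction:
    return segment_tf(CANONICAL_SEGMENTS["alveoli"])


def infected_alveoli_tf() -> RationalTransferFunction:
    """Alveolar section of a respiratory-distress patient (reduced compliance)."""
    return RationalTransferFunction((1.0,), INFECTED_ALVEOLI)


def canonical_segments() -> dict[str, SegmentSpec]:
    return dict(CANONICAL_SEGMENTS)


def airway_cascade(condition: str = "infected") -> RationalTransferFunction:
    """Series cascade nasal * trachea * bronchi * alveoli (order 8, unity DC).

    ``condition`` selects the healthy or the stiffened alveolar section; the
    three conducting sections are identical in both cases.
    """
    if condition not in ("healthy", "infected"):
        raise ValueError(f"condition must be 'healthy' or 'infected', got {condition!r}")
    tf = (
        segment_tf(CANONICAL_SEGMENTS["nasal"])
        * segment_tf(CANONICAL_SEGMENTS["trachea"])
        * segment_tf(CANONICAL_SEGMENTS["bronchi"])
    )
    alv = healthy_alveoli_tf() if condition == "healthy" else infected_alveoli_tf()
    return tf * alv


def load_segment_table(path: str | Path | None = None) -> pd.DataFrame:
    """Lumped R/L/C values of the four sections with RC/LC product columns."""
    if path is None:
        with resources.as_file(
            resources.files("oxyloop.data") / "airway_segments.csv"
        ) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def segments_from_table(df: pd.DataFrame | None = None) -> dict[str, SegmentSpec]:
    """Reconstruct SegmentSpecs from the section table's RC/LC columns
    (validation path; the bronchi LC column and the L*C product disagree by 6%
    in the source — the tabulated LC column is the one the equations use)."""
    if df is None:
        df = load_segment_table()
    out = {}
    for row in df.itertuples():
        out[row.section] = SegmentSpec(row.section, LC=row.LC, RC=row.RC)
    return out


@dataclass(frozen=True)
class Margins:
    """Bode stability margins. Missing crossovers yield infinite margins
    (and NaN crossover frequencies) with the corresponding flag set."""

    gain_margin_db: float
    phase_margin_deg: float
    w_phase_crossover: float  # rad/s where phase crosses -180 deg
    w_gain_crossover: float   # rad/s where |H| crosses 1
    no_phase_crossover: bool = False
    no_gain_crossover: bool = False


def _phase_deg(tf: RationalTransferFunction, w: np.ndarray) -> np.ndarray:
    """Unwrapped phase in degrees including the exact dead-time term."""
    jw = 1j * np.asarray(w, dtype=float)
    h = np.polyval(tf.num, jw) / np.polyval(tf.den, jw)
    ph = np.unwrap(np.angle(h))
    return np.degrees(ph) - np.degrees(w * tf.dead_time)


def stability_margins(
    tf: RationalTransferFunction,
    w_min: float = 1e-4,
    w_max: float = 1e8,
    n_grid: int = 20000,
) -> Margins:
    """Gain and phase margins from the frequency response.

    The dead time enters as the exact phase shift ``-w d``.  Crossovers are
    located on a dense log grid and refined by root bracketing; when a
    crossover does not exist the margin is infinite and flagged.
    """
    if len(tf.num) > len(tf.den):
        raise ValueError("stability margins require a proper transfer function")
    w = np.logspace(math.log10(w_min), math.log10(w_max), n_grid)
    mag = np.abs(tf.freq_response(w))
    with np.errstate(divide="ignore"):
        logmag = np.log10(np.where(mag > 0, mag, np.finfo(float).tiny))
    phase = _phase_deg(tf, w)

    def phase_at(v: float, i: int) -> float:
        """Phase at v, unwrapped along the grid up to index i for branch safety."""
        grid = np.concatenate([w[: i + 1], [v]])
        return float(_phase_deg(tf, grid)[-1])

    # --- gain crossover: |H| = 1 -> phase margin
    w_gc = math.nan
    pm = math.inf
    no_gc = True
    idx = np.nonzero(np.diff(np.sign(logmag)) != 0)[0]
    if idx.size:
        i = int(idx[0])
        f = lambda v: math.log10(abs(tf.freq_response(np.array([v]))[0]))
        w_gc = float(optimize.brentq(f, w[i], w[i + 1], xtol=1e-12, rtol=1e-14))
        pm = 180.0 + phase_at(w_gc, i)
        no_gc = False

    # --- phase crossover: phase = -180 deg -> gain margin
    w_pc = math.nan
    gm_db = math.inf
    no_pc = True
    idx = np.nonzero(np.diff(np.sign(phase + 180.0)) != 0)[0]
    if idx.size:
        i = int(idx[0])
        w_pc = float(
            optimize.brentq(
                lambda v: phase_at(v, i) + 180.0, w[i], w[i + 1], xtol=1e-12, rtol=1e-14
            )
        )
        gm_db = -20.0 * math.log10(abs(tf.freq_response(np.array([w_pc]))[0]))
        no_pc = False

    return Margins(
        gain_margin_db=gm_db,
        phase_margin_deg=pm,
        w_phase_crossover=w_pc,
        w_gain_crossover=w_gc,
        no_phase_crossover=no_pc,
        no_gain_crossover=no_gc,
    )
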