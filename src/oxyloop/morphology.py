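"""Airway morphometry and its electrical analogy.

The conducting airways are described as a Weibel-type dichotomously branching
tree: generation ``z`` contains ``2**z`` identical branches of diameter ``d``
and length ``l``; ``s`` is the *total* cross-sectional area of the generation
and ``u`` the mean flow velocity through it.  Each generation maps onto a
lumped electrical analogue:

* resistance  ``R = (8 mu l / (pi r^4)) / n``  — Poiseuille resistance of one
  branch, divided by the ``n`` parallel branches of the generation;
* inertance   ``L = rho l / s``               — gas-column inertia against the
  total generation area;
* compliance  ``C = l s / (rho n u^2)``       — kinetic-energy equivalent
  capacitance.

All three are computed in cgs units (g, cm, s, dyn) and converted to the
clinical pressure/volume units cm H2O and litres at the end, so that R carries
cm H2O/(L/s), L cm H2O/(L/s^2) and C L/cm H2O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AirProperties",
    "AirwayGeneration",
    "RLCTriple",
    "generation_resistance",
    "generation_inertance",
    "generation_compliance",
    "build_morphology_table",
    "load_generation_table",
    "rows_from_frame",
    "morphology_frame",
]

GENERATION_COLUMNS = ["z", "n", "d_cm", "l_cm", "s_cm2", "u_cm_s"]


@dataclass(frozen=True)
class AirProperties:
    """Physical properties of air and unit-conversion constants (cgs base).

    Parameters
    ----------
    mu : dynamic viscosity, g/(cm s) (poise). Default is air at ~20 C.
    rho : density, g/cm^3. Default is air at sea level, ~15 C.
    p_cmH2O : dyn/cm^2 per cm of water column.
    v_L : cm^3 per litre.
    """

    mu: float = 1.81e-4
    rho: float = 1.225e-3
    p_cmH2O: float = 980.665
    v_L: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("mu", "rho", "p_cmH2O", "v_L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AirProperties.{name} must be strictly positive")

    @property
    def r_scale(self) -> float:
        """cgs (dyn s/cm^5) -> cm H2O/(L/s); also scales inertance."""
        return self.v_L / self.p_cmH2O

    @property
    def c_scale(self) -> float:
        """cgs (cm^5/dyn) -> L/cm H2O."""
        return self.p_cmH2O / self.v_L


@dataclass(frozen=True)
class AirwayGeneration:
    """One generation of the branching airway tree."""

    z: int
    n: int
    d: float  # single-branch diameter, cm
    l: float  # branch length, cm
    s: float  # total generation cross-section, cm^2
    u: float  # mean flow velocity, cm/s

    def validate(self) -> None:
        if self.z < 0:
            raise ValueError(f"generation index z={self.z} must be >= 0")
        if self.n < 1:
            raise ValueError(f"branch count n={self.n} must be >= 1")
        for name in ("d", "l", "s", "u"):
            if not getattr(self, name) > 0:
                raise ValueError(
                    f"AirwayGeneration.{name}={getattr(self, name)} must be "
                    f"strictly positive (generation z={self.z})"
                )


@dataclass(frozen=True)
class RLCTriple:
    """Resistance / inertance / compliance of one generation."""

    R: float  # cm H2O/(L/s)
    L: float  # cm H2O/(L/s^2)
    C: float  # L/cm H2O


def generation_resistance(g: AirwayGeneration, air: AirProperties = AirProperties()) -> float:
    """Poiseuille flow resistance of a generation, cm H2O/(L/s).

    The single-branch value ``8 mu l / (pi r^4)`` is divided by the number of
    parallel branches ``n``; the tabulated per-generation resistances are the
    parallel values.
    """
    g.validate()
    r = g.d / 2.0
    single = 8.0 * air.mu * g.l / (math.pi * r**4)
    return (single / g.n) * air.r_scale


def generation_inertance(g: AirwayGeneration, air: AirProperties = AirProperties()) -> float:
    """Gas-column inertance ``rho l / s`` of a generation, cm H2O/(L/s^2).

    Uses the listed *total* cross-sectional area directly (no branch-count
    division).
    """
    g.validate()
    return (air.rho * g.l / g.s) * air.r_scale


def generation_compliance(g: AirwayGeneration, air: AirProperties = AirProperties()) -> float:
    """Compliance ``l s / (rho n u^2)`` of a generation, L/cm H2O."""
    g.validate()
    return (g.l * g.s / (air.rho * g.n * g.u**2)) * air.c_scale


def build_morphology_table(
    rows: list[AirwayGeneration], air: AirProperties = AirProperties()
) -> list[RLCTriple]:
    """Apply the three analogue formulas to every generation, order preserved."""
    if not rows:
        raise ValueError("build_morphology_table: rows must be nonempty")
    out = []
    for i, g in enumerate(rows):
        try:
            out.append(
                RLCTriple(
                    R=generation_resistance(g, air),
                    L=generation_inertance(g, air),
                    C=generation_compliance(g, air),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


def load_generation_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a generation-geometry CSV (packaged 24-generation table by default).

    The packaged table also carries ``R_printed/L_printed/C_printed`` columns
    with the source's own tabulated analogue values for validation.
    """
    if path is None:
        with resources.as_file(
            resources.files("oxyloop.data") / "airway_generations.csv"
        ) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in GENERATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"generation table is missing columns {missing}")
    return df


def rows_from_frame(df: pd.DataFrame) -> list[AirwayGeneration]:
    return [
        AirwayGeneration(
            z=int(row.z), n=int(row.n), d=float(row.d_cm), l=float(row.l_cm),
            s=float(row.s_cm2), u=float(row.u_cm_s),
        )
        for row in df.itertuples()
    ]


def morphology_frame(
    df: pd.DataFrame, air: AirProperties = AirProperties()
) -> pd.DataFrame:
    """Return a copy of ``df`` with computed ``R``, ``L``, ``C`` columns."""
    triples = build_morphology_table(rows_from_frame(df), air)
    out = df.copy()
    out["R"] = [t.R for t in triples]
    out["L"] = [t.L for t in triples]
    out["C"] = [t.C for t in triples]
    return out
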