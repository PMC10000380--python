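"""Three-compartment oxygen exchange: alveolar air / lung tissue / capillary blood.

Oxygen moves down partial-pressure gradients across two barriers (air/tissue,
tissue/blood).  With the flow of oxygen treated as an electrical current, each
compartment is a capacitor and each barrier a resistor, giving three coupled
first-order balance equations with reciprocal time constants

    k_AA = 1/(R_A C_A),  k_AT = 1/(R_A C_T),
    k_TT = 1/(R_T C_T),  k_BB = 1/(R_B C_B).

The canonical published values are (0.2429, 4.76, 15.87, 88.88) 1/s.  The
published rational model of the blood-side response,

    TF_BO2(s) = (20 s^2 + 200 s + 62) / (s^3 + 110 s^2 + 350 s + 67),

is taken verbatim as the canonical gas-exchange block for all simulations: its
denominator has a nonzero constant term, which the *autonomous* exchange
equations cannot produce (their coupling matrix is singular — pure exchange
conserves the equilibrium).  The ODE path therefore carries an explicit
input-coupling gain ``k_in`` (fresh-gas ventilation drive) and is provided for
time-domain experiments; it is not the block used in the closed-loop study.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .plant import RationalTransferFunction

__all__ = [
    "GasExchangeParams",
    "GasExchangeRates",
    "GasExchangeState",
    "CANONICAL_RATES",
    "gas_exchange_derivatives",
    "coupling_matrix",
    "derive_rate_constants",
    "gas_exchange_tf",
    "gas_exchange_variant",
    "GAS_MODEL_VARIANTS",
    "patient_model",
    "load_gas_params",
]


@dataclass(frozen=True)
class GasExchangeParams:
    """Compartment volumes (L), solubilities (M/mm) and diffusion rates (L/s)."""

    V_A: float = 1.9e-7
    V_T: float = 4.2e-8
    V_B: float = 7.5e-9
    sigma_A: float = 2.5e-5
    sigma_T: float = 1.2e-6
    sigma_B: float = 1.2e-6
    D_TA: float = 2.4e-12
    D_TB: float = 8.0e-12  # printed as a range (6.7-10)e-12; mid-range default

    D_TB_RANGE = (6.7e-12, 1.0e-11)

    def __post_init__(self) -> None:
        for name in ("V_A", "V_T", "V_B", "sigma_A", "sigma_T", "sigma_B", "D_TA", "D_TB"):
            if not getattr(self, name) > 0:
                raise ValueError(f"GasExchangeParams.{name} must be strictly positive")
        lo, hi = self.D_TB_RANGE
        if not (lo <= self.D_TB <= hi):
            raise ValueError(
                f"D_TB={self.D_TB} outside the physiological range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class GasExchangeRates:
    """Reciprocal time constants of the exchange network, 1/s."""

    k_AA: float
    k_AT: float
    k_TT: float
    k_BB: float

    def __post_init__(self) -> None:
        for name in ("k_AA", "k_AT", "k_TT", "k_BB"):
            if not getattr(self, name) > 0:
                raise ValueError(f"GasExchangeRates.{name} must be strictly positive")


#: Canonical published reciprocal time constants.
CANONICAL_RATES = GasExchangeRates(k_AA=0.2429, k_AT=4.76, k_TT=15.87, k_BB=88.88)


@dataclass(frozen=True)
class GasExchangeState:
    """Oxygen potentials (partial-pressure analogues, % of supply scale)."""

    v_AA: float  # alveolar air
    v_LT: float  # lung tissue
    v_CB: float  # capillary blood

    def as_array(self) -> np.ndarray:
        return np.array([self.v_AA, self.v_LT, self.v_CB])


def coupling_matrix(rates: GasExchangeRates = CANONICAL_RATES) -> np.ndarray:
    """Autonomous 3x3 exchange matrix A with d(state)/dt = A @ state (k_in=0).

    Rows sum to zero — pure exchange preserves a uniform potential — so A is
    singular and its characteristic polynomial has zero constant term.  The
    negative trace is k_AA + k_AT + k_TT + k_BB.
    """
    return np.array(
        [
            [-rates.k_AA, rates.k_AA, 0.0],
            [rates.k_AT, -(rates.k_AT + rates.k_TT), rates.k_TT],
            [0.0, rates.k_BB, -rates.k_BB],
        ]
    )


def gas_exchange_derivatives(
    state: GasExchangeState,
    rates: GasExchangeRates = CANONICAL_RATES,
    v_in: float = 0.0,
    k_in: float | None = None,
) -> GasExchangeState:
    """Time derivative of the compartment potentials.

    ``v_in`` is the driving (supply-side) potential and ``k_in`` its coupling
    gain into the alveolar compartment; ``k_in=None`` defaults to ``k_AA``.
    With ``k_in=0`` the system is the autonomous exchange network.
    """
    if k_in is None:
        k_in = rates.k_AA
    dv_AA = rates.k_AA * (state.v_LT - state.v_AA) + k_in * (v_in - state.v_AA)
    dv_LT = rates.k_TT * (state.v_CB - state.v_LT) + rates.k_AT * (state.v_AA - state.v_LT)
    dv_CB = rates.k_BB * (state.v_LT - state.v_CB)
    return GasExchangeState(dv_AA, dv_LT, dv_CB)


def derive_rate_constants(
    p: GasExchangeParams, scale: float = 1.0
) -> GasExchangeRates:
    """Rate constants from the physical parameters: k = scale * D / (sigma V).

    The published rates are not reproducible from the parameter table under a
    single convention; ``scale`` exposes the unit ambiguity explicitly.  With
    ``scale=0.1`` and the mid-range D_TB the tissue and blood rates (15.87,
    88.89) match the canonical values; the alveolar pair does not fit the same
    convention and the canonical values stay authoritative.
    """
    if not scale > 0:
        raise ValueError("scale must be strictly positive")
    return GasExchangeRates(
        k_AA=scale * p.D_TA / (p.sigma_A * p.V_A),
        k_AT=scale * p.D_TA / (p.sigma_T * p.V_T),
        k_TT=scale * p.D_TB / (p.sigma_T * p.V_T),
        k_BB=scale * p.D_TB / (p.sigma_B * p.V_B),
    )


def gas_exchange_tf() -> RationalTransferFunction:
    """Canonical blood-oxygen response TF_BO2 (verbatim published coefficients)."""
    return RationalTransferFunction((20.0, 200.0, 62.0), (1.0, 110.0, 350.0, 67.0))


#: Published parameter-variation studies of the gas-exchange numerator/constant.
GAS_MODEL_VARIANTS: dict[str, RationalTransferFunction] = {
    "canonical": gas_exchange_tf(),
    "model1": RationalTransferFunction((10.0, 300.0, 62.0), (1.0, 110.0, 350.0, 67.0)),
    "model2": RationalTransferFunction((20.0, 400.0, 62.0), (1.0, 110.0, 350.0, 67.0)),
    "model3": RationalTransferFunction((20.0, 400.0, 52.0), (1.0, 110.0, 350.0, 67.0)),
}


def gas_exchange_variant(name: str = "canonical") -> RationalTransferFunction:
    try:
        return GAS_MODEL_VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown gas model variant {name!r}; choose from {sorted(GAS_MODEL_VARIANTS)}"
        ) from None


def patient_model(
    airway: RationalTransferFunction,
    gas: RationalTransferFunction | None = None,
    intermediate_delay: float = 0.0,
) -> RationalTransferFunction:
    """Full patient model TP_M = airway cascade x gas exchange, with the
    gas-transport dead time carried on the composite."""
    if intermediate_delay < 0:
        raise ValueError("intermediate_delay must be >= 0")
    if gas is None:
        gas = gas_exchange_tf()
    composite = airway * gas
    return composite.with_dead_time(composite.dead_time + intermediate_delay)


def load_gas_params(path: str | Path | None = None) -> GasExchangeParams:
    """Load compartment parameters from YAML (packaged defaults when path=None)."""
    if path is None:
        with resources.as_file(
            resources.files("oxyloop.data") / "gas_exchange_params.yaml"
        ) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    block = raw.get("gas_exchange", raw)
    block = {k: v for k, v in block.items() if k != "D_TB_range"}
    known = {"V_A", "V_T", "V_B", "sigma_A", "sigma_T", "sigma_B", "D_TA", "D_TB"}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown gas_exchange keys: {sorted(unknown)}")
    return GasExchangeParams(**{k: float(v) for k, v in block.items()})
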