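"""Physical parameters of the two diffusion regions and the tissue reaction kinetics.

The tissue obeys a reaction-diffusion balance for oxygen partial pressure
P (mmHg),

    dP/dt = D * lap(P) + K * (1 - P/P0) - (M0/k) * P / (P + P50),

where the source term ``K*(1 - P/P0)`` models homogeneous capillary supply at
average capillary PO2 ``P0`` and the Michaelis-Menten term models saturable
mitochondrial consumption. The gas-permeable PDMS membrane carries no sources
or sinks and differs from tissue in both diffusivity and solubility.

All quantities are held internally in micrometres, seconds and mmHg;
literature diffusivities quoted in cm^2/s are converted once on construction
(1 cm^2/s = 1e8 um^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import brentq

#: conversion factor for diffusivities quoted in cm^2/s
CM2_PER_S_TO_UM2_PER_S = 1.0e8


def _check_positive(obj, allow_zero: tuple[str, ...] = ()) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if f.name in allow_zero:
            if v < 0:
                raise ValueError(f"{type(obj).__name__}.{f.name} must be >= 0, got {v}")
        elif not v > 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class TissueParams:
    """Skeletal-muscle oxygen transport constants.

    Defaults are the standard literature values for resting rat skeletal
    muscle used throughout this package.

    Attributes
    ----------
    D : float
        Oxygen diffusivity in tissue, um^2/s (default 2.41e-5 cm^2/s).
    k : float
        Oxygen solubility in tissue, mL O2 / mL / mmHg.
    M0 : float
        Maximal volumetric oxygen consumption, mL O2 / mL / s.
    P50 : float
        PO2 at which consumption is half-maximal, mmHg.
    P0 : float
        Average capillary PO2, mmHg.
    K : float
        Capillary-to-tissue oxygen transport rate, mmHg/s.
    """

    D: float = 2.41e-5 * CM2_PER_S_TO_UM2_PER_S
    k: float = 3.89e-5
    M0: float = 1.57e-4
    P50: float = 0.5
    P0: float = 48.0
    K: float = 30.0

    def __post_init__(self) -> None:
        _check_positive(self)

    @classmethod
    def from_cgs(cls, D_cm2_s: float = 2.41e-5, **kwargs) -> "TissueParams":
        """Construct with the diffusivity given in cm^2/s (literature units)."""
        return cls(D=D_cm2_s * CM2_PER_S_TO_UM2_PER_S, **kwargs)

    @property
    def consumption_rate(self) -> float:
        """M0/k, the maximal consumption expressed in mmHg/s (~4.04 for defaults)."""
        return self.M0 / self.k


@dataclass(frozen=True)
class MembraneParams:
    """PDMS membrane constants.

    PDMS has a higher oxygen diffusivity than tissue and roughly a third of
    its solubility; the product D'*k' (permeability) still exceeds many
    tissue pathways, which is what lets the gas challenge spread laterally
    inside the membrane.

    Attributes
    ----------
    D_prime : float
        Oxygen diffusivity in PDMS, um^2/s (default 3.40e-5 cm^2/s).
    k_prime : float
        Oxygen solubility in PDMS, mL O2 / mL / mmHg.
    thickness : float
        Membrane height, um (spin-coated sheets are ~25 um).
    """

    D_prime: float = 3.40e-5 * CM2_PER_S_TO_UM2_PER_S
    k_prime: float = 1.32e-5
    thickness: float = 25.0

    def __post_init__(self) -> None:
        _check_positive(self)

    @classmethod
    def from_cgs(cls, D_cm2_s: float = 3.40e-5, **kwargs) -> "MembraneParams":
        return cls(D_prime=D_cm2_s * CM2_PER_S_TO_UM2_PER_S, **kwargs)


def reaction_rate(P, params: TissueParams = TissueParams()):
    """Net rate of PO2 change from capillary supply minus consumption, mmHg/s.

    ``K*(1 - P/P0) - (M0/k) * P/(P + P50)``, valid in the tissue region only
    (the membrane carries no reaction). Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any P is negative — a negative partial pressure signals solver
        instability and is never clamped silently.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("negative PO2 passed to reaction_rate (solver instability?)")
    out = params.K * (1.0 - P / params.P0) - params.consumption_rate * P / (P + params.P50)
    return out if out.ndim else float(out)


def equilibrium_po2(params: TissueParams = TissueParams()) -> float:
    """PO2 at which capillary supply exactly balances consumption, mmHg.

    The root is unique because supply is strictly decreasing and consumption
    strictly increasing in P. For the default parameters it sits near
    41.6 mmHg — the far-field tissue PO2 any unperturbed region relaxes to.
    """
    lo, hi = 0.0, params.P0
    # supply-only rate at P0 is zero minus consumption, so rate(P0) < 0; rate(0) = K > 0
    return float(brentq(lambda p: reaction_rate(p, params), lo, hi, xtol=1e-12, rtol=1e-15))
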