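"""Five-state FKBP-occupancy scheme for RyR2 and the occupancy-dependent gating law.

The cardiac ryanodine receptor (RyR2) is modelled as a single gating unit whose
opening rate depends on which FK-binding protein, if any, occupies its
(effective single) FKBP site.  The occupancy scheme has five states::

                 k1*[FKBP12]          k2
        Free  <------------>  12  <------->  12*
                 k_m1                k_m2

                 k3*[FKBP12.6]       k4
        Free  <------------>  12.6 <------>  12.6*
                 k_m3                k_m4

``12*`` and ``12.6*`` are the tightly-bound, conformationally altered states
that raise the channel's Ca2+ sensitivity; their summed probability is the
open-driving fraction ``nu``.  FKBP12 acts as a high-affinity partial agonist
(k2/k_m2 = 1/6 at default rates), FKBP12.6 as a high-affinity competitor of
near-zero efficacy (k4/k_m4 = 0.004).

Gating itself is a two-state closed/open chain C <-> O with closing rate
``kC`` and an opening rate ``k_O`` chosen so that the equilibrium open
probability equals ``alpha + nu``, where ``alpha`` is the spontaneous
background activity observed with no FKBP bound::

    k_O = kC * (alpha + nu) / (1 - (alpha + nu))          (rational law, default)

A linear alternative ``k_O = kC * (alpha + nu)`` (equilibrium Po =
(alpha+nu)/(1+alpha+nu)) is selectable for sensitivity checks.

All concentrations are in micromolar internally, matching the rate units.
The equilibrium occupancy distribution is computed in closed form from the
mass-action ratios; binding is collapsed to one effective site per channel
(tetramer stoichiometry is deliberately not resolved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from typing import Literal, Union

import numpy as np
import yaml

__all__ = [
    "DomainError",
    "KineticParameters",
    "LigandConcentrations",
    "OccupancyDistribution",
    "GatingRates",
    "GatingLaw",
    "equilibrium_occupancy",
    "opening_rate",
    "equilibrium_po",
    "equilibrium_table",
    "to_micromolar",
]

GatingLaw = Literal["rational", "linear"]

#: Concentration unit conversion factors to micromolar.
_UNIT_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "nM": 1e-3, "pM": 1e-6, "fM": 1e-9}


class DomainError(ValueError):
    """Raised when inputs leave the model's physical domain."""


def to_micromolar(value: float, unit: str = "uM") -> float:
    """Convert a concentration from *unit* (M, mM, uM, nM, pM, fM) to micromolar."""
    try:
        return float(value) * _UNIT_TO_UM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the RyR2/FKBP gating model.

    Association rates ``k1`` (FKBP12) and ``k3`` (FKBP12.6) are in per-uM
    per-s; all other rates in per-s.  ``alpha`` is the dimensionless
    spontaneous background activity (equilibrium Po with no FKBP bound).
    """

    k1: float
    k_m1: float
    k2: float
    k_m2: float
    k3: float
    k_m3: float
    k4: float
    k_m4: float
    kC: float
    alpha: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise DomainError(f"parameter {f.name} must be finite, got {v!r}")
            if f.name != "alpha" and v <= 0:
                raise DomainError(f"rate {f.name} must be strictly positive, got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "KineticParameters":
        """The packaged default calibration (see ``data/default_rates.yaml``)."""
        text = resources.files("ryrgate.data").joinpath("default_rates.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "KineticParameters":
        d = self.to_dict()
        d.update(kw)
        return KineticParameters.from_dict(d)


@dataclass(frozen=True)
class LigandConcentrations:
    """Free cytosolic FKBP concentrations, in micromolar."""

    fkbp12: float = 0.0
    fkbp12_6: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fkbp12", "fkbp12_6"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or v < 0:
                raise DomainError(f"{name} must be a finite non-negative concentration, got {v!r}")


@dataclass(frozen=True)
class OccupancyDistribution:
    """Stationary probabilities over the five FKBP-occupancy states.

    ``nu`` — the open-driving fraction — is the summed probability of the two
    activated-conformation states, ``x_12s + x_126s``.
    """

    x_free: float
    x_12: float
    x_12s: float
    x_126: float
    x_126s: float

    def __post_init__(self) -> None:
        a = self.as_array()
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise DomainError("occupancy probabilities must lie in [0, 1]")
        if abs(a.sum() - 1.0) > 1e-9:
            raise DomainError(f"occupancy probabilities must sum to 1, got {a.sum()}")

    @property
    def nu(self) -> float:
        return self.x_12s + self.x_126s

    def as_array(self) -> np.ndarray:
        """Probabilities in state order (Free, 12, 12*, 12.6, 12.6*)."""
        return np.array([self.x_free, self.x_12, self.x_12s, self.x_126, self.x_126s])


@dataclass(frozen=True)
class GatingRates:
    """Opening/closing rates of the C<->O chain and its equilibrium Po."""

    k_O: float
    k_C: float
    po_eq: float

    def __post_init__(self) -> None:
        if self.k_O < 0 or self.k_C <= 0:
            raise DomainError("gating rates must be non-negative (k_C strictly positive)")
        if not 0.0 <= self.po_eq < 1.0:
            raise DomainError(f"po_eq must lie in [0, 1), got {self.po_eq}")


def equilibrium_occupancy(
    params: KineticParameters, conc: LigandConcentrations
) -> OccupancyDistribution:
    """Closed-form stationary distribution of the occupancy scheme.

    Because the scheme is a tree, the stationary distribution satisfies
    detailed balance edge by edge and follows directly from the mass-action
    ratios: with ``c12 = [FKBP12] k1/k_m1``, ``r12 = k2/k_m2``,
    ``c126 = [FKBP12.6] k3/k_m3`` and ``r126 = k4/k_m4``::

        x_free = 1 / (1 + c12 (1 + r12) + c126 (1 + r126))
        x_12   = c12 x_free          x_12s  = c12 r12 x_free
        x_126  = c126 x_free         x_126s = c126 r126 x_free
    """
    if not isinstance(conc, LigandConcentrations):
        conc = LigandConcentrations(*conc)
    c12 = conc.fkbp12 * params.k1 / params.k_m1
    r12 = params.k2 / params.k_m2
    c126 = conc.fkbp12_6 * params.k3 / params.k_m3
    r126 = params.k4 / params.k_m4
    x_free = 1.0 / (1.0 + c12 * (1.0 + r12) + c126 * (1.0 + r126))
    return OccupancyDistribution(
        x_free=x_free,
        x_12=c12 * x_free,
        x_12s=c12 * r12 * x_free,
        x_126=c126 * x_free,
        x_126s=c126 * r126 * x_free,
    )


def _po_from_nu(params: KineticParameters, nu: float, law: GatingLaw) -> float:
    p = params.alpha + nu
    if law == "rational":
        if p >= 1.0:
            raise DomainError("occupancy-driven Po saturation exceeded (alpha + nu >= 1)")
        return p
    if law == "linear":
        return p / (1.0 + p)
    raise ValueError(f"unknown gating law {law!r}")


def opening_rate(
    params: KineticParameters,
    occ: Union[OccupancyDistribution, float],
    law: GatingLaw = "rational",
) -> GatingRates:
    """Opening rate of the C<->O chain for a given occupancy (or bare ``nu``).

    Under the default rational law ``k_O = kC (alpha+nu) / (1 - (alpha+nu))``,
    so the equilibrium Po of the chain is exactly ``alpha + nu``.  Under the
    linear alternative ``k_O = kC (alpha+nu)`` and Po is
    ``(alpha+nu)/(1+alpha+nu)``.
    """
    nu = occ.nu if isinstance(occ, OccupancyDistribution) else float(occ)
    if not 0.0 <= nu <= 1.0:
        raise DomainError(f"nu must lie in [0, 1], got {nu}")
    po = _po_from_nu(params, nu, law)
    if law == "rational":
        k_o = params.kC * po / (1.0 - po)
    else:
        k_o = params.kC * (params.alpha + nu)
    return GatingRates(k_O=k_o, k_C=params.kC, po_eq=po)


def equilibrium_po(
    params: KineticParameters,
    conc: LigandConcentrations,
    law: GatingLaw = "rational",
) -> float:
    """Analytic steady-state open probability at fixed ligand concentrations."""
    return opening_rate(params, equilibrium_occupancy(params, conc), law).po_eq


def equilibrium_table(params, conc_list, law: GatingLaw = "rational"):
    """Equilibrium occupancy/Po over a list of concentration pairs, as a DataFrame.

    Columns follow the export convention: fkbp12_uM, fkbp12_6_uM, x_free, x_12,
    x_12s, x_126, x_126s, nu, k_O, po.
    """
    import pandas as pd

    rows = []
    for conc in conc_list:
        if not isinstance(conc, LigandConcentrations):
            conc = LigandConcentrations(*conc)
        occ = equilibrium_occupancy(params, conc)
        gr = opening_rate(params, occ, law)
        rows.append(
            {
                "fkbp12_uM": conc.fkbp12,
                "fkbp12_6_uM": conc.fkbp12_6,
                "x_free": occ.x_free,
                "x_12": occ.x_12,
                "x_12s": occ.x_12s,
                "x_126": occ.x_126,
                "x_126s": occ.x_126s,
                "nu": occ.nu,
                "k_O": gr.k_O,
                "po": gr.po_eq,
            }
        )
    return pd.DataFrame(rows)
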