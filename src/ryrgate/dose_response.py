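"""Concentration-response curves, Hill/EC50 estimation, and ligand competition.

The model predicts a sigmoidal rise of steady-state Po with [FKBP12] from the
background ``alpha`` toward ``alpha + k2/(k2+k_m2)``, with a sub-picomolar
half-rise, and a monotone fall of Po with [FKBP12.6] at fixed [FKBP12]
(competitive displacement of the higher-efficacy ligand).  Curves can be
computed analytically (closed-form equilibrium) or by trial-averaged Monte
Carlo simulation of single channels; EC50 is estimated by a four-parameter
log-logistic (Hill) fit on log10 concentration, with the half-maximum defined
on the fitted span (ceiling - floor), i.e. on the Po increase above its floor.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import curve_fit

from .kinetic_model import (
    GatingLaw,
    KineticParameters,
    LigandConcentrations,
    equilibrium_po,
)
from .stochastic_sim import ConcentrationProtocol, trial_average_po

__all__ = [
    "DoseResponseCurve",
    "Ec50Fit",
    "Ec50FitError",
    "dose_response_curve",
    "competition_curve",
    "estimate_ec50",
    "ec50_closed_form",
]

_LIGANDS = ("fkbp12", "fkbp12_6")


class Ec50FitError(RuntimeError):
    """Raised when a concentration-response curve cannot support a Hill fit."""


@dataclass
class DoseResponseCurve:
    """Steady-state Po versus the concentration of one varied ligand (uM)."""

    concentrations: np.ndarray
    po_mean: np.ndarray
    po_se: np.ndarray
    mode: str
    ligand: str = "fkbp12"
    fixed_other: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.po_mean = np.asarray(self.po_mean, dtype=float)
        self.po_se = np.asarray(self.po_se, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        if np.any((self.po_mean < 0) | (self.po_mean > 1)):
            raise ValueError("po values must lie in [0, 1]")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                f"{self.ligand}_uM": self.concentrations,
                "po": self.po_mean,
                "po_se": self.po_se if len(self.po_se) else np.nan,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class Ec50Fit:
    """Four-parameter log-logistic fit: po = floor + span/(1 + (ec50/c)^hill)."""

    ec50: float          # uM
    hill: float
    floor: float
    ceiling: float
    rss: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.floor > self.ceiling:
            raise ValueError("floor must not exceed ceiling")

    @property
    def ec50_pM(self) -> float:
        return self.ec50 * 1e6

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (1.0 + (self.ec50 / conc) ** self.hill)

    def to_dict(self) -> dict:
        return {
            "ec50_uM": self.ec50,
            "ec50_pM": self.ec50_pM,
            "hill": self.hill,
            "floor": self.floor,
            "ceiling": self.ceiling,
            "rss": self.rss,
        }


def _conc_pair(ligand: str, varied: float, fixed_other: float) -> LigandConcentrations:
    if ligand == "fkbp12":
        return LigandConcentrations(fkbp12=varied, fkbp12_6=fixed_other)
    return LigandConcentrations(fkbp12=fixed_other, fkbp12_6=varied)


def dose_response_curve(
    params: KineticParameters,
    ligand: str,
    grid: np.ndarray,
    fixed_other_conc: float = 0.0,
    mode: str = "analytic",
    n_trials: int = 100,
    duration: float = 600.0,
    window: float = 10.0,
    seed=None,
    law: GatingLaw = "rational",
) -> DoseResponseCurve:
    """Steady-state Po over a concentration grid (uM) of one ligand.

    ``mode="analytic"`` evaluates the closed-form equilibrium; ``"monte_carlo"``
    trial-averages seeded single-channel simulations started from the
    stationary state (binding at sub-picomolar concentrations equilibrates far
    too slowly to reach steady state within any feasible trial).
    """
    if ligand not in _LIGANDS:
        raise ValueError(f"unknown ligand {ligand!r} (expected one of {_LIGANDS})")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be non-empty")

    po_mean, po_se = [], []
    if mode == "analytic":
        for c in grid:
            po_mean.append(equilibrium_po(params, _conc_pair(ligand, c, fixed_other_conc), law))
        po_se = np.array([])
    elif mode == "monte_carlo":
        from .stochastic_sim import child_seeds

        seeds = child_seeds(seed, grid.size)
        for c, ss in zip(grid, seeds):
            protocol = ConcentrationProtocol.constant(_conc_pair(ligand, c, fixed_other_conc))
            ts = trial_average_po(
                params, protocol, duration, n_trials, window, ss, law=law, init="equilibrium"
            )
            po_mean.append(ts.steady_state_po(harvest_fraction=1.0))
            po_se.append(ts.steady_state_sem(harvest_fraction=1.0) if n_trials > 1 else np.nan)
        po_se = np.asarray(po_se)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return DoseResponseCurve(
        concentrations=grid,
        po_mean=np.asarray(po_mean),
        po_se=po_se,
        mode=mode,
        ligand=ligand,
        fixed_other=fixed_other_conc,
    )


def competition_curve(
    params: KineticParameters,
    fkbp12_fixed: float,
    fkbp12_6_grid: np.ndarray,
    mode: str = "analytic",
    **kwargs,
) -> DoseResponseCurve:
    """Equilibrium Po versus [FKBP12.6] at a fixed [FKBP12] (both uM)."""
    if fkbp12_fixed < 0:
        raise ValueError("fkbp12_fixed must be non-negative")
    return dose_response_curve(
        params, "fkbp12_6", fkbp12_6_grid, fixed_other_conc=fkbp12_fixed, mode=mode, **kwargs
    )


def ec50_closed_form(params: KineticParameters, ligand: str = "fkbp12") -> float:
    """Exact half-rise concentration (uM) of the equilibrium binding curve.

    With the other ligand absent, nu(c) is hyperbolic in c and reaches half of
    its saturating value at ``(k_off/k_on) / (1 + k_act/k_deact)`` — the bare
    dissociation constant sharpened by the conformational equilibrium.
    """
    if ligand == "fkbp12":
        return (params.k_m1 / params.k1) / (1.0 + params.k2 / params.k_m2)
    if ligand == "fkbp12_6":
        return (params.k_m3 / params.k3) / (1.0 + params.k4 / params.k_m4)
    raise ValueError(f"unknown ligand {ligand!r}")


def estimate_ec50(curve: DoseResponseCurve, min_span: float = 1e-3) -> Ec50Fit:
    """Fit a four-parameter Hill curve on log-concentration and locate EC50.

    Zero-concentration points cannot enter a log-concentration fit and are
    excluded (the floor parameter absorbs the baseline).  A flat or non-sigmoid
    curve raises :class:`Ec50FitError` rather than extrapolating silently.
    """
    mask = curve.concentrations > 0
    c = curve.concentrations[mask]
    po = curve.po_mean[mask]
    if c.size < 4:
        raise Ec50FitError("need at least 4 positive-concentration points for a 4-parameter fit")
    span = float(po.max() - po.min())
    if span < min_span:
        raise Ec50FitError(f"curve is flat (span {span:.2e} < {min_span}); no EC50 is defined")
    if np.log10(c.max() / c.min()) < 1.0:
        raise Ec50FitError("grid must span at least one decade of concentration")

    logc = np.log10(c)

    def model(lc, floor, span_, log_ec50, hill):
        return floor + span_ / (1.0 + 10.0 ** (hill * (log_ec50 - lc)))

    # initial guess: half-rise grid point, unit Hill slope
    half = po.min() + span / 2.0
    i0 = int(np.argmin(np.abs(po - half)))
    p0 = [max(po.min(), 0.0), span, logc[i0], 1.0]
    bounds = (
        [0.0, min_span / 10.0, logc.min() - 3.0, 0.05],
        [1.0, 1.0, logc.max() + 3.0, 20.0],
    )
    try:
        popt, _ = curve_fit(model, logc, po, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise Ec50FitError(f"Hill fit did not converge: {exc}") from exc

    floor, span_, log_ec50, hill = popt
    resid = po - model(logc, *popt)
    fit = Ec50Fit(
        ec50=10.0 ** log_ec50,
        hill=float(hill),
        floor=float(floor),
        ceiling=float(floor + span_),
        rss=float(np.sum(resid**2)),
    )
    # sanity: the half-rise must be bracketed by the grid (no silent extrapolation)
    if not (c.min() / 10.0 <= fit.ec50 <= c.max() * 10.0):
        raise Ec50FitError(
            f"fitted EC50 ({fit.ec50:.3g} uM) falls far outside the measured grid"
        )
    return fit
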