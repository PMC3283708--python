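"""Single-channel analysis: idealization, open probability, dwell-time fitting.

Implements the standard analysis chain for two-level single-channel records:

* **50 % threshold idealization** — the record is segmented into open/closed
  events wherever the current crosses the midpoint between the closed and
  open levels (levels taken from acquisition metadata, supplied explicitly,
  or estimated from a two-component Gaussian fit of the amplitude histogram).
* **Open probability** — open time over total time, for the whole record
  (conventionally requiring >= 3 min of recording) or in fixed windows
  (10 s windows resolve modal gating).
* **Dwell-time extraction** — sojourn durations per conductance class, with
  events shorter than a resolution limit (1 ms by default, matching the
  recording bandwidth) excluded from lifetime analysis.
* **Maximum-likelihood exponential-mixture fitting** — dwell distributions
  are mixtures of exponentials whose component count bounds the number of
  underlying kinetic states; components are fitted by direct maximisation of
  the truncation-corrected log-likelihood (each component density
  renormalised over [cutoff, inf), which is required for unbiased time
  constants when short events are excluded), with multi-start optimisation in
  (log tau, logit area) coordinates.  Component count is selected by a
  sequential likelihood-ratio test (chi-square, 2 df per added component), or
  by BIC.

Out of scope: burst analysis, exact missed-event corrections, amplitude and
subconductance analysis, multi-channel records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .stochastic_sim import PoTimeSeries
from .trace_synthesis import CurrentTrace

__all__ = [
    "IdealizedRecord",
    "DwellFit",
    "DwellFitError",
    "LevelEstimationError",
    "ShortRecordWarning",
    "idealize_threshold50",
    "compute_po",
    "extract_dwells",
    "fit_dwell_pdf_mle",
    "select_n_components",
    "goodness_of_fit_chi2",
]

OPEN, CLOSED = 1, 0


class LevelEstimationError(RuntimeError):
    """Raised when open/closed current levels cannot be resolved."""


class DwellFitError(RuntimeError):
    """Raised when the mixture likelihood cannot be maximised."""


class ShortRecordWarning(UserWarning):
    """Whole-record Po computed from less than the conventional 3 minutes."""


@dataclass
class IdealizedRecord:
    """Alternating open/closed event list from threshold idealization."""

    states: np.ndarray      # 1 = open, 0 = closed, alternating
    durations: np.ndarray   # seconds, strictly positive
    threshold: float        # pA
    total_duration: float   # seconds

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.states) != len(self.durations):
            raise ValueError("states and durations must have equal length")
        if len(self.states) == 0:
            raise ValueError("record must contain at least one event")
        if np.any(self.durations <= 0):
            raise ValueError("event durations must be strictly positive")
        if np.any(np.diff(self.states) == 0):
            raise ValueError("events must alternate between open and closed")
        if abs(self.durations.sum() - self.total_duration) > 1e-6 * max(1.0, self.total_duration):
            raise ValueError("event durations must sum to the total duration")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"state": np.where(self.states == OPEN, "O", "C"), "duration_s": self.durations}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, threshold: float = float("nan")) -> "IdealizedRecord":
        import pandas as pd

        df = pd.read_csv(path)
        states = (df["state"].to_numpy() == "O").astype(np.int8)
        durations = df["duration_s"].to_numpy(dtype=float)
        return cls(states=states, durations=durations, threshold=threshold,
                   total_duration=float(durations.sum()))


def _estimate_levels(samples: np.ndarray, max_points: int = 50_000, seed: int = 0):
    """Two-component Gaussian amplitude-histogram fit; returns (closed, open) levels."""
    from sklearn.mixture import GaussianMixture

    x = samples
    if len(x) > max_points:
        idx = np.random.default_rng(seed).choice(len(x), max_points, replace=False)
        x = x[idx]
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed, reg_covar=1e-8)
    gm.fit(x.reshape(-1, 1))
    mu = np.sort(gm.means_.ravel())
    sd = np.sqrt(gm.covariances_.ravel()).max()
    if mu[1] - mu[0] < 3.0 * sd:
        raise LevelEstimationError(
            "amplitude histogram is effectively unimodal; open/closed levels "
            "cannot be resolved — supply levels explicitly"
        )
    return float(mu[0]), float(mu[1])


def idealize_threshold50(
    trace: CurrentTrace,
    levels: Optional[Tuple[float, float]] = None,
    estimate_levels: bool = False,
) -> IdealizedRecord:
    """Idealize a record by 50 % threshold crossing.

    The threshold is the midpoint of the closed and open current levels.
    Levels are taken from ``levels`` if given, estimated from the amplitude
    histogram if ``estimate_levels`` is set, and otherwise read from the
    trace's acquisition metadata.  Durations are multiples of the sampling
    interval (crossings are resolved to the nearest sample).
    """
    fs = trace.spec.sample_rate
    if levels is not None:
        lo, hi = sorted(levels)
    elif estimate_levels:
        lo, hi = _estimate_levels(trace.samples)
    else:
        lo, hi = sorted((trace.spec.closed_current, trace.spec.open_current))
    threshold = 0.5 * (lo + hi)
    # open is the side of the threshold where the open level lies
    open_is_high = trace.spec.open_current >= trace.spec.closed_current if levels is None \
        else True
    above = trace.samples >= threshold
    is_open = above if open_is_high else ~above

    change = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(is_open)]])
    durations = (ends - starts) / fs
    states = is_open[starts].astype(np.int8)
    return IdealizedRecord(
        states=states,
        durations=durations,
        threshold=threshold,
        total_duration=len(trace.samples) / fs,
    )


def compute_po(
    record: IdealizedRecord, window: Optional[float] = None
) -> Union[float, PoTimeSeries]:
    """Open probability of a record: whole-record scalar or windowed series.

    Windows with no event boundary inherit the state spanning them (a window
    inside one long closure scores 0, inside one long opening scores 1).
    """
    if window is None:
        if record.total_duration < 180.0:
            warnings.warn(
                f"whole-record Po from only {record.total_duration:.1f} s "
                "(< 180 s of continuous recording)",
                ShortRecordWarning,
                stacklevel=2,
            )
        return float(record.durations[record.states == OPEN].sum() / record.total_duration)
    if window <= 0:
        raise ValueError("window must be positive")
    if window > record.total_duration:
        raise ValueError("window exceeds record duration")
    starts = record.start_times
    open_dur = np.where(record.states == OPEN, record.durations, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(open_dur)])
    n = int(np.floor(record.total_duration / window + 1e-9))
    edges = np.arange(n + 1) * window
    j = np.clip(np.searchsorted(starts, edges, side="right") - 1, 0, len(starts) - 1)
    c_at = csum[j] + np.where(record.states[j] == OPEN, edges - starts[j], 0.0)
    po = np.diff(c_at) / window
    return PoTimeSeries(window=window, po_per_window=np.clip(po, 0.0, 1.0), n_trials=1)


def extract_dwells(
    record: IdealizedRecord,
    state: Union[int, str],
    min_duration: float = 1e-3,
    merge_flanking: bool = False,
) -> np.ndarray:
    """Dwell times (s) of one conductance class, excluding unresolved events.

    Events of the *requested* class shorter than ``min_duration`` are dropped.
    By default excluded events are simply omitted (flanking events of the
    other class are left untouched); with ``merge_flanking`` the two
    neighbours of a sub-resolution *opposite*-class event are concatenated
    (including the gap) into a single dwell of the requested class.
    """
    state = OPEN if state in (OPEN, "O", "open") else CLOSED
    if not merge_flanking:
        sel = record.durations[record.states == state]
        out = sel[sel >= min_duration]
    else:
        out_list: List[float] = []
        acc = None
        for s, d in zip(record.states, record.durations):
            if s == state:
                acc = d if acc is None else acc + d
            elif d < min_duration and acc is not None:
                acc += d  # unresolved opposite-class gap: bridge it
            else:
                if acc is not None:
                    out_list.append(acc)
                acc = None
        if acc is not None:
            out_list.append(acc)
        out = np.array([d for d in out_list if d >= min_duration])
    if len(out) == 0:
        warnings.warn("no events survive the resolution cutoff", UserWarning, stacklevel=2)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# Exponential-mixture maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class DwellFit:
    """Fitted exponential mixture over dwell times >= cutoff.

    ``taus`` (seconds, strictly increasing) and ``areas`` describe the
    untruncated mixture; the fitted density is renormalised over
    [cutoff, inf).  ``selection_table`` is populated by
    :func:`select_n_components`.
    """

    taus: np.ndarray
    areas: np.ndarray
    n_components: int
    loglik: float
    n_events: int
    cutoff: float = 0.0
    selection_table: Optional[List[dict]] = None

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if len(self.taus) != self.n_components or len(self.areas) != self.n_components:
            raise ValueError("component count mismatch")
        if np.any(self.taus <= 0) or np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be positive and strictly increasing")
        if np.any(self.areas < 0) or abs(self.areas.sum() - 1.0) > 1e-8:
            raise ValueError("areas must be non-negative and sum to 1")

    @property
    def taus_ms(self) -> np.ndarray:
        return self.taus * 1e3

    def _norm(self) -> float:
        """Probability mass of the untruncated mixture above the cutoff."""
        return float(np.sum(self.areas * np.exp(-self.cutoff / self.taus)))

    def pdf(self, t: np.ndarray) -> np.ndarray:
        """Truncation-corrected density on [cutoff, inf)."""
        t = np.asarray(t, dtype=float)
        dens = np.sum(
            self.areas[:, None] / self.taus[:, None] * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        ) / self._norm()
        return np.where(t >= self.cutoff, dens, 0.0)

    def cdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        up = np.sum(
            self.areas[:, None]
            * (np.exp(-self.cutoff / self.taus[:, None]) - np.exp(-t[None, :] / self.taus[:, None])),
            axis=0,
        ) / self._norm()
        return np.clip(np.where(t >= self.cutoff, up, 0.0), 0.0, 1.0)

    @property
    def bic(self) -> float:
        k_free = 2 * self.n_components - 1
        return k_free * np.log(self.n_events) - 2.0 * self.loglik

    def to_dict(self) -> dict:
        d = {
            "taus_ms": self.taus_ms.tolist(),
            "areas": self.areas.tolist(),
            "n_components": self.n_components,
            "loglik": self.loglik,
            "n_events": self.n_events,
            "cutoff_ms": self.cutoff * 1e3,
        }
        if self.selection_table is not None:
            d["selection_table"] = self.selection_table
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _neg_loglik_grad(theta: np.ndarray, t: np.ndarray, k: int, cutoff: float):
    """-loglik of the truncated mixture and its gradient.

    theta = (log tau_1..k, logits_1..k-1); the last logit is fixed at 0 and
    mixture weights are the softmax of the logits.
    """
    log_tau = np.clip(theta[:k], -50.0, 50.0)  # keep exp() finite for wild starts
    logits = np.concatenate([theta[k:], [0.0]])
    log_w = logits - logsumexp(logits)
    tau = np.exp(log_tau)
    n = len(t)
    # log f(t) = logsumexp_i [log w_i - log tau_i - t/tau_i] - log Z(cutoff)
    a = log_w[None, :] - log_tau[None, :] - t[:, None] / tau[None, :]
    log_f = logsumexp(a, axis=1)
    log_z = logsumexp(log_w - cutoff / tau)
    nll = -(np.sum(log_f) - n * log_z)

    # responsibilities r_ji and truncation weights q_i
    r = np.exp(a - log_f[:, None])
    q = np.exp(log_w - cutoff / tau - log_z)
    big_r = r.sum(axis=0)
    d_log_tau = (r * (t[:, None] / tau[None, :] - 1.0)).sum(axis=0) - n * q * cutoff / tau
    d_logits = (big_r - n * q)[:-1]
    return nll, -np.concatenate([d_log_tau, d_logits])


def fit_dwell_pdf_mle(
    dwells: np.ndarray,
    n_components: int,
    cutoff: float = 0.0,
    n_starts: int = 8,
    seed: int = 0,
) -> DwellFit:
    """Maximum-likelihood exponential-mixture fit of a dwell-time sample.

    Maximises the truncation-corrected log-likelihood (component densities
    renormalised over [cutoff, inf)) over (log tau, logit area) with
    multi-start L-BFGS from log-spaced sample quantiles.  For one component
    the closed-form MLE ``tau = mean(t) - cutoff`` is used directly.
    """
    t = np.asarray(dwells, dtype=float)
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if np.any(t < cutoff):
        raise ValueError("all dwells must be >= cutoff")
    n = len(t)
    if n < 10 * (2 * k - 1):
        raise DwellFitError(
            f"{n} events is too few for {k} components (need >= {10 * (2 * k - 1)})"
        )

    if k == 1:
        tau = float(t.mean() - cutoff)
        ll = float(-n * (np.log(tau) + 1.0) + n * 0.0)  # -n log tau - sum (t-c)/tau = -n(log tau + 1)
        return DwellFit(taus=np.array([tau]), areas=np.array([1.0]),
                        n_components=1, loglik=ll, n_events=n, cutoff=cutoff)

    rng = np.random.default_rng(seed)
    # starts: log-spaced quantiles of the (shifted) sample, jittered
    shifted = np.maximum(t - cutoff, 1e-12)
    base_q = np.quantile(shifted, np.linspace(0.15, 0.95, k))
    base_q = np.maximum(base_q, 1e-9)
    best = None
    for s in range(n_starts):
        jitter = rng.normal(0.0, 0.4, size=k) if s else np.zeros(k)
        log_tau0 = np.sort(np.log(base_q) + jitter)
        logits0 = rng.normal(0.0, 0.3, size=k - 1) if s else np.zeros(k - 1)
        theta0 = np.concatenate([log_tau0, logits0])
        res = optimize.minimize(
            _neg_loglik_grad,
            theta0,
            args=(t, k, cutoff),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.success or res.status == 1:  # status 1: iteration limit, still usable
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise DwellFitError(
            f"mixture likelihood failed to converge in {n_starts} starts "
            f"(k={k}, n={n}, cutoff={cutoff})"
        )

    log_tau = best.x[:k]
    logits = np.concatenate([best.x[k:], [0.0]])
    w = np.exp(logits - logsumexp(logits))
    order = np.argsort(log_tau)
    taus = np.exp(log_tau[order])
    areas = w[order]
    # collapse numerically duplicated components is not attempted; strictly
    # increasing taus are enforced by a tiny perturbation if the optimiser
    # returned ties
    eps = 1e-12
    for i in range(1, k):
        if taus[i] <= taus[i - 1]:
            taus[i] = taus[i - 1] * (1 + 1e-9) + eps
    return DwellFit(
        taus=taus, areas=areas / areas.sum(), n_components=k,
        loglik=-float(best.fun), n_events=n, cutoff=cutoff,
    )


def select_n_components(
    dwells: np.ndarray,
    max_components: int = 4,
    cutoff: float = 0.0,
    alpha: float = 0.05,
    criterion: str = "lrt",
    seed: int = 0,
) -> DwellFit:
    """Fit 1..max_components mixtures and select the component count.

    ``criterion="lrt"``: add components while twice the log-likelihood gain
    exceeds the chi-square(2 df) critical value at ``alpha`` (stops at the
    first non-significant addition).  ``"bic"``: minimise BIC.  The returned
    fit carries the full comparison table.
    """
    if criterion not in ("lrt", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")

    fits: List[DwellFit] = []
    table: List[dict] = []
    for k in range(1, max_components + 1):
        try:
            f = fit_dwell_pdf_mle(dwells, k, cutoff=cutoff, seed=seed)
        except DwellFitError:
            if not fits:
                raise
            break
        fits.append(f)
        row = {"n_components": f.n_components, "loglik": f.loglik, "bic": f.bic}
        if len(fits) > 1:
            lr = 2.0 * (f.loglik - fits[-2].loglik)
            row["lr_stat"] = lr
            row["p_value"] = float(stats.chi2.sf(max(lr, 0.0), df=2))
        table.append(row)
        # sequential LRT: once an added component is non-significant, larger
        # mixtures are not entertained
        if criterion == "lrt" and len(fits) > 1 and row["p_value"] >= alpha:
            break

    if criterion == "lrt":
        chosen = fits[0]
        for i in range(1, len(fits)):
            if table[i]["p_value"] < alpha:
                chosen = fits[i]
            else:
                break
    else:
        chosen = min(fits, key=lambda f: f.bic)
    chosen.selection_table = table
    return chosen


def goodness_of_fit_chi2(
    dwells: np.ndarray,
    fit: DwellFit,
    bins_per_decade: int = 10,
    min_expected: float = 5.0,
) -> Tuple[float, float]:
    """Chi-square comparison of the log-binned histogram with the fitted pdf.

    Returns (statistic, p_value); degrees of freedom are the merged bin count
    minus one minus the number of free mixture parameters.
    """
    t = np.asarray(dwells, dtype=float)
    lo = max(fit.cutoff, t.min())
    edges = 10.0 ** np.arange(
        np.floor(np.log10(max(lo, 1e-12)) * bins_per_decade) / bins_per_decade,
        np.log10(t.max()) + 1.0 / bins_per_decade,
        1.0 / bins_per_decade,
    )
    obs, edges = np.histogram(t, bins=edges)
    expected = len(t) * np.diff(fit.cdf(edges))
    # merge sparse bins from the right
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if o_acc or e_acc:
        if exp_m:
            obs_m[-1] += o_acc
            exp_m[-1] += e_acc
    obs_m = np.asarray(obs_m, dtype=float)
    exp_m = np.asarray(exp_m, dtype=float)
    exp_m *= obs_m.sum() / exp_m.sum()
    stat = float(np.sum((obs_m - exp_m) ** 2 / exp_m))
    dof = max(len(obs_m) - 1 - (2 * fit.n_components - 1), 1)
    return stat, float(stats.chi2.sf(stat, df=dof))
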