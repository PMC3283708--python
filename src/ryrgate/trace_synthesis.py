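"""Synthetic single-channel current records and dwell-time samples.

Emulates the acquisition chain of a planar-bilayer single-channel recording:
a two-level (closed/open) current driven by the Markov gating path, low-pass
filtered with a Gaussian filter characterised by its -3 dB cutoff (the
standard description of the analog recording filter), sampled uniformly, with
additive Gaussian baseline noise.  Defaults follow the recording conditions
the model is calibrated against: 20 kHz sampling, 800 Hz (-3 dB) low-pass.

Also provides direct exponential-mixture dwell-time sampling (optionally
left-truncated, mimicking the exclusion of unresolved sub-millisecond events)
and slow modal switching of the gating rates, which produces the 10-s-scale
fluctuations of windowed Po seen in long RyR2 records.

What the generator does **not** emulate: capacitance transients, baseline
drift, subconductance levels and multi-channel superposition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .kinetic_model import KineticParameters
from .stochastic_sim import FREE, StatePath

__all__ = [
    "AcquisitionSpec",
    "CurrentTrace",
    "ModalSpec",
    "GAUSSIAN_SIGMA_COEF",
    "synthesize_trace",
    "generate_dwell_sample",
    "generate_modal_path",
    "CONTROL_OPEN_MIXTURE",
    "CONTROL_CLOSED_MIXTURE",
]

#: sigma_t * fc for a Gaussian filter with -3 dB point at fc: sqrt(ln 2)/(2 pi).
GAUSSIAN_SIGMA_COEF = math.sqrt(math.log(2.0)) / (2.0 * math.pi)

#: Control-like dwell mixtures (seconds): two open / three closed components,
#: open time constants of order 1 ms and closed of order 1-100 ms, with means
#: near the control values (~1 ms open, ~26 ms closed).
CONTROL_OPEN_MIXTURE = {"taus": (0.0007, 0.0025), "areas": (0.75, 0.25)}
CONTROL_CLOSED_MIXTURE = {"taus": (0.0012, 0.012, 0.110), "areas": (0.5, 0.3, 0.2)}


@dataclass(frozen=True)
class ModalSpec:
    """Slow hidden-Markov modulation of the gating rates.

    Each mode m has an exponential dwell with mean ``dwell_means[m]`` (s) and
    multiplies the background opening rate by ``ko_multipliers[m]``.
    """

    dwell_means: Tuple[float, ...]
    ko_multipliers: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.dwell_means) != len(self.ko_multipliers):
            raise ValueError("dwell_means and ko_multipliers must have equal length")
        if len(self.dwell_means) < 1:
            raise ValueError("at least one mode is required")
        if any(d <= 0 for d in self.dwell_means) or any(m <= 0 for m in self.ko_multipliers):
            raise ValueError("mode dwell means and multipliers must be positive")

    @property
    def n_modes(self) -> int:
        return len(self.dwell_means)

    @classmethod
    def from_po_levels(
        cls, params: KineticParameters, po_levels: Sequence[float], dwell_means: Sequence[float]
    ) -> "ModalSpec":
        """Build multipliers so each mode's equilibrium Po equals the given level."""
        from .kinetic_model import opening_rate

        ko_bg = opening_rate(params, 0.0, "rational").k_O
        mults = []
        for p in po_levels:
            if not 0.0 < p < 1.0:
                raise ValueError("mode Po levels must lie in (0, 1)")
            mults.append(params.kC * p / (1.0 - p) / ko_bg)
        return cls(dwell_means=tuple(float(d) for d in dwell_means), ko_multipliers=tuple(mults))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Recording-chain description: sampling, filtering, levels, noise."""

    sample_rate: float = 20_000.0       # Hz
    filter_cutoff: Optional[float] = 800.0  # Hz, -3 dB low-pass; None disables
    open_current: float = 30.0          # pA
    closed_current: float = 0.0         # pA
    noise_sd: float = 3.0               # pA, additive Gaussian
    modal_spec: Optional[ModalSpec] = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.filter_cutoff is not None and self.sample_rate <= 2.0 * self.filter_cutoff:
            raise ValueError("sample_rate must exceed twice the filter cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.open_current == self.closed_current:
            raise ValueError("open and closed current levels must differ")

    def to_dict(self) -> dict:
        return {
            "sample_rate": self.sample_rate,
            "filter_cutoff": self.filter_cutoff,
            "open_current": self.open_current,
            "closed_current": self.closed_current,
            "noise_sd": self.noise_sd,
        }


@dataclass
class CurrentTrace:
    """Uniformly sampled, filtered, noisy current record (pA)."""

    samples: np.ndarray
    spec: AcquisitionSpec
    truth: Optional[StatePath] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.spec.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.spec.sample_rate

    def write_csv(self, path, sidecar: Optional[str] = None) -> None:
        """Write samples as a one-column CSV plus a JSON acquisition sidecar."""
        import pandas as pd

        pd.DataFrame({"current_pA": self.samples}).to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(self.spec.to_dict(), fh, indent=1)

    @classmethod
    def read_csv(cls, path, sidecar=None, spec: Optional[AcquisitionSpec] = None):
        import pandas as pd

        samples = pd.read_csv(path)["current_pA"].to_numpy()
        if spec is None:
            if sidecar is None:
                raise ValueError("provide either a sidecar path or an AcquisitionSpec")
            with open(sidecar) as fh:
                d = json.load(fh)
            spec = AcquisitionSpec(**{k: d[k] for k in
                                      ("sample_rate", "filter_cutoff", "open_current",
                                       "closed_current", "noise_sd")})
        return cls(samples=samples, spec=spec)


def synthesize_trace(path: StatePath, spec: AcquisitionSpec, seed=None) -> CurrentTrace:
    """Render a gating path as a sampled, filtered, noisy current record.

    The two-level signal follows the path's conductance (open = activated
    occupancy or flicker-gate open, per the path's gating law); it is low-pass
    filtered at the -3 dB cutoff with a Gaussian kernel, then white Gaussian
    baseline noise is added.  The truth path is carried unmodified.
    """
    if spec.filter_cutoff is not None and path.duration < 2.0 / spec.filter_cutoff:
        raise ValueError("path too short for the requested filter cutoff")
    n = int(round(path.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    idx = np.clip(np.searchsorted(path.times, t, side="right") - 1, 0, len(path.times) - 1)
    open_sample = path.conducting()[idx]
    signal = np.where(open_sample, spec.open_current, spec.closed_current).astype(float)
    if spec.filter_cutoff is not None:
        sigma = GAUSSIAN_SIGMA_COEF * spec.sample_rate / spec.filter_cutoff
        signal = gaussian_filter1d(signal, sigma, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n)
    return CurrentTrace(samples=signal, spec=spec, truth=path)


def generate_dwell_sample(
    taus: Sequence[float],
    areas: Sequence[float],
    n: int,
    cutoff: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Draw n dwell times (s) from an exponential mixture, left-truncated at cutoff.

    ``areas`` are the mixture fractions of the *untruncated* mixture; by
    memorylessness the truncated draw is ``cutoff + Exp(tau_i)`` with the
    component chosen with probability proportional to ``a_i exp(-cutoff/tau_i)``.
    """
    taus = np.asarray(taus, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if taus.ndim != 1 or taus.size == 0 or np.any(taus <= 0):
        raise ValueError("taus must be positive")
    if areas.shape != taus.shape or np.any(areas < 0) or abs(areas.sum() - 1.0) > 1e-9:
        raise ValueError("areas must be non-negative and sum to 1")
    if n <= 0:
        raise ValueError("n must be positive")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    rng = np.random.default_rng(seed)
    w = areas * np.exp(-cutoff / taus)
    w = w / w.sum()
    comp = rng.choice(taus.size, size=n, p=w)
    return cutoff + rng.exponential(taus[comp])


def generate_modal_path(
    params: KineticParameters,
    modal_spec: ModalSpec,
    duration: float,
    seed=None,
) -> StatePath:
    """Gating path under slow modal switching of the opening rate.

    The hidden mode chain dwells exponentially (mean ``dwell_means[m]``) and
    moves to a uniformly chosen other mode (for two modes it alternates).  The
    flicker gate runs with ``k_O = k_O_bg * multiplier[m]`` within each mode;
    the occupancy coordinate stays FKBP-free.  With a single mode this reduces
    to the plain background simulation.  Mode switch times are recorded in
    ``path.meta["mode_times"]`` / ``meta["modes"]``.
    """
    from .kinetic_model import opening_rate

    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    ko_bg = opening_rate(params, 0.0, "rational").k_O
    kC = params.kC

    # hidden mode trajectory
    mode_times = [0.0]
    modes = [0 if modal_spec.n_modes == 1 else int(rng.integers(modal_spec.n_modes))]
    t = 0.0
    while True:
        t += rng.exponential(modal_spec.dwell_means[modes[-1]])
        if t >= duration:
            break
        m = modes[-1]
        if modal_spec.n_modes > 1:
            step = int(rng.integers(modal_spec.n_modes - 1))
            m = (m + 1 + step) % modal_spec.n_modes
        mode_times.append(t)
        modes.append(m)

    # gate chain with piecewise-constant opening rate
    times = [0.0]
    gates = [0]
    g = 0
    t = 0.0
    bounds = mode_times[1:] + [duration]
    for m, seg_end in zip(modes, bounds):
        ko = ko_bg * modal_spec.ko_multipliers[m]
        while True:
            rate = kC if g == 1 else ko
            t_next = t + rng.exponential(1.0 / rate)
            if t_next >= seg_end:
                t = seg_end
                break
            t = t_next
            g ^= 1
            times.append(t)
            gates.append(g)

    return StatePath(
        times=np.array(times),
        occ=np.full(len(times), FREE, dtype=np.int8),
        gate=np.array(gates, dtype=np.int8),
        duration=float(duration),
        law="rational",
        meta={"mode_times": mode_times, "modes": modes},
    )
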