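"""Exact stochastic simulation of the joint (FKBP occupancy x gating) process.

The joint process is a continuous-time Markov chain over ten states:
five occupancy states (Free, 12, 12*, 12.6, 12.6*) crossed with the two-level
gate (C, O).  Binding/conformational transitions and gating transitions never
co-occur at one event.  Sampling uses the Gillespie direct method, which is
statistically exact; piecewise-constant concentration protocols are handled by
discarding the pending waiting time at each segment boundary (exact by
exponential memorylessness).

State-wise gating (see the methods note): the analytic open-driving fraction
``nu`` is an ensemble probability.  Per channel, the gating law is applied
with the nu-indicator of the current occupancy state (1 in 12*/12.6*, else 0).
Under the default rational law the indicator value 1 saturates the law
(alpha + nu >= 1), whose limit is an always-conducting channel: the channel
therefore conducts whenever its occupancy coordinate is activated, while the
background flicker chain C<->O runs with ``k_O = kC alpha/(1-alpha)``.  The
resulting ensemble Po is ``nu + (1-nu) alpha``, equal to the analytic
``alpha + nu`` up to the negligible cross-term ``alpha*nu`` (< 7.2e-4 at the
default calibration).  Under the linear law the activated opening rate is the
finite ``kC (1+alpha)`` and conduction follows the gate alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .kinetic_model import (
    GatingLaw,
    KineticParameters,
    LigandConcentrations,
    equilibrium_occupancy,
    opening_rate,
)

__all__ = [
    "OCC_LABELS",
    "GATE_LABELS",
    "ConcentrationProtocol",
    "StatePath",
    "PoTimeSeries",
    "simulate_path",
    "trial_average_po",
    "run_antagonism_protocol",
    "run_washout",
    "build_antagonism_protocol",
    "build_washout_protocol",
    "child_seeds",
]

# Occupancy state codes.
FREE, B12, A12, B126, A126 = range(5)
OCC_LABELS = ("Free", "12", "12*", "12.6", "12.6*")
GATE_LABELS = ("C", "O")
_ACTIVATED = np.array([False, False, True, False, True])


@dataclass(frozen=True)
class ConcentrationProtocol:
    """Piecewise-constant ligand schedule: ordered (start time s, concentrations)."""

    segments: Tuple[Tuple[float, LigandConcentrations], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        times = [t for t, _ in self.segments]
        if times[0] != 0.0:
            raise ValueError("protocol must start at t = 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        for _, c in self.segments:
            if not isinstance(c, LigandConcentrations):
                raise TypeError("segment concentrations must be LigandConcentrations")

    @classmethod
    def constant(cls, conc: LigandConcentrations, description: str = "") -> "ConcentrationProtocol":
        return cls(segments=((0.0, conc),), description=description)

    @classmethod
    def from_steps(cls, steps: Sequence[Tuple[float, float, float]], description: str = ""):
        """Build from (t, fkbp12_uM, fkbp12_6_uM) triples."""
        return cls(
            segments=tuple((float(t), LigandConcentrations(f12, f126)) for t, f12, f126 in steps),
            description=description,
        )

    @classmethod
    def from_file(cls, path) -> "ConcentrationProtocol":
        """Read a protocol from a YAML/JSON list of {t, fkbp12_uM, fkbp12_6_uM}."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if isinstance(doc, dict):
            desc, doc = doc.get("description", ""), doc["segments"]
        else:
            desc = ""
        steps = [(seg["t"], seg.get("fkbp12_uM", 0.0), seg.get("fkbp12_6_uM", 0.0)) for seg in doc]
        return cls.from_steps(steps, description=desc)

    def to_file(self, path) -> None:
        doc = {
            "description": self.description,
            "segments": [
                {"t": t, "fkbp12_uM": c.fkbp12, "fkbp12_6_uM": c.fkbp12_6}
                for t, c in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def conc_at(self, t: float) -> LigandConcentrations:
        out = self.segments[0][1]
        for start, c in self.segments:
            if start <= t:
                out = c
            else:
                break
        return out


@dataclass
class StatePath:
    """Continuous-time trajectory of the joint (occupancy, gate) process.

    ``times[i]`` is the entry time of state ``(occ[i], gate[i])``, valid on
    ``[times[i], times[i+1])``; the final state persists to ``duration``.
    ``law`` records the gating law used, which determines conduction: under
    the rational law the channel conducts when the gate is open *or* the
    occupancy is activated; under the linear law, when the gate is open.
    """

    times: np.ndarray
    occ: np.ndarray
    gate: np.ndarray
    duration: float
    seed: Optional[int] = None
    law: GatingLaw = "rational"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.occ = np.asarray(self.occ, dtype=np.int8)
        self.gate = np.asarray(self.gate, dtype=np.int8)
        if len(self.times) == 0 or self.times[0] != 0.0:
            raise ValueError("path must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.times[-1] > self.duration:
            raise ValueError("event times must not exceed duration")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def interval_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.times, np.append(self.times[1:], self.duration)

    def conducting(self) -> np.ndarray:
        """Boolean per event interval: is the channel passing current?"""
        open_gate = self.gate == 1
        if self.law == "rational":
            return open_gate | _ACTIVATED[self.occ]
        return open_gate

    def open_fraction(self, t0: float = 0.0, t1: Optional[float] = None) -> float:
        """Fraction of [t0, t1) the channel spends conducting."""
        t1 = self.duration if t1 is None else t1
        if not 0.0 <= t0 < t1 <= self.duration:
            raise ValueError("invalid time window")
        return float((self._cum_open(np.array([t1])) - self._cum_open(np.array([t0])))[0]) / (t1 - t0)

    def _cum_open(self, t: np.ndarray) -> np.ndarray:
        """Cumulative conducting time C(t), vectorized over query times."""
        starts, ends = self.interval_bounds
        cond = self.conducting().astype(float)
        seg = cond * (ends - starts)
        csum = np.concatenate([[0.0], np.cumsum(seg)])
        j = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        return csum[j] + cond[j] * (t - starts[j])

    def po_windows(self, window: float) -> np.ndarray:
        """Open fraction over consecutive windows (trailing partial discarded)."""
        if window <= 0:
            raise ValueError("window must be positive")
        if window > self.duration:
            raise ValueError("window exceeds path duration")
        n = int(np.floor(self.duration / window + 1e-9))
        edges = np.arange(n + 1) * window
        c = self._cum_open(edges)
        return np.diff(c) / window

    def occupancy_fractions(self) -> np.ndarray:
        """Time fraction spent in each occupancy state (order of OCC_LABELS)."""
        starts, ends = self.interval_bounds
        dur = ends - starts
        return np.bincount(self.occ, weights=dur, minlength=5) / self.duration

    def mean_dwell(self, coord: str = "gate", value: int = 1) -> float:
        """Mean sojourn length in gate==value (or occ==value) along the path."""
        arr = self.gate if coord == "gate" else self.occ
        starts, ends = self.interval_bounds
        dur = ends - starts
        # merge consecutive intervals with the same coordinate value
        change = np.concatenate([[True], np.diff(arr) != 0])
        run_id = np.cumsum(change) - 1
        run_val = arr[change]
        run_dur = np.bincount(run_id, weights=dur)
        sel = run_dur[run_val == value]
        # drop the censored first/last sojourns
        if len(sel) > 2:
            sel = sel[1:-1]
        if len(sel) == 0:
            return float("nan")
        return float(sel.mean())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "occupancy": [OCC_LABELS[i] for i in self.occ],
                "gate": [GATE_LABELS[i] for i in self.gate],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class PoTimeSeries:
    """Windowed open probability, optionally trial-averaged.

    ``po_per_window`` is the across-trial mean per window; ``trial_windows``
    (n_trials x n_windows) retains the per-trial values for error estimates.
    """

    window: float
    po_per_window: np.ndarray
    n_trials: int
    trial_windows: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.po_per_window = np.asarray(self.po_per_window, dtype=float)
        if self.window <= 0:
            raise ValueError("window must be positive")
        if np.any(self.po_per_window < -1e-12) or np.any(self.po_per_window > 1 + 1e-12):
            raise ValueError("windowed Po values must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        """Window start times."""
        return np.arange(len(self.po_per_window)) * self.window

    def sem_per_window(self) -> np.ndarray:
        if self.trial_windows is None or self.n_trials < 2:
            raise ValueError("per-trial values required for an SEM estimate")
        return self.trial_windows.std(axis=0, ddof=1) / np.sqrt(self.n_trials)

    def steady_state_po(self, harvest_fraction: float = 0.5) -> float:
        """Mean Po over the final ``harvest_fraction`` of the record."""
        k = self._harvest_start(harvest_fraction)
        return float(self.po_per_window[k:].mean())

    def steady_state_sem(self, harvest_fraction: float = 0.5) -> float:
        """SEM of the steady-state Po across trials."""
        if self.trial_windows is None or self.n_trials < 2:
            raise ValueError("per-trial values required for an SEM estimate")
        k = self._harvest_start(harvest_fraction)
        per_trial = self.trial_windows[:, k:].mean(axis=1)
        return float(per_trial.std(ddof=1) / np.sqrt(self.n_trials))

    def _harvest_start(self, harvest_fraction: float) -> int:
        if not 0.0 < harvest_fraction <= 1.0:
            raise ValueError("harvest_fraction must lie in (0, 1]")
        n = len(self.po_per_window)
        return n - max(1, int(round(n * harvest_fraction)))

    def mean_po(self, t0: float, t1: float) -> float:
        """Mean Po over windows fully inside [t0, t1)."""
        t = self.times
        sel = (t >= t0 - 1e-9) & (t + self.window <= t1 + 1e-9)
        if not sel.any():
            raise ValueError("no complete window inside the requested interval")
        return float(self.po_per_window[sel].mean())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"window_start": self.times, "po": self.po_per_window})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gillespie core
# ---------------------------------------------------------------------------

def _occupancy_transitions(params: KineticParameters, conc: LigandConcentrations):
    """Per-occupancy-state tuples of (rate, target)."""
    return (
        ((params.k1 * conc.fkbp12, B12), (params.k3 * conc.fkbp12_6, B126)),  # Free
        ((params.k_m1, FREE), (params.k2, A12)),                              # 12
        ((params.k_m2, B12),),                                                # 12*
        ((params.k_m3, FREE), (params.k4, A126)),                             # 12.6
        ((params.k_m4, B126),),                                               # 12.6*
    )


def _gate_open_rates(params: KineticParameters, law: GatingLaw) -> np.ndarray:
    """C->O rate per occupancy state under the state-wise nu-indicator."""
    ko_bg = opening_rate(params, 0.0, law).k_O
    rates = np.full(5, ko_bg)
    if law == "linear":
        rates[_ACTIVATED] = params.kC * (1.0 + params.alpha)
    # rational law: activated states conduct regardless of the flicker gate,
    # so the background chain keeps ko_bg everywhere.
    return rates


def _draw_initial_state(params, conc, law, rng) -> Tuple[int, int]:
    occ = equilibrium_occupancy(params, conc)
    o = int(rng.choice(5, p=occ.as_array() / occ.as_array().sum()))
    ko = _gate_open_rates(params, law)[o]
    p_open = ko / (ko + params.kC)
    g = int(rng.random() < p_open)
    return o, g


def simulate_path(
    params: KineticParameters,
    protocol: ConcentrationProtocol,
    duration: float,
    seed,
    law: GatingLaw = "rational",
    init: str = "free_closed",
) -> StatePath:
    """Exact Gillespie sample of the joint occupancy x gating CTMC.

    Parameters
    ----------
    protocol : piecewise-constant ligand schedule (perfect perfusion steps).
    duration : total simulated time, s.
    seed : int or numpy SeedSequence/Generator; same seed => bit-identical path.
    init : "free_closed" starts FKBP-free with the gate closed (the
        FKBP-depleted experimental condition); "equilibrium" draws the initial
        state from the stationary law of the first segment's concentrations
        (the exact stationary start for steady-state averages).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(protocol, LigandConcentrations):
        protocol = ConcentrationProtocol.constant(protocol)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None

    gate_open = _gate_open_rates(params, law)
    kC = params.kC

    if init == "equilibrium":
        o, g = _draw_initial_state(params, protocol.segments[0][1], law, rng)
    elif init == "free_closed":
        o, g = FREE, 0
    else:
        raise ValueError(f"unknown init {init!r}")

    times: List[float] = [0.0]
    occs: List[int] = [o]
    gates: List[int] = [g]

    seg_starts = [t for t, _ in protocol.segments] + [duration]
    t = 0.0
    exponential = rng.exponential
    uniform = rng.random
    for si, (seg_t, conc) in enumerate(protocol.segments):
        seg_end = min(seg_starts[si + 1], duration)
        if seg_t >= duration:
            break
        occ_tr = _occupancy_transitions(params, conc)
        occ_tot = [sum(r for r, _ in tr) for tr in occ_tr]
        t = max(t, seg_t)
        while True:
            r_gate = kC if g == 1 else gate_open[o]
            total = occ_tot[o] + r_gate
            t_next = t + exponential(1.0 / total)
            if t_next >= seg_end:
                t = seg_end
                break
            t = t_next
            u = uniform() * total
            if u < r_gate:
                g ^= 1
            else:
                u -= r_gate
                for r, target in occ_tr[o]:
                    if u < r:
                        o = target
                        break
                    u -= r
                else:  # numerical guard: attribute to the last transition
                    o = occ_tr[o][-1][1]
            times.append(t)
            occs.append(o)
            gates.append(g)
        if seg_end >= duration:
            break

    return StatePath(
        times=np.array(times),
        occ=np.array(occs, dtype=np.int8),
        gate=np.array(gates, dtype=np.int8),
        duration=float(duration),
        seed=seed_int,
        law=law,
        meta={"init": init, "protocol": protocol.description},
    )


def child_seeds(seed, n: int) -> List[np.random.SeedSequence]:
    """Deterministically spawn n per-trial seed sequences from a master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def trial_average_po(
    params: KineticParameters,
    protocol: ConcentrationProtocol,
    duration: float,
    n_trials: int,
    window: float,
    seed,
    law: GatingLaw = "rational",
    init: str = "free_closed",
) -> PoTimeSeries:
    """Mean open fraction per window across independent channel simulations."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if window > duration:
        raise ValueError("window exceeds simulation duration")
    rows = []
    for ss in child_seeds(seed, n_trials):
        path = simulate_path(params, protocol, duration, np.random.default_rng(ss), law=law, init=init)
        rows.append(path.po_windows(window))
    trial_windows = np.vstack(rows)
    return PoTimeSeries(
        window=window,
        po_per_window=trial_windows.mean(axis=0),
        n_trials=n_trials,
        trial_windows=trial_windows,
    )


# ---------------------------------------------------------------------------
# Named experimental protocols
# ---------------------------------------------------------------------------

def build_antagonism_protocol(variant: str) -> ConcentrationProtocol:
    """20-minute antagonism protocols (concentrations in uM).

    ``pre_fkbp12_6``: control -> +200 nM FKBP12.6 -> incremental FKBP12 up to
    1 uM (tests whether prior FKBP12.6 occupancy blocks activation).
    ``post_fkbp12_6``: control -> +200 nM FKBP12 -> +200 nM FKBP12.6 (tests
    whether FKBP12.6 can reverse an established activation).
    """
    if variant == "pre_fkbp12_6":
        return ConcentrationProtocol.from_steps(
            [
                (0.0, 0.0, 0.0),
                (120.0, 0.0, 0.2),
                (480.0, 0.001, 0.2),
                (720.0, 0.2, 0.2),
                (960.0, 1.0, 0.2),
            ],
            description="pre-block: FKBP12.6 200 nM first, then FKBP12 steps to 1 uM",
        )
    if variant == "post_fkbp12_6":
        return ConcentrationProtocol.from_steps(
            [
                (0.0, 0.0, 0.0),
                (120.0, 0.2, 0.0),
                (660.0, 0.2, 0.2),
            ],
            description="post-activation: FKBP12 200 nM first, FKBP12.6 200 nM after",
        )
    raise ValueError(f"unknown variant {variant!r} (expected 'pre_fkbp12_6' or 'post_fkbp12_6')")


ANTAGONISM_DURATION = 1200.0  # s (20 simulated minutes)


def run_antagonism_protocol(
    params: KineticParameters,
    variant: str,
    seed,
    n_trials: int = 10,
    window: float = 10.0,
    law: GatingLaw = "rational",
) -> PoTimeSeries:
    """Windowed Po for the pre-/post-FKBP12.6 antagonism protocols."""
    protocol = build_antagonism_protocol(variant)
    return trial_average_po(
        params, protocol, ANTAGONISM_DURATION, n_trials, window, seed, law=law, init="free_closed"
    )


def build_washout_protocol(fkbp12_conc: float, bind_time: float, washout_time: float):
    """Exposure to FKBP12 followed by perfusion back to zero ligand."""
    if bind_time > 0:
        segs = [(0.0, fkbp12_conc, 0.0), (float(bind_time), 0.0, 0.0)]
    else:
        segs = [(0.0, 0.0, 0.0)]
    return (
        ConcentrationProtocol.from_steps(segs, description="FKBP12 exposure then washout"),
        float(bind_time) + float(washout_time),
    )


def run_washout(
    params: KineticParameters,
    fkbp12_conc: float,
    bind_time: float,
    washout_time: float,
    seed,
    n_trials: int = 10,
    window: float = 10.0,
    law: GatingLaw = "rational",
) -> PoTimeSeries:
    """Windowed Po across an FKBP12 exposure phase and a washout phase."""
    protocol, duration = build_washout_protocol(fkbp12_conc, bind_time, washout_time)
    return trial_average_po(
        params, protocol, duration, n_trials, window, seed, law=law, init="free_closed"
    )
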