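"""Idealization, open probability, dwell extraction and mixture fitting."""

import numpy as np
import pytest

from ryrgate.channel_stats import (
    DwellFit,
    DwellFitError,
    IdealizedRecord,
    LevelEstimationError,
    ShortRecordWarning,
    _neg_loglik_grad,
    compute_po,
    extract_dwells,
    fit_dwell_pdf_mle,
    goodness_of_fit_chi2,
    idealize_threshold50,
    select_n_components,
)
from ryrgate.stochastic_sim import StatePath
from ryrgate.trace_synthesis import (
    AcquisitionSpec,
    CONTROL_CLOSED_MIXTURE,
    CONTROL_OPEN_MIXTURE,
    CurrentTrace,
    generate_dwell_sample,
    synthesize_trace,
)


def record(*events):
    """Build an IdealizedRecord from (state_char, duration_s) pairs."""
    states = np.array([1 if s == "O" else 0 for s, _ in events], dtype=np.int8)
    durations = np.array([d for _, d in events], dtype=float)
    return IdealizedRecord(states=states, durations=durations, threshold=15.0,
                           total_duration=float(durations.sum()))


def square_path(durations_open_first, duration=None):
    """Alternating O/C gate path starting open, from a list of durations (s)."""
    times = np.concatenate([[0.0], np.cumsum(durations_open_first)[:-1]])
    gates = np.array([1 - i % 2 for i in range(len(durations_open_first))], dtype=np.int8)
    total = float(np.sum(durations_open_first))
    return StatePath(times=times, occ=np.zeros(len(times), dtype=np.int8),
                     gate=gates, duration=duration or total)


class TestIdealize:
    def test_noiseless_square_trace_recovered_exactly(self):
        fs = 20000.0
        # durations are integer multiples of the sampling interval
        durs = np.array([40, 100, 20, 400, 60, 380]) / fs
        path = square_path(durs)
        trace = synthesize_trace(path, AcquisitionSpec(noise_sd=0.0, filter_cutoff=None))
        rec = idealize_threshold50(trace)
        assert np.array_equal(rec.states, [1, 0, 1, 0, 1, 0])
        assert np.allclose(rec.durations, durs, atol=0.5 / fs)

    def test_all_closed_trace(self):
        spec = AcquisitionSpec(noise_sd=0.0, filter_cutoff=None)
        trace = CurrentTrace(samples=np.zeros(10000), spec=spec)
        rec = idealize_threshold50(trace)
        assert len(rec) == 1 and rec.states[0] == 0
        with pytest.warns(ShortRecordWarning):
            assert compute_po(rec) == 0.0

    def test_estimated_levels_match_spec_levels(self, default_params):
        from ryrgate.trace_synthesis import ModalSpec, generate_modal_path

        spec = ModalSpec.from_po_levels(default_params, [0.3], [30.0])
        path = generate_modal_path(default_params, spec, 20.0, seed=1)
        trace = synthesize_trace(path, AcquisitionSpec(), seed=2)
        rec = idealize_threshold50(trace, estimate_levels=True)
        assert rec.threshold == pytest.approx(15.0, abs=1.5)

    def test_unimodal_trace_raises(self):
        rng = np.random.default_rng(3)
        spec = AcquisitionSpec(noise_sd=3.0)
        trace = CurrentTrace(samples=rng.normal(0, 3, 50000), spec=spec)
        with pytest.raises(LevelEstimationError):
            idealize_threshold50(trace, estimate_levels=True)


class TestComputePo:
    def test_simple_arithmetic(self):
        rec = record(*[("O", 1.0), ("C", 4.0)] * 3)
        with pytest.warns(ShortRecordWarning):
            assert compute_po(rec) == pytest.approx(0.2)

    def test_windowed_inherits_spanning_state(self):
        rec = record(("O", 0.5), ("C", 100.0))
        ts = compute_po(rec, window=10.0)
        assert len(ts.po_per_window) == 10
        assert ts.po_per_window[0] == pytest.approx(0.05)
        assert np.all(ts.po_per_window[1:] == 0.0)
        rec2 = record(("C", 5.0), ("O", 50.0), ("C", 5.0))
        ts2 = compute_po(rec2, window=10.0)
        assert np.all(ts2.po_per_window[1:5] == 1.0)  # windows inside the opening

    def test_windowed_matches_modal_truth(self, default_params):
        from ryrgate.trace_synthesis import ModalSpec, generate_modal_path

        spec = ModalSpec.from_po_levels(default_params, [0.01, 0.25], [30.0, 30.0])
        path = generate_modal_path(default_params, spec, 200.0, seed=4)
        trace = synthesize_trace(path, AcquisitionSpec(), seed=5)
        ts = compute_po(idealize_threshold50(trace), window=10.0)
        assert np.allclose(ts.po_per_window, path.po_windows(10.0), atol=0.02)

    def test_invalid_window(self):
        rec = record(("O", 1.0), ("C", 4.0))
        with pytest.raises(ValueError):
            compute_po(rec, window=-1.0)
        with pytest.raises(ValueError):
            compute_po(rec, window=100.0)

    def test_long_record_no_warning(self, recwarn):
        rec = record(("O", 10.0), ("C", 200.0))
        compute_po(rec)
        assert not any(isinstance(w.message, ShortRecordWarning) for w in recwarn.list)


class TestExtractDwells:
    def test_exclusion_rule(self):
        rec = record(("O", 0.5e-3), ("C", 1.0), ("O", 2e-3), ("C", 2.0), ("O", 3e-3))
        assert np.allclose(extract_dwells(rec, "open"), [2e-3, 3e-3])

    def test_zero_cutoff_is_identity(self):
        rec = record(("O", 0.5e-3), ("C", 1.0), ("O", 2e-3))
        assert np.allclose(extract_dwells(rec, "open", min_duration=0.0), [0.5e-3, 2e-3])

    def test_all_excluded_warns(self):
        rec = record(("O", 0.2e-3), ("C", 1.0), ("O", 0.3e-3))
        with pytest.warns(UserWarning, match="cutoff"):
            out = extract_dwells(rec, "open")
        assert len(out) == 0

    def test_merge_flanking_bridges_unresolved_gaps(self):
        rec = record(("C", 5e-3), ("O", 0.5e-3), ("C", 3e-3), ("O", 2e-3), ("C", 4e-3))
        merged = extract_dwells(rec, "closed", merge_flanking=True)
        assert np.allclose(merged, [8.5e-3, 4e-3])
        plain = extract_dwells(rec, "closed")
        assert np.allclose(plain, [5e-3, 3e-3, 4e-3])

    def test_mean_dwell_consistency_identity(self):
        rng = np.random.default_rng(6)
        durs = rng.exponential(0.01, size=200)
        events = [("O" if i % 2 else "C", d) for i, d in enumerate(durs)]
        rec = record(*events)
        open_dwells = extract_dwells(rec, "open", min_duration=0.0)
        assert open_dwells.mean() == pytest.approx(
            rec.durations[rec.states == 1].mean(), rel=1e-12
        )


class TestMixtureMle:
    def test_single_exponential_equals_sample_mean(self):
        d = generate_dwell_sample([0.005], [1.0], 5000, seed=7)
        fit = fit_dwell_pdf_mle(d, 1)
        assert fit.taus[0] == d.mean()  # closed-form MLE, exact

    def test_truncated_single_exponential(self):
        d = generate_dwell_sample([0.002], [1.0], 50_000, cutoff=1e-3, seed=8)
        fit = fit_dwell_pdf_mle(d, 1, cutoff=1e-3)
        assert fit.taus[0] == pytest.approx(d.mean() - 1e-3, rel=1e-12)
        assert fit.taus[0] == pytest.approx(0.002, rel=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_component_recovery(self, seed):
        d = generate_dwell_sample([0.001, 0.010], [0.5, 0.5], 20_000, seed=seed)
        fit = fit_dwell_pdf_mle(d, 2, seed=seed)
        assert fit.taus[0] == pytest.approx(0.001, rel=0.10)
        assert fit.taus[1] == pytest.approx(0.010, rel=0.10)
        assert fit.areas[0] == pytest.approx(0.5, abs=0.05)

    def test_truncated_recovery_unbiased(self):
        # truncation correction: the fit sees only dwells >= 1 ms yet recovers
        # the untruncated mixture parameters
        d = generate_dwell_sample([0.0012, 0.012], [0.6, 0.4], 30_000, cutoff=1e-3, seed=9)
        fit = fit_dwell_pdf_mle(d, 2, cutoff=1e-3, seed=9)
        assert fit.taus[0] == pytest.approx(0.0012, rel=0.10)
        assert fit.taus[1] == pytest.approx(0.012, rel=0.10)
        assert fit.areas[0] == pytest.approx(0.6, abs=0.05)

    def test_loglik_at_optimum_beats_truth(self):
        taus, areas = np.array([0.001, 0.010]), np.array([0.5, 0.5])
        for seed in range(3):
            d = generate_dwell_sample(taus, areas, 5000, seed=seed)
            fit = fit_dwell_pdf_mle(d, 2, seed=seed)
            theta_true = np.concatenate([np.log(taus), [0.0]])
            ll_true = -_neg_loglik_grad(theta_true, d, 2, 0.0)[0]
            assert fit.loglik >= ll_true - 1e-6

    def test_fitted_pdf_normalized_over_truncated_support(self):
        from scipy.integrate import quad

        d = generate_dwell_sample([0.0012, 0.012], [0.6, 0.4], 20_000, cutoff=1e-3, seed=10)
        fit = fit_dwell_pdf_mle(d, 2, cutoff=1e-3, seed=10)
        mass, _ = quad(lambda t: fit.pdf(np.array([t]))[0], 1e-3, np.inf, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-9)

    def test_goodness_of_fit_not_rejected_when_well_specified(self):
        d = generate_dwell_sample([0.001, 0.012], [0.5, 0.5], 30_000, cutoff=1e-3, seed=11)
        fit = fit_dwell_pdf_mle(d, 2, cutoff=1e-3, seed=11)
        stat, p = goodness_of_fit_chi2(d, fit)
        assert p > 0.01

    def test_too_few_events_rejected(self):
        with pytest.raises(DwellFitError, match="too few"):
            fit_dwell_pdf_mle(np.full(20, 0.01), 3)

    def test_dwells_below_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            fit_dwell_pdf_mle(np.array([0.5e-3, 2e-3] * 20), 1, cutoff=1e-3)

    def test_json_export(self, tmp_path):
        import json

        d = generate_dwell_sample([0.002], [1.0], 1000, seed=12)
        fit = fit_dwell_pdf_mle(d, 1)
        f = tmp_path / "fit.json"
        fit.to_json(f)
        loaded = json.loads(f.read_text())
        assert loaded["n_components"] == 1
        assert loaded["taus_ms"][0] == pytest.approx(fit.taus_ms[0])


class TestSelectComponents:
    def test_control_closed_structure_selected(self):
        d = generate_dwell_sample(CONTROL_CLOSED_MIXTURE["taus"], CONTROL_CLOSED_MIXTURE["areas"],
                                  20_000, cutoff=1e-3, seed=13)
        fit = select_n_components(d, max_components=4, cutoff=1e-3, seed=13)
        assert fit.n_components == 3
        assert fit.selection_table is not None
        assert fit.selection_table[1]["p_value"] < 0.05

    def test_control_open_structure_selected(self):
        d = generate_dwell_sample(CONTROL_OPEN_MIXTURE["taus"], CONTROL_OPEN_MIXTURE["areas"],
                                  20_000, cutoff=1e-3, seed=14)
        fit = select_n_components(d, max_components=4, cutoff=1e-3, seed=14)
        assert fit.n_components == 2

    def test_single_exponential_selects_one(self):
        d = generate_dwell_sample([0.005], [1.0], 10_000, seed=15)
        fit = select_n_components(d, max_components=3, seed=15)
        assert fit.n_components == 1

    def test_bic_criterion_agrees_on_easy_case(self):
        d = generate_dwell_sample([0.001, 0.020], [0.5, 0.5], 20_000, seed=16)
        fit = select_n_components(d, max_components=3, criterion="bic", seed=16)
        assert fit.n_components == 2


def test_record_validation():
    with pytest.raises(ValueError, match="alternat"):
        IdealizedRecord(states=np.array([1, 1]), durations=np.array([1.0, 1.0]),
                        threshold=0.0, total_duration=2.0)
    with pytest.raises(ValueError):
        IdealizedRecord(states=np.array([1, 0]), durations=np.array([1.0, -1.0]),
                        threshold=0.0, total_duration=0.0)


def test_event_csv_round_trip(tmp_path):
    rec = record(("O", 1e-3), ("C", 0.5), ("O", 2e-3))
    f = tmp_path / "events.csv"
    rec.to_csv(f)
    back = IdealizedRecord.from_csv(f)
    assert np.array_equal(back.states, rec.states)
    assert np.allclose(back.durations, rec.durations)
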