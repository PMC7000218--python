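"""Fate taxonomy: alignment, classification, stalls, window binning,
inter-mitotic times, heatmaps, and densities."""

import numpy as np
import pytest
from scipy.stats import binom

from zincycle import (
    ClassifierConfig,
    SyntheticConfig,
    align_to_mitosis,
    bin_by_mitosis_window,
    cdk2_density,
    classify_ensemble,
    classify_fate,
    detect_stall,
    generate_trace_ensemble,
    intermitotic_times,
    sort_heatmap,
)
from zincycle.fate import fate_fractions
from zincycle.traces import CellTrace, TraceEnsemble

DT = 0.2


def trace_from(values, divisions=(), cell_id=0, dt=DT):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * dt
    return CellTrace(cell_id=cell_id, t=t, ratio=values,
                     division_times=list(divisions))


def aligned_trace(ratio_fn, followup=20.0, divisions_after=(), cell_id=0):
    """Trace with mitosis at t=0 and given post-mitosis shape."""
    t = np.arange(-5.0, followup + DT / 2, DT)
    return CellTrace(cell_id=cell_id, t=t, ratio=ratio_fn(t),
                     division_times=[0.0, *divisions_after])


def ramp_crossing_at(t_cross, base=0.5, rate=0.35, level=1.0):
    def fn(t):
        return np.clip(level + rate * (t - t_cross), base, 1.9)
    return fn


class TestAlign:
    def test_alignment_re_zeroes(self):
        tr = trace_from(np.ones(300), divisions=[20.0])
        aligned, excluded = align_to_mitosis(TraceEnsemble([tr]))
        assert excluded == []
        assert aligned[0].division_times[0] == 0.0
        assert aligned[0].t[0] == pytest.approx(-20.0)

    def test_non_dividers_excluded(self):
        """Exactly the never-dividing cells are excluded (generator truth)."""
        cfg = SyntheticConfig(seed=21)
        ens, truth = generate_trace_ensemble(cfg, "ZD", 60)
        # drop the recorded division from 30% of cells
        no_div = set(truth.cells["cell_id"].iloc[::3])
        for tr in ens:
            if tr.cell_id in no_div:
                tr.division_times = []
        _, excluded = align_to_mitosis(ens)
        assert set(excluded) == no_div

    def test_idempotent(self):
        tr = trace_from(np.ones(300), divisions=[20.0])
        once, _ = align_to_mitosis(TraceEnsemble([tr]))
        twice, _ = align_to_mitosis(TraceEnsemble(once))
        assert np.array_equal(once[0].t, twice[0].t)
        assert once[0].division_times == twice[0].division_times


class TestClassifyFate:
    def test_prompt_commit_is_inc(self):
        rec = classify_fate(aligned_trace(ramp_crossing_at(2.0)))
        assert rec.fate == "CDK2inc"
        assert rec.commit_time <= 4.0

    def test_flat_low_is_quiescent(self):
        rec = classify_fate(aligned_trace(lambda t: np.full_like(t, 0.5)))
        assert rec.fate == "CDK2low"
        assert rec.commit_time is None

    def test_late_crossing_is_emerge(self):
        rec = classify_fate(aligned_trace(ramp_crossing_at(8.0)))
        assert rec.fate == "CDK2emerge"
        assert rec.commit_time > 4.0

    def test_short_followup_unclassifiable(self):
        rec = classify_fate(aligned_trace(ramp_crossing_at(2.0), followup=6.0))
        assert rec.fate == "unclassifiable"

    def test_zd_inc_fraction_near_planted(self):
        """Default ZD ensemble at n=2000: classified CDK2inc within the
        binomial 95% CI of the planted 9%."""
        ens, _ = generate_trace_ensemble(SyntheticConfig(seed=1), "ZD", 2000)
        frac = fate_fractions(classify_ensemble(ens))
        lo, hi = binom.interval(0.95, 2000, 0.09)
        assert lo / 2000 <= frac["CDK2inc"] <= hi / 2000

    def test_time_shift_invariance(self):
        tr = aligned_trace(ramp_crossing_at(2.0))
        shifted = CellTrace(cell_id=0, t=tr.t + 30.0, ratio=tr.ratio,
                            division_times=[30.0])
        aligned, _ = align_to_mitosis(TraceEnsemble([shifted]))
        assert classify_fate(aligned[0]).fate == classify_fate(tr).fate

    def test_threshold_monotonicity(self):
        """Raising the commit threshold never increases the CDK2inc count."""
        ens, _ = generate_trace_ensemble(SyntheticConfig(seed=5), "MM", 300)
        incs = []
        for thr in (0.8, 1.0, 1.2, 1.4):
            recs = classify_ensemble(ens, ClassifierConfig(commit_threshold=thr))
            incs.append((recs["fate"] == "CDK2inc").sum())
        assert all(a >= b for a, b in zip(incs, incs[1:]))

    def test_fractions_partition(self):
        ens, _ = generate_trace_ensemble(SyntheticConfig(seed=2), "MM", 400)
        frac = fate_fractions(classify_ensemble(ens))
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)


class TestDetectStall:
    def test_plateau_stall_detected(self):
        """Rise to 1.2 held 12 h with no division: stalled with plateau
        estimate near 1.2."""
        tr = aligned_trace(
            lambda t: np.clip(1.0 + 0.35 * (t - 1.0), 0.5, 1.2), followup=16.0
        )
        stalled, plateau = detect_stall(tr)
        assert stalled
        assert plateau == pytest.approx(1.2, abs=0.05)

    def test_full_activation_then_division_not_stalled(self):
        tr = aligned_trace(ramp_crossing_at(2.0), followup=16.0,
                           divisions_after=[14.0])
        stalled, plateau = detect_stall(tr)
        assert not stalled

    def test_transient_plateau_not_stalled(self):
        def shape(t):
            r = np.full_like(t, 0.5)
            r[(t > 1.0) & (t <= 5.0)] = 1.2  # only 4 h at the plateau
            return r

        tr = aligned_trace(shape, followup=20.0)
        stalled, _ = detect_stall(tr)
        assert not stalled


class TestWindowBinning:
    def test_boundary_mitosis_joins_post_window(self):
        tr = aligned_trace(ramp_crossing_at(2.0))
        shifted = CellTrace(cell_id=0, t=tr.t + 8.0, ratio=tr.ratio,
                            division_times=[8.0])
        groups, _ = bin_by_mitosis_window(TraceEnsemble([shifted]), t_perturb=8.0)
        assert [r.cell_id for r in groups["[0,4)"]] == [0]

    def test_out_of_range_counted(self):
        tr = aligned_trace(ramp_crossing_at(2.0))
        late = CellTrace(cell_id=1, t=tr.t + 40.0, ratio=tr.ratio,
                         division_times=[40.0])
        groups, excluded = bin_by_mitosis_window(TraceEnsemble([late]), t_perturb=8.0)
        assert excluded == 1
        assert all(not v for v in groups.values())

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            bin_by_mitosis_window(TraceEnsemble([]), t_perturb=8.0, window=0.0)

    def test_schedule_recovery(self):
        """Schedule-conditioned ensemble: pre-perturbation quiescence ~15%
        and first-window CDK2inc ~43% within binomial CIs."""
        cfg = SyntheticConfig(seed=3, perturbation_time=8.0)
        ens, _ = generate_trace_ensemble(cfg, "schedule", 1500)
        groups, _ = bin_by_mitosis_window(ens, t_perturb=8.0)
        pre = groups["[-4,0)"]
        post = groups["[0,4)"]
        low_frac = sum(r.fate == "CDK2low" for r in pre) / len(pre)
        inc_frac = sum(r.fate == "CDK2inc" for r in post) / len(post)
        lo, hi = binom.interval(0.95, len(pre), 0.15)
        assert lo / len(pre) <= low_frac <= hi / len(pre)
        lo, hi = binom.interval(0.95, len(post), 0.43)
        assert lo / len(post) <= inc_frac <= hi / len(post)


class TestIntermitoticTimes:
    def test_single_pair(self):
        tr = trace_from(np.ones(300), divisions=[10.0, 23.0])
        durations, mode = intermitotic_times(TraceEnsemble([tr]))
        assert durations.tolist() == [13.0]
        assert mode == pytest.approx(13.5)

    def test_no_linked_divisions(self):
        tr = trace_from(np.ones(300), divisions=[10.0])
        durations, mode = intermitotic_times(TraceEnsemble([tr]))
        assert durations.size == 0
        assert mode is None

    def test_mode_recovers_cycle_length(self):
        """MM ensemble with 13-h mode cycle lengths: histogram mode 13 +/- 1 h."""
        ens, _ = generate_trace_ensemble(SyntheticConfig(seed=6), "MM", 450)
        durations, mode = intermitotic_times(ens)
        assert durations.size >= 1000
        assert abs(mode - 13.0) <= 1.0


class TestHeatmapAndDensity:
    def test_end_activity_order(self):
        hi = trace_from(np.full(100, 1.3), cell_id=1)
        lo = trace_from(np.full(100, 0.5), cell_id=2)
        matrix, order = sort_heatmap(TraceEnsemble([hi, lo]), "end_activity")
        assert order == [2, 1]
        assert matrix[0, 0] == 0.5

    def test_mitosis_time_order(self):
        a = trace_from(np.ones(100), divisions=[9.0], cell_id=1)
        b = trace_from(np.ones(100), divisions=[2.0], cell_id=2)
        _, order = sort_heatmap(TraceEnsemble([a, b]), "mitosis_time")
        assert order == [2, 1]

    def test_permutation_invariance(self):
        traces = [trace_from(np.full(100, v), cell_id=i)
                  for i, v in enumerate((0.9, 0.4, 1.5))]
        _, order_a = sort_heatmap(TraceEnsemble(traces))
        _, order_b = sort_heatmap(TraceEnsemble(traces[::-1]))
        assert order_a == order_b

    def test_density_integrates_to_one(self):
        ens, _ = generate_trace_ensemble(SyntheticConfig(seed=4), "ZD", 100)
        hist, edges = cdk2_density(ens, at=30.0)
        assert float(np.sum(hist * np.diff(edges))) == pytest.approx(1.0, abs=1e-9)

    def test_single_value_density(self):
        tr = trace_from(np.full(100, 0.5))
        hist, edges = cdk2_density(TraceEnsemble([tr]), at=5.0)
        assert float(np.sum(hist * np.diff(edges))) == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(hist) == 1

    def test_bimodal_modes_recovered(self):
        """Mixture of quiescent (0.5) and stalled (1.25) ratios shows two
        density modes at the planted locations within one bin."""
        rng = np.random.default_rng(0)
        traces = []
        for i in range(200):
            center = 0.5 if i < 120 else 1.25
            traces.append(
                trace_from(rng.normal(center, 0.04, 100), cell_id=i)
            )
        edges = np.arange(0.0, 2.0, 0.1)
        hist, edges = cdk2_density(TraceEnsemble(traces), at=5.0, bins=edges)
        # local maxima of the binned density
        peaks = [
            i for i in range(1, hist.size - 1)
            if hist[i] >= hist[i - 1] and hist[i] >= hist[i + 1] and hist[i] > 0.2
        ]
        centers = (edges[:-1] + edges[1:]) / 2
        assert any(abs(centers[i] - 0.5) <= 0.1 for i in peaks)
        assert any(abs(centers[i] - 1.25) <= 0.1 for i in peaks)

    def test_empty_slice_rejected(self):
        tr = trace_from(np.ones(10))
        with pytest.raises(ValueError, match="alive"):
            cdk2_density(TraceEnsemble([tr]), at=100.0)
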