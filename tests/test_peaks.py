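"""Peak calling: fold track, run detection, Poisson test, BH FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipenrich.coverage import CoverageTrack, ReadInterval, group_by_reference
from clipenrich.params import PipelineParams
from clipenrich.peaks import (
    bh_adjust,
    call_peaks,
    candidate_runs,
    ko_fold_track,
    peak_statistics,
    poisson_upper_p,
    significant_peaks,
)
from clipenrich.scenarios import PEAK_FOOTPRINT, transcriptome_peak_scenario
from clipenrich.simulate import simulate_transcriptome_experiment

PARAMS = PipelineParams()


def _rpm(values):
    return CoverageTrack("tx", np.asarray(values, float), 1_000_000, units="rpm")


class TestKoFoldTrack:
    def test_equal_tracks_halved_by_pseudocount(self):
        fold = ko_fold_track(_rpm(np.full(10, 5.0)), _rpm(np.full(10, 5.0)), global_pc=5.0)
        assert fold.tolist() == [0.5] * 10

    def test_zero_knockout(self):
        fold = ko_fold_track(_rpm(np.full(10, 10.0)), _rpm(np.zeros(10)), global_pc=5.0)
        assert fold.tolist() == [2.0] * 10

    def test_zero_ip_unmasked(self):
        fold = ko_fold_track(_rpm(np.zeros(10)), _rpm(np.ones(10)), global_pc=5.0)
        assert fold.tolist() == [0.0] * 10

    def test_low_signal_positions_forced_to_one(self):
        ip = np.full(100, 1.0)
        ip[:3] = 0.9  # together just under 3% of the cumulative signal
        fold = ko_fold_track(_rpm(ip), _rpm(np.zeros(100)), 5.0, low_signal_fraction=0.03)
        assert fold[:3].tolist() == [1.0, 1.0, 1.0]
        assert fold[3] == pytest.approx(0.2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            ko_fold_track(_rpm(np.ones(3)), _rpm(np.ones(4)), 5.0)


class TestCandidateRuns:
    def test_single_qualifying_run(self):
        fold = np.ones(100)
        fold[40:65] = 3.0  # 25 positions
        rpm = np.full(100, 20.0)
        assert candidate_runs(fold, rpm, PARAMS) == [(40, 65)]

    def test_exactly_20_positions_rejected(self):
        fold = np.ones(100)
        fold[40:60] = 3.0  # exactly 20: "more than 20" is strict
        assert candidate_runs(fold, np.full(100, 20.0), PARAMS) == []

    def test_fold_exactly_two_rejected(self):
        fold = np.full(100, 2.0)  # "more than twofold" is strict
        assert candidate_runs(fold, np.full(100, 20.0), PARAMS) == []

    def test_mean_rpm_threshold_strict(self):
        fold = np.ones(100)
        fold[10:50] = 3.0
        assert candidate_runs(fold, np.full(100, 10.0), PARAMS) == []
        assert candidate_runs(fold, np.full(100, 10.01), PARAMS) == [(10, 50)]

    def test_run_at_track_edge(self):
        fold = np.ones(50)
        fold[25:] = 2.5
        assert candidate_runs(fold, np.full(50, 20.0), PARAMS) == [(25, 50)]


def _brute_poisson_tail(observed: int, lam: float) -> float:
    """Independent oracle: sum the pmf from observed upward."""
    if observed == 0:
        return 1.0
    # sum lower tail in extended precision, subtract from 1
    import math

    total = 0.0
    log_pmf = -lam  # log pmf at k = 0
    for k in range(observed):
        total += math.exp(log_pmf)
        log_pmf += math.log(lam) - math.log(k + 1)
    return max(0.0, 1.0 - total)


class TestPoisson:
    def test_observed_zero_is_total_mass(self):
        assert poisson_upper_p(0, 0.5) == 1.0
        assert poisson_upper_p(0, 50) == 1.0

    def test_hand_values(self):
        assert poisson_upper_p(5, 1.0) == pytest.approx(0.003660, abs=5e-7)
        assert poisson_upper_p(2, 2.0) == pytest.approx(0.593994, abs=5e-7)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 2.0, 10.0])
    def test_matches_brute_force(self, lam):
        for observed in range(0, 40, 3):
            assert poisson_upper_p(observed, lam) == pytest.approx(
                _brute_poisson_tail(observed, lam), abs=1e-10
            )

    def test_invalid_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            poisson_upper_p(3, 0.0)


def _bh_oracle(pvalues):
    """Loop-based step-up: q_(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    best = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        best = min(best, pvalues[idx] * (n / rank))
        q[idx] = best
    return q


class TestBH:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.04]).tolist() == pytest.approx([0.03, 0.03, 0.04])

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]).tolist() == [0.2, 0.2, 0.2]

    def test_single_p(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])

    def test_matches_loop_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 50)))
            assert bh_adjust(p).tolist() == _bh_oracle(list(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(200)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_in_sorted_order_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        q = bh_adjust(p)
        assert (q <= 1.0).all() and (q >= p).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPeakStatistics:
    def test_no_reads(self):
        observed, lam = peak_statistics((10, 40), [], [], 1000, 1000, 5.0)
        assert observed == 0
        assert lam == 5.0
        assert poisson_upper_p(observed, lam) == 1.0

    def test_counts_and_lambda(self):
        ip = [ReadInterval("tx", 10, 20)] * 30
        ko = [ReadInterval("tx", 12, 22)] * 5
        observed, lam = peak_statistics((10, 40), ip, ko, 1000, 1000, 5.0)
        assert observed == 30
        assert lam == 10.0
        assert poisson_upper_p(observed, lam) == pytest.approx(
            _brute_poisson_tail(30, 10.0), abs=1e-10
        )

    def test_library_ratio_invariance(self):
        ip = [ReadInterval("tx", 10, 20)] * 7
        ko = [ReadInterval("tx", 10, 20)] * 3
        _, lam1 = peak_statistics((5, 30), ip, ko, 1000, 2000, 5.0)
        _, lam2 = peak_statistics((5, 30), ip, ko, 2000, 4000, 5.0)
        assert lam1 == lam2

    def test_overlap_is_half_open(self):
        ip = [ReadInterval("tx", 0, 10), ReadInterval("tx", 40, 50)]
        observed, _ = peak_statistics((10, 40), ip, [], 1000, 1000, 5.0)
        assert observed == 0  # touching endpoints do not overlap

    def test_zero_ko_library_rejected(self):
        with pytest.raises(ValueError, match="knockout library"):
            peak_statistics((0, 10), [], [], 1000, 0, 5.0)


def _planted_run(seed):
    cfg, kw = transcriptome_peak_scenario(seed)
    ann, reads, _ = simulate_transcriptome_experiment(cfg, **kw)
    peaks = call_peaks(
        reads["ip"], reads["ko"], cfg.library_sizes["ip"], cfg.library_sizes["ko"], ann
    )
    return ann, peaks


class TestCallPeaks:
    def test_planted_footprint_recovered(self):
        """A fourfold, 40-nt CDS footprint yields exactly one significant
        peak overlapping the truth interval with Jaccard >= 0.6."""
        ann, peaks = _planted_run(0)
        sig = significant_peaks(peaks, 0.05)
        assert len(sig) == 1
        row = sig.iloc[0]
        u5 = int(ann.iloc[0]["len_5utr"])
        truth = (u5 + PEAK_FOOTPRINT.start, u5 + PEAK_FOOTPRINT.end)  # 1-based
        inter = max(0, min(row["end_1based"], truth[1]) - max(row["start_1based"], truth[0]) + 1)
        union = (row["end_1based"] - row["start_1based"] + 1) + (truth[1] - truth[0] + 1) - inter
        assert inter / union >= 0.6

    def test_reported_peaks_satisfy_invariants(self):
        _, peaks = _planted_run(1)
        assert len(peaks) > 0
        assert (peaks["length"] >= PARAMS.peak_min_run).all()
        assert (peaks["mean_fold"] > PARAMS.peak_min_fold).all()
        assert (peaks["mean_rpm"] > PARAMS.peak_min_rpm).all()
        assert ((peaks["p"] >= 0) & (peaks["p"] <= 1)).all()
        assert (peaks["q"] >= peaks["p"]).all()

    def test_non_canonical_decoy_contributes_no_peaks(self):
        cfg, kw = transcriptome_peak_scenario(2)
        ann, reads, _ = simulate_transcriptome_experiment(cfg, n_decoys=2, **kw)
        decoys = set(ann.loc[ann["canonical"] == 0, "transcript_id"])
        # plant IP reads directly on a decoy: still no peaks from it
        decoy = sorted(decoys)[0]
        ip = group_by_reference(reads["ip"])
        ip[decoy] = [ReadInterval(decoy, 50, 60)] * 500
        peaks = call_peaks(ip, reads["ko"], 20_000, 20_000, ann)
        assert not set(peaks["locus"]) & decoys

    def test_shift_equivariance(self):
        """Translating all reads by +k translates every peak by +k."""
        cfg, kw = transcriptome_peak_scenario(3)
        ann, reads, _ = simulate_transcriptome_experiment(cfg, **kw)
        k = 30
        ann_long = ann.copy()
        ann_long["len_3utr"] += k  # room to shift within bounds
        def shift(rs):
            return [ReadInterval(r.reference, r.start + k, r.end + k) for r in rs]
        base = call_peaks(reads["ip"], reads["ko"], 20_000, 20_000, ann_long)
        moved = call_peaks(shift(reads["ip"]), shift(reads["ko"]), 20_000, 20_000, ann_long)
        assert len(base) == len(moved) > 0
        assert (moved["start_1based"].to_numpy() == base["start_1based"].to_numpy() + k).all()
        assert (moved["end_1based"].to_numpy() == base["end_1based"].to_numpy() + k).all()
        assert np.allclose(moved["p"].to_numpy(), base["p"].to_numpy())

    def test_missing_knockout_rejected(self):
        cfg, kw = transcriptome_peak_scenario(4)
        ann, reads, _ = simulate_transcriptome_experiment(cfg, **kw)
        with pytest.raises(ValueError, match="knockout"):
            call_peaks(reads["ip"], {}, 20_000, 0, ann)

    def test_coverage_count_mode_runs(self):
        cfg, kw = transcriptome_peak_scenario(5)
        ann, reads, _ = simulate_transcriptome_experiment(cfg, **kw)
        peaks = call_peaks(
            reads["ip"], reads["ko"], 20_000, 20_000, ann, count_mode="coverage"
        )
        assert len(significant_peaks(peaks, 0.05)) >= 1

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(
        fold=st.floats(1.0, 6.0),
        width=st.integers(5, 80),
        seed=st.integers(0, 10_000),
    )
    def test_invariants_on_random_plantings(self, fold, width, seed):
        """Whatever is planted, every reported peak obeys the strict
        fold / RPM / length thresholds."""
        from clipenrich.simulate import Footprint, SampleSpec, SimulationConfig

        cfg = SimulationConfig(
            library_sizes={"ip": 4000, "ko": 4000},
            read_length=10,
            seed=seed,
            samples=[SampleSpec("ip", "ip", "treated"), SampleSpec("ko", "knockout", "treated")],
        )
        ann, reads, _ = simulate_transcriptome_experiment(
            cfg,
            1,
            lambda rng: (80, 400, 120),
            cds_footprint=Footprint(50, 50 + width - 1, fold, frozenset({"treated"})),
        )
        peaks = call_peaks(reads["ip"], reads["ko"], 4000, 4000, ann)
        if len(peaks):
            assert (peaks["length"] >= 21).all()
            assert (peaks["mean_fold"] > 2.0).all()
            assert (peaks["mean_rpm"] > 10.0).all()
            assert (peaks["q"] >= peaks["p"]).all()
            assert (peaks["q"] <= 1.0).all()
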