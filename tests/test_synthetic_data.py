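"""Generator invariants: determinism, geometry, truth sampling, moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chicaudit.core_model import DistanceBinning, enumerate_cis_pairs, _attach_counts
from chicaudit.synthetic_data import (
    TruthSet,
    apply_perturbations,
    default_null_model,
    generate_fragment_map,
    sample_truth,
    simulate_counts,
)
from chicaudit.core_model import WeightCurve


class TestFragmentMap:
    def test_determinism_and_contiguity(self):
        a = generate_fragment_map(100, 4000, 0.1, seed=7)
        b = generate_fragment_map(100, 4000, 0.1, seed=7)
        pd.testing.assert_frame_equal(a.fragments, b.fragments)
        assert a.bait_ids == b.bait_ids
        assert a.n_fragments == 100 and a.n_baits == 10
        frag = a.fragments
        assert (frag["start"].to_numpy()[1:] == frag["end"].to_numpy()[:-1] + 1).all()

    def test_total_span_tracks_mean_length(self):
        fmap = generate_fragment_map(400, 4000, 0.1, seed=1)
        span = fmap.fragments["end"].max()
        assert abs(span - 400 * 4000) / (400 * 4000) < 0.2

    def test_zero_baits_errors(self):
        with pytest.raises(ValueError, match="0 baits"):
            generate_fragment_map(50, 4000, 0.001, seed=0)

    def test_decoy_chromosome_is_unbaited(self):
        fmap = generate_fragment_map(50, 4000, 0.2, seed=0, n_decoy_fragments=20)
        decoy_ids = set(
            fmap.fragments.loc[fmap.fragments["chrom"] == "chrD", "id"]
        )
        assert not decoy_ids & set(fmap.bait_ids)


class TestTruthSampling:
    def test_null_prior_gives_empty_truth(self, small_fmap):
        truth = sample_truth(small_fmap, prior_params=(0.0, 0.0, 12, 2), seed=1)
        assert truth.true_pairs == {}

    def test_saturated_prior_marks_every_pair(self):
        fmap = generate_fragment_map(12, 4000, 1 / 12, seed=4)
        truth = sample_truth(fmap, prior_params=(1.0, 1.0, 12, 2), seed=4)
        n_pairs = len(enumerate_cis_pairs(fmap, 1.5e6))
        assert len(truth.true_pairs) == n_pairs

    def test_multiplier_must_exceed_one(self):
        with pytest.raises(ValueError, match="exceed 1"):
            TruthSet(true_pairs={(1, 2): 1.0},
                     prior_curve=WeightCurve(params=(0, 0.3, 12, 2)))

    def test_per_bin_truth_fraction_tracks_prior(self):
        fmap = generate_fragment_map(500, 4000, 0.1, seed=3)
        params = (0.01, 0.4, 12.0, 2.0)
        truth = sample_truth(fmap, prior_params=params, seed=3)
        prior = WeightCurve(params=params)
        pairs = enumerate_cis_pairs(fmap, 1.5e6)
        binning = DistanceBinning(width_bp=300_000, upper_bp=1_500_000)
        idx = binning.bin_index(pairs["distance_bp"].to_numpy())
        hit = np.array(
            [(int(b), int(o)) in truth.true_pairs
             for b, o in zip(pairs["bait_id"], pairs["other_id"])]
        )
        for b in range(binning.n_bins):
            sel = idx == b
            n = int(sel.sum())
            if n < 50:
                continue
            k = int(hit[sel].sum())
            p_bin = prior.weight(pairs["distance_bp"].to_numpy()[sel]).mean()
            lo, hi = stats.binom.interval(0.999, n, p_bin)
            assert lo <= k <= hi


class TestSimulatedCounts:
    def test_same_seed_identical_tables(self, small_fmap, truth_model, empty_truth):
        t1 = simulate_counts(small_fmap, truth_model, empty_truth, 2, seed=5)
        t2 = simulate_counts(small_fmap, truth_model, empty_truth, 2, seed=5)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.records, b.records)

    def test_replicates_share_truth_but_not_noise(self, small_fmap, truth_model,
                                                  spiked_truth):
        t = simulate_counts(small_fmap, truth_model, spiked_truth, 2, seed=5)
        assert not t[0].records.equals(t[1].records)

    def test_per_bin_mean_matches_distance_function(self):
        # unit biases, no noise, no truth: E[count] = f(d)
        fmap = generate_fragment_map(800, 4000, 0.15, seed=9)
        model = default_null_model(
            fmap, seed=9, bait_bias_sd=0.0, other_end_bias_sd=0.0,
            lambda_range=(0.0, 0.0),
        )
        truth = sample_truth(fmap, prior_params=(0, 0, 12, 2), seed=9)
        (table,) = simulate_counts(fmap, model, truth, 1, seed=9)
        binning = DistanceBinning(width_bp=300_000, upper_bp=1_500_000)
        pairs = _attach_counts(enumerate_cis_pairs(fmap, binning.upper_bp), table)
        idx = binning.bin_index(pairs["distance_bp"].to_numpy())
        for b in range(binning.n_bins):
            sel = idx == b
            if sel.sum() < 10_000:
                continue
            mean_obs = pairs.loc[sel, "count"].mean()
            mean_exp = model.distance_fit.f(
                pairs.loc[sel, "distance_bp"].to_numpy()
            ).mean()
            assert mean_obs == pytest.approx(mean_exp, rel=0.05)

    def test_variance_mean_relation(self):
        # NB identity: Var/mean = 1 + mean/r
        fmap = generate_fragment_map(800, 4000, 0.15, seed=10)
        model = default_null_model(
            fmap, seed=10, bait_bias_sd=0.0, other_end_bias_sd=0.0,
            lambda_range=(0.0, 0.0), dispersion_r=2.0,
        )
        truth = sample_truth(fmap, prior_params=(0, 0, 12, 2), seed=10)
        (table,) = simulate_counts(fmap, model, truth, 1, seed=10)
        pairs = _attach_counts(enumerate_cis_pairs(fmap, 1.5e6), table)
        d = pairs["distance_bp"].to_numpy()
        sel = (d > 20_000) & (d <= 100_000)
        counts = pairs.loc[sel, "count"].to_numpy()
        mu = model.distance_fit.f(d[sel])  # unit biases, no spikes
        # law of total variance: Var = E[mu + mu^2/r] + Var(mu)
        mean = counts.mean()
        ratio_obs = counts.var() / mean
        ratio_exp = (mu.mean() + (mu**2).mean() / 2.0 + mu.var()) / mu.mean()
        assert ratio_obs == pytest.approx(ratio_exp, rel=0.10)


class TestPerturbations:
    def test_identity_perturbation(self, small_fmap, truth_model, null_tables):
        out = apply_perturbations(
            small_fmap, null_tables[0],
            cnv_regions=[(("chrS", 1, 10_000_000), 1.0)],
        )
        pd.testing.assert_frame_equal(out.records, null_tables[0].records)

    def test_overlapping_cnv_regions_error(self, small_fmap, null_tables):
        with pytest.raises(ValueError, match="overlap"):
            apply_perturbations(
                small_fmap, null_tables[0],
                cnv_regions=[(("chrS", 1, 100_000), 2.0),
                             (("chrS", 50_000, 200_000), 0.5)],
            )

    def test_cnv_amplification_doubles_affected_counts(self, small_fmap,
                                                       truth_model, empty_truth):
        region = ("chrS", 1, 400_000)
        base, pert = [], []
        for seed in range(8):
            (table,) = simulate_counts(small_fmap, truth_model, empty_truth, 1,
                                       seed=100 + seed)
            out = apply_perturbations(small_fmap, table,
                                      cnv_regions=[(region, 2.0)], seed=seed)
            mid_b = small_fmap.midpoint(table.records["bait_id"].to_numpy())
            mid_o = small_fmap.midpoint(table.records["other_id"].to_numpy())
            chrom = small_fmap.chrom(table.records["bait_id"].to_numpy())
            hit = (chrom == "chrS") & (
                ((mid_b >= 1) & (mid_b <= 400_000))
                | ((mid_o >= 1) & (mid_o <= 400_000))
            )
            base.append(table.records.loc[hit, "count"].sum())
            key = set(
                zip(table.records.loc[hit, "bait_id"],
                    table.records.loc[hit, "other_id"])
            )
            sel = [
                (b, o) in key
                for b, o in zip(out.records["bait_id"], out.records["other_id"])
            ]
            pert.append(out.records.loc[sel, "count"].sum())
        assert np.sum(pert) / np.sum(base) == pytest.approx(2.0, rel=0.10)

    def test_breakpoint_raises_counts_to_short_range_level(self, small_fmap,
                                                           truth_model,
                                                           empty_truth):
        # fuse loci ~750 kb apart; spanning pairs should jump toward f(10 kb)
        (table,) = simulate_counts(small_fmap, truth_model, empty_truth, 1, seed=42)
        bp = ("chrS", 150_000, 900_000)
        out = apply_perturbations(small_fmap, table, breakpoint=bp,
                                  model=truth_model, seed=1)
        pairs = _attach_counts(enumerate_cis_pairs(small_fmap, 1.5e6), out)
        mid_b = small_fmap.midpoint(pairs["bait_id"].to_numpy())
        mid_o = small_fmap.midpoint(pairs["other_id"].to_numpy())
        lo = np.minimum(mid_b, mid_o)
        hi = np.maximum(mid_b, mid_o)
        spanning = (lo <= bp[1]) & (hi >= bp[2]) & (
            small_fmap.chrom(pairs["bait_id"].to_numpy()) == "chrS"
        )
        assert spanning.sum() > 20
        mean_obs = pairs.loc[spanning, "count"].mean()
        d_eff = pairs.loc[spanning, "distance_bp"].to_numpy() - (bp[2] - bp[1])
        # biases average ~1; compare against the null mean at the fused distance
        mean_exp = truth_model.distance_fit.f(np.maximum(d_eff, 1.0e4)).mean()
        far_mean = truth_model.distance_fit.f(
            pairs.loc[spanning, "distance_bp"].to_numpy()
        ).mean()
        assert mean_obs > 4 * far_mean
        assert mean_obs == pytest.approx(mean_exp, rel=0.5)
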