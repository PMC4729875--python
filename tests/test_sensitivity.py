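"""Sensitivity model: subsampling, FN arithmetic, rate estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrocall import sensitivity as sens
from retrocall.simulate import (FamilySpec, SimConfig, plant_insertion,
                                select_integration_site, simulate_library)


def call_row(call_id, pos, family="L1", chrom="chr1", sample="S1"):
    return {"call_id": call_id, "sample": sample, "chrom": chrom,
            "position": pos, "family": family}


class TestGermlineConcordance:
    def test_identical_sets_give_one(self):
        early = pd.DataFrame([call_row("a", 100), call_row("b", 900, "Alu")])
        out = sens.germline_concordance(early, early)
        assert out == {"L1": 1.0, "Alu": 1.0}

    def test_one_of_ten_missing(self):
        early = pd.DataFrame([call_row(f"e{i}", 1000 * i) for i in range(10)])
        late = pd.DataFrame([call_row(f"l{i}", 1000 * i) for i in range(9)])
        out = sens.germline_concordance(early, late)
        assert out["L1"] == pytest.approx(0.9)

    def test_family_with_no_early_calls_is_missing_not_zero(self):
        early = pd.DataFrame([call_row("a", 100)])
        late = pd.DataFrame([call_row("b", 100, "Alu")])
        out = sens.germline_concordance(early, late)
        assert "Alu" not in out

    def test_matches_bruteforce_pairwise_oracle(self, rng):
        window = 100
        early = pd.DataFrame([call_row(f"e{i}", int(p),
                                       family=("L1" if i % 2 else "Alu"))
                              for i, p in enumerate(rng.integers(0, 5000, 40))])
        late = pd.DataFrame([call_row(f"l{i}", int(p),
                                      family=("L1" if i % 3 else "Alu"))
                             for i, p in enumerate(rng.integers(0, 5000, 40))])
        out = sens.germline_concordance(early, late, match_window=window)
        for family in ("L1", "Alu"):
            esub = early[early["family"] == family]
            lsub = late[late["family"] == family]
            matched = sum(
                any(e["chrom"] == l["chrom"]
                    and abs(e["position"] - l["position"]) <= window
                    for _, l in lsub.iterrows())
                for _, e in esub.iterrows())
            assert out[family] == pytest.approx(matched / len(esub))


def simulate_one_sample(genome, library, rng, n=30, depth=12, vaf=1.0,
                        duplicate_rate=0.0):
    cfg = SimConfig(depth=depth, duplicate_rate=duplicate_rate, seed=1)
    spec = FamilySpec("L1", "L1-Ta")
    truths, used = [], []
    for i in range(n):
        while True:
            site = select_integration_site(genome, True, 1, rng)
            if all(c != site.chrom or abs(site.position - q) > 700
                   for c, q in used):
                used.append((site.chrom, site.position))
                break
        t, _ = plant_insertion(genome, spec, site, rng, library, vaf=vaf,
                               ins_id=f"g{i}", is_germline=True,
                               emit_haplotype=False)
        truths.append(t)
    reads = simulate_library(genome, truths, cfg, rng, "S1", library)
    targets = pd.DataFrame([{"id": t.id, "family": t.family, "chrom": t.chrom,
                             "position": t.position} for t in truths])
    return reads, targets


class TestSubsampling:
    def test_extreme_depths(self, genome, library, rng):
        reads, targets = simulate_one_sample(genome, library, rng, n=15)
        curve = sens.subsample_detection(reads, targets,
                                         grid=np.array([0.0, 1.0]), reps=3,
                                         rng=rng)
        assert curve.mean["L1"].iloc[0] == 0.0   # nothing sampled
        assert curve.mean["L1"].iloc[1] == 1.0   # full library, depth 12 >> 2

    def test_mean_curve_is_monotone_in_depth(self, genome, library, rng):
        reads, targets = simulate_one_sample(genome, library, rng, n=20, depth=6)
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
        curve = sens.subsample_detection(reads, targets, grid=grid, reps=10,
                                         rng=rng)
        assert (np.diff(curve.mean["L1"].to_numpy()) >= 0).all()

    def test_reps_below_one_errors(self, genome, library, rng):
        reads, targets = simulate_one_sample(genome, library, rng, n=3)
        with pytest.raises(ValueError):
            sens.subsample_detection(reads, targets, grid=np.array([0.5]),
                                     reps=0, rng=rng)

    def test_matches_closed_form_binomial_oracle(self, genome, library, rng):
        # P(detect at depth s | k uniques) = 1 - (1-s)^k - k s (1-s)^(k-1)
        reads, targets = simulate_one_sample(genome, library, rng, n=40,
                                             depth=8)
        grid = np.array([0.1, 0.3, 0.5, 0.8])
        curves = sens.insertion_detection_curves(reads, targets, grid,
                                                 reps=10, rng=rng)
        k = reads.groupby("truth_id")["start"].apply(
            lambda s: len(set(s)))  # uniques per insertion (both junctions)
        for s in grid:
            closed = np.array([1 - (1 - s) ** ki - ki * s * (1 - s) ** (ki - 1)
                               for ki in k[targets["id"]].to_numpy()])
            observed = curves.loc[s].to_numpy()
            pooled_mc_sd = np.sqrt(np.mean(closed * (1 - closed))
                                   / (10 * len(targets)))
            assert abs(observed.mean() - closed.mean()) < 4 * pooled_mc_sd + 0.01


class TestFNArithmetic:
    def test_printed_inputs_reproduce_overall_fn(self):
        fn = sens.weighted_fn(sens.FAMILY_WEIGHTS_HIPSC,
                              sens.BASELINE_DETECTION_HIPSC)
        assert round(100 * fn, 1) == 7.9

    def test_constant_detection_reduces_to_complement(self):
        for r in (0.0, 0.37, 1.0):
            fn = sens.weighted_fn({"L1": 3, "Alu": 11},
                                  {"L1": r, "Alu": r})
            assert fn == pytest.approx(1 - r)

    def test_single_nonzero_weight(self):
        fn = sens.weighted_fn({"L1": 5, "Alu": 0}, {"L1": 0.8, "Alu": 0.1})
        assert fn == pytest.approx(0.2)

    def test_zero_total_weight_errors(self):
        with pytest.raises(ValueError):
            sens.weighted_fn({"L1": 0.0}, {"L1": 0.5})

    @settings(derandomize=True, max_examples=100)
    @given(scale=st.floats(0.01, 100),
           d1=st.floats(0, 1), d2=st.floats(0, 1),
           w1=st.floats(0.1, 50), w2=st.floats(0.1, 50))
    def test_invariant_to_weight_rescaling(self, scale, d1, d2, w1, w2):
        base = sens.weighted_fn({"a": w1, "b": w2}, {"a": d1, "b": d2})
        scaled = sens.weighted_fn({"a": w1 * scale, "b": w2 * scale},
                                  {"a": d1, "b": d2})
        assert scaled == pytest.approx(base)

    def test_vaf_adjusted_fn_reproduces_printed_values(self):
        baseline = sens.weighted_fn(sens.FAMILY_WEIGHTS_HIPSC,
                                    sens.BASELINE_DETECTION_HIPSC)
        fn50 = sens.fn_at_vaf(sens.DETECTION_AT_50_HIPSC,
                              sens.FAMILY_WEIGHTS_HIPSC, baseline)
        fn5 = sens.fn_at_vaf(sens.DETECTION_AT_5_HIPSC,
                             sens.FAMILY_WEIGHTS_HIPSC, baseline)
        assert round(100 * fn50, 1) == 30.5
        assert round(100 * fn5, 1) == 94.4

    def test_full_detection_recovers_baseline(self):
        d = {f: 1.0 for f in sens.FAMILY_WEIGHTS_HIPSC}
        fn = sens.fn_at_vaf(d, sens.FAMILY_WEIGHTS_HIPSC, 0.079)
        assert fn == pytest.approx(0.079)

    def test_zero_baseline_constant_detection_closed_form(self):
        d = {f: 0.6 for f in sens.FAMILY_WEIGHTS_HIPSC}
        assert sens.fn_at_vaf(d, sens.FAMILY_WEIGHTS_HIPSC, 0.0) == pytest.approx(0.4)

    def test_out_of_range_detection_errors(self):
        with pytest.raises(ValueError):
            sens.fn_at_vaf({"L1": 1.2}, {"L1": 1.0}, 0.1)

    def test_false_positive_complement(self):
        assert 100 * sens.false_positive_rate(0.985) == pytest.approx(1.5)


def curves_frame(probabilities, grid=None):
    grid = np.array([0.05, 0.5, 1.0]) if grid is None else grid
    return pd.DataFrame({i: np.full(len(grid), p)
                         for i, p in probabilities.items()}, index=grid)


class TestRateEstimate:
    def test_perfect_detection_corrects_nothing(self):
        obs = pd.DataFrame({"id": ["a", "b", "c"], "vaf": [0.5, 0.5, 0.5]})
        est = sens.estimate_insertion_rate(obs, curves_frame({"a": 1, "b": 1, "c": 1}))
        assert est.corrected_per_line == pytest.approx(3.0)

    def test_half_detection_doubles(self):
        obs = pd.DataFrame({"id": ["a", "b", "c"], "vaf": [1.0, 1.0, 1.0]})
        est = sens.estimate_insertion_rate(
            obs, curves_frame({"a": 0.5, "b": 0.5, "c": 0.5}))
        assert est.corrected_per_line == pytest.approx(6.0)
        assert est.per_cell == pytest.approx(6.0)  # mean VAF 1

    def test_scale_consistency(self):
        obs = pd.DataFrame({"id": ["a", "b"], "vaf": [0.4, 0.6]})
        low = sens.estimate_insertion_rate(obs, curves_frame({"a": 0.25, "b": 0.4}))
        high = sens.estimate_insertion_rate(obs, curves_frame({"a": 0.5, "b": 0.8}))
        assert low.corrected_per_line == pytest.approx(2 * high.corrected_per_line)

    def test_zero_probability_excluded_with_warning(self):
        obs = pd.DataFrame({"id": ["a", "b"], "vaf": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            est = sens.estimate_insertion_rate(obs, curves_frame({"a": 0.0, "b": 1.0}))
        assert est.excluded == ["a"]
        assert est.corrected_per_line == pytest.approx(1.0)

    def test_baseline_normalization_inflates_correction(self):
        obs = pd.DataFrame({"id": ["a"], "vaf": [1.0]})
        est = sens.estimate_insertion_rate(obs, curves_frame({"a": 0.5}),
                                           baseline_fn=0.2)
        assert est.corrected_per_line == pytest.approx(1 / (0.5 * 0.8))

    def test_vaf_floor_restricts_grid(self):
        grid = np.array([0.01, 0.5, 1.0])
        curves = pd.DataFrame({"a": [0.0, 0.6, 1.0]}, index=grid)
        obs = pd.DataFrame({"id": ["a"], "vaf": [1.0]})
        est = sens.estimate_insertion_rate(obs, curves, vaf_floor=0.05)
        assert est.per_insertion_probability["a"] == pytest.approx(0.8)

    def test_corrected_never_below_observed(self):
        obs = pd.DataFrame({"id": list("abcd"), "vaf": [0.2, 0.4, 0.6, 1.0]})
        est = sens.estimate_insertion_rate(
            obs, curves_frame({"a": 0.9, "b": 0.8, "c": 1.0, "d": 0.95}))
        assert est.corrected_per_line >= est.observed
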