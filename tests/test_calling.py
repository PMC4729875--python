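"""Junction calling: duplicate collapse, clustering, reporting thresholds."""

import numpy as np
import pandas as pd
import pytest

from retrocall import calling
from retrocall.calling import (call_insertions, cluster_amplicons,
                               collapse_duplicates, match_catalog, run_caller)
from retrocall.consensus import ConsensusLibrary
from retrocall.simulate import FamilySpec, SimConfig, plant_insertion, \
    select_integration_site, simulate_library


def make_reads(starts, side="3p", family="L1", sample="S1", chrom="chr1",
               dups=None):
    rows = []
    for i, start in enumerate(starts):
        mult = 1 if dups is None else dups[i]
        for j in range(mult):
            rows.append({"read_id": f"r{i}_{j}", "sample": sample,
                         "chrom": chrom, "start": start, "end": start + 150,
                         "strand": "+", "side": side, "family": family,
                         "elem_offset": 0, "diag": "AAAAAAAA",
                         "dup_group": f"g{i}", "truth_id": "t"})
    return pd.DataFrame(rows)


class TestCollapse:
    def test_identical_reads_collapse_to_one(self):
        reads = make_reads([1000], dups=[10])
        uniques = collapse_duplicates(reads)
        assert len(uniques) == 1
        assert uniques.iloc[0]["multiplicity"] == 10

    def test_one_base_apart_stays_distinct(self):
        uniques = collapse_duplicates(make_reads([1000, 1001]))
        assert len(uniques) == 2

    def test_matches_bruteforce_distinct_keys(self, rng):
        reads = pd.concat([
            make_reads(rng.integers(0, 50, size=200).tolist(), side=s,
                       family=f, sample=smp)
            for s in ("5p", "3p") for f in ("L1", "Alu") for smp in ("A", "B")
        ], ignore_index=True)
        uniques = collapse_duplicates(reads)
        # nested-loop oracle over distinct (sample, chrom, start, side, family)
        keys = []
        for _, r in reads.iterrows():
            key = (r["sample"], r["chrom"], r["start"], r["side"], r["family"])
            if key not in keys:
                keys.append(key)
        assert len(uniques) == len(keys)
        assert int(uniques["multiplicity"].sum()) == len(reads)


class TestCluster:
    def test_far_apart_uniques_form_two_clusters(self):
        u = collapse_duplicates(make_reads([1000, 1400]))
        out = cluster_amplicons(u, window=200)
        assert out["cluster"].nunique() == 2

    def test_single_linkage_chains_through_gaps(self):
        u = collapse_duplicates(make_reads([1000, 1150, 1300]))
        out = cluster_amplicons(u, window=200)
        assert out["cluster"].nunique() == 1

    def test_negative_window_errors(self):
        u = collapse_duplicates(make_reads([1000]))
        with pytest.raises(ValueError):
            cluster_amplicons(u, window=-1)

    def test_matches_transitive_closure_oracle(self, rng):
        starts = rng.integers(0, 4000, size=120).tolist()
        u = collapse_duplicates(make_reads(starts))
        window = 150
        out = cluster_amplicons(u, window=window)
        # O(n^2) transitive closure over |start_i - start_j| <= window
        pts = u["start"].tolist()
        n = len(pts)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if abs(pts[i] - pts[j]) <= window:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(n):
            oracle.setdefault(find(i), set()).add(pts[i])
        got = {frozenset(g["start"]) for _, g in out.groupby("cluster")}
        assert got == {frozenset(s) for s in oracle.values()}


class TestThreshold:
    def test_separation_of_five_is_reported(self):
        u = cluster_amplicons(collapse_duplicates(make_reads([1000, 1005])), 200)
        assert len(call_insertions(u)) == 1

    def test_separation_of_four_is_not(self):
        u = cluster_amplicons(collapse_duplicates(make_reads([1000, 1004])), 200)
        assert len(call_insertions(u)) == 0

    def test_duplicates_never_count(self):
        u = cluster_amplicons(collapse_duplicates(make_reads([1000], dups=[50])), 200)
        assert len(call_insertions(u)) == 0

    def test_junction_is_max_multiplicity_start_ties_to_5prime(self):
        reads = make_reads([1000, 1010, 1020], dups=[3, 3, 1])
        u = cluster_amplicons(collapse_duplicates(reads), 200)
        calls = call_insertions(u)
        assert calls.iloc[0]["junction3"] == 1000


class TestFamilyAssignment:
    def test_equal_diagnostic_matches_is_unresolved(self):
        lib = ConsensusLibrary(
            families={"Alu": {"AluYa5": "C" + "A" * 99, "AluYb8": "C" + "A" * 99}},
            diagnostic_positions={"Alu": [10, 20]})
        members = make_reads([1000, 1010], family="Alu")
        members["diag"] = "GG"  # matches neither subfamily better
        members = collapse_duplicates(members)
        fam, sub = calling.assign_family_subfamily(members, lib)
        assert (fam, sub) == ("Alu", "unresolved")

    def test_unknown_family_errors(self, library):
        members = collapse_duplicates(make_reads([1000, 1010], family="HERV9"))
        with pytest.raises(ValueError):
            calling.assign_family_subfamily(members, library)

    def test_simulated_alu_yb8_subfamily_recovered(self, genome, library, rng):
        spec = FamilySpec("Alu", "AluYb8", full_length_fraction=1.0,
                          twin_priming_fraction=0.0,
                          untemplated_nt_probability=0.0)
        site = select_integration_site(genome, True, 1, rng)
        truth, _ = plant_insertion(genome, spec, site, rng, library,
                                   emit_haplotype=False)
        cfg = SimConfig(depth=20, duplicate_rate=0.0, seed=1)
        reads = simulate_library(genome, [truth], cfg, rng, "S1", library)
        calls = run_caller(reads, library=library)
        assert len(calls) == 1
        assert calls.iloc[0]["family"] == "Alu"
        assert calls.iloc[0]["subfamily"] == "AluYb8"


class TestCatalogMatch:
    def catalog(self, pos, family="L1"):
        return pd.DataFrame([{"chrom": "chr1", "start": pos, "end": pos + 1,
                              "name": family, "score": 0, "strand": "+"}])

    def calls_at(self, pos, family="L1"):
        return pd.DataFrame([{"call_id": "c1", "sample": "S1", "chrom": "chr1",
                              "family": family, "subfamily": "x",
                              "junction5": -1, "junction3": pos,
                              "position": pos, "n_unique": 3,
                              "max_separation": 10, "catalog_status": "novel"}])

    def test_exact_same_family_is_known(self):
        out = match_catalog(self.calls_at(5000), self.catalog(5000))
        assert out.iloc[0]["catalog_status"] == "known"

    def test_same_position_different_family_is_novel(self):
        out = match_catalog(self.calls_at(5000, "L1"), self.catalog(5000, "Alu"))
        assert out.iloc[0]["catalog_status"] == "novel"

    def test_window_boundary(self):
        known = match_catalog(self.calls_at(5100), self.catalog(5000),
                              match_window=100)
        novel = match_catalog(self.calls_at(5101), self.catalog(5000),
                              match_window=100)
        assert known.iloc[0]["catalog_status"] == "known"
        assert novel.iloc[0]["catalog_status"] == "novel"

    def test_malformed_record_skipped_with_warning(self, caplog):
        bad = pd.DataFrame([{"chrom": "chr1", "start": 900, "end": 100,
                             "name": "L1", "score": 0, "strand": "+"}])
        with caplog.at_level("WARNING"):
            out = match_catalog(self.calls_at(5000), bad)
        assert out.iloc[0]["catalog_status"] == "novel"
        assert any("malformed" in rec.message for rec in caplog.records)


class TestEndToEnd:
    def plant_many(self, genome, library, rng, n, vaf):
        truths, used = [], []
        spec = FamilySpec("L1", "L1-Ta")
        for i in range(n):
            while True:
                site = select_integration_site(genome, True, 1, rng)
                if all(c != site.chrom or abs(site.position - q) > 700
                       for c, q in used):
                    used.append((site.chrom, site.position))
                    break
            t, _ = plant_insertion(genome, spec, site, rng, library, vaf=vaf,
                                   ins_id=f"i{i}", emit_haplotype=False)
            truths.append(t)
        return truths

    def test_noise_free_recall_and_specificity(self, genome, library, rng):
        cfg = SimConfig(depth=20, duplicate_rate=0.1, seed=1)
        truths = self.plant_many(genome, library, rng, 30, vaf=1.0)
        reads = simulate_library(genome, truths, cfg, rng, "S1", library)
        calls = run_caller(reads, library=library)
        matched = 0
        for t in truths:
            near = calls[(calls["chrom"] == t.chrom)
                         & ((calls["position"] - t.position).abs() <= 200)]
            matched += bool(len(near))
        assert matched / len(truths) >= 0.95
        for _, c in calls.iterrows():
            assert any(t.chrom == c["chrom"]
                       and abs(t.position - c["position"]) <= 200
                       for t in truths), "call without a truth insertion"

    def test_calls_invariant_to_read_order(self, genome, library, rng):
        cfg = SimConfig(depth=15, duplicate_rate=0.2, seed=1)
        truths = self.plant_many(genome, library, rng, 10, vaf=1.0)
        reads = simulate_library(genome, truths, cfg, rng, "S1", library)
        shuffled = reads.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = run_caller(reads, library=library)
        b = run_caller(shuffled, library=library)
        pd.testing.assert_frame_equal(a, b)

    def test_recall_never_increases_as_vaf_drops(self, genome, library):
        cfg = SimConfig(depth=10, duplicate_rate=0.0, seed=1)
        mean_recall = []
        for vaf in (1.0, 0.3, 0.05):
            recalls = []
            for seed in (1, 2, 3):
                rng = np.random.default_rng(seed)
                truths = self.plant_many(genome, library, rng, 20, vaf)
                reads = simulate_library(genome, truths, cfg, rng, "S1", library)
                calls = run_caller(reads, library=library)
                hit = sum(bool(len(calls[(calls["chrom"] == t.chrom)
                                         & ((calls["position"] - t.position)
                                            .abs() <= 200)]))
                          for t in truths)
                recalls.append(hit / len(truths))
            mean_recall.append(np.mean(recalls))
        assert mean_recall[0] >= mean_recall[1] >= mean_recall[2]
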