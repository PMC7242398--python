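"""recomb: identity blocks, background exclusion, t-test, four-gamete R_min."""
import numpy as np
import pandas as pd
import pytest

import clonepop as cp
from conftest import make_matrix


def two_isolates(a, b):
    return make_matrix(np.vstack([a, b]).astype(np.int8), ids=["x", "y"])


class TestIdenticalRuns:
    def test_run_at_threshold_boundary(self):
        a = np.zeros(3000, dtype=np.int8)
        b = a.copy()
        b[0] = 1
        b[1500] = 1  # identical runs of 1499 and 1499
        m = two_isolates(a, b)
        assert len(cp.identical_runs(m, "x", "y", min_snps=1500)) == 0
        assert len(cp.identical_runs(m, "x", "y", min_snps=1499)) == 2

    def test_full_identity_single_block(self):
        a = np.random.default_rng(1).integers(0, 2, 10_000).astype(np.int8)
        m = two_isolates(a, a)
        runs = cp.identical_runs(m, "x", "y", min_snps=1500)
        assert len(runs) == 1
        assert runs.loc[0, "n_snps"] == 10_000
        assert (runs.loc[0, "start_idx"], runs.loc[0, "end_idx"]) == (0, 9999)

    def test_missing_terminates_run_by_default(self):
        a = np.zeros(4000, dtype=np.int8)
        b = a.copy()
        b[2000] = -1
        m = two_isolates(a, b)
        runs = cp.identical_runs(m, "x", "y", min_snps=1500)
        assert len(runs) == 2
        skip = cp.identical_runs(m, "x", "y", min_snps=1500, skip_missing=True)
        assert len(skip) == 1 and skip.loc[0, "n_snps"] == 3999

    def test_symmetry(self, full_cohort):
        m = full_cohort.matrix
        r1 = cp.identical_runs(m, "Bb13", "A2007-002", min_snps=500)
        r2 = cp.identical_runs(m, "A2007-002", "Bb13", min_snps=500)
        pd.testing.assert_frame_equal(r1, r2)

    def test_min_snps_monotonicity(self, full_cohort):
        m = full_cohort.matrix
        ns = [len(cp.identical_runs(m, "Bb13", "A2007-002", min_snps=k))
              for k in (2500, 1500, 500, 50)]
        assert ns == sorted(ns)

    def test_unknown_isolate_errors(self, full_cohort):
        with pytest.raises(KeyError):
            cp.identical_runs(full_cohort.matrix, "Bb13", "nobody")

    def test_planted_blocks_recovered_with_exact_boundaries(self, full_cohort):
        m = full_cohort.matrix
        for _, b in full_cohort.blocks.iterrows():
            runs = cp.identical_runs(m, b["donor"], b["recipient"],
                                     min_snps=1500)
            match = runs[(runs["chrom"] == b["chrom"])
                         & (runs["start_idx"] == b["start_idx"])
                         & (runs["end_idx"] == b["end_idx"])]
            assert len(match) == 1


class TestBackgroundAndCandidates:
    def test_interval_merge_oracle(self):
        df = pd.DataFrame({"chrom": "c1", "start_idx": [100, 250],
                           "end_idx": [300, 400]})
        merged = cp.merge_intervals(df)
        assert merged.values.tolist() == [["c1", 100, 400]]

    def test_union_idempotent(self):
        df = pd.DataFrame({"chrom": "c1", "start_idx": [10, 10],
                           "end_idx": [50, 50]})
        assert len(cp.merge_intervals(df)) == 1

    def test_empty_background_warns_empty(self, full_cohort):
        bg = cp.background_blocks(full_cohort.matrix, "Bb13", [])
        assert bg.empty

    def test_candidate_inside_background_excluded(self):
        a = np.zeros(5000, dtype=np.int8)
        b = a.copy()
        m = two_isolates(a, b)
        bg = pd.DataFrame({"chrom": ["chr01"], "start_idx": [0],
                           "end_idx": [4999]})
        assert len(cp.candidate_blocks(m, "x", "y", bg, min_snps=1500)) == 0

    def test_candidate_disjoint_from_background_retained(self):
        a = np.zeros(5000, dtype=np.int8)
        m = two_isolates(a, a)
        bg = pd.DataFrame({"chrom": ["chr02"], "start_idx": [0],
                           "end_idx": [4999]})
        assert len(cp.candidate_blocks(m, "x", "y", bg, min_snps=1500)) == 1

    def test_overlap_policies(self):
        a = np.zeros(2000, dtype=np.int8)
        m = two_isolates(a, a)  # one candidate 0..1999
        bg = pd.DataFrame({"chrom": ["chr01"], "start_idx": [0],
                           "end_idx": [199]})  # 10% of the candidate
        assert len(cp.candidate_blocks(m, "x", "y", bg, 1500, "any")) == 0
        assert len(cp.candidate_blocks(m, "x", "y", bg, 1500, 0.5)) == 1
        assert len(cp.candidate_blocks(m, "x", "y", bg, 1500, 0.1)) == 0

    def test_same_mat_copy_excluded_in_cohort(self, full_cohort):
        m = full_cohort.matrix
        meta = full_cohort.meta
        blocks = full_cohort.blocks
        decoy = blocks[blocks["role"] == "candidate_excluded"].iloc[0]
        bg_iso = blocks[blocks["role"] == "background_copy"].iloc[0]["recipient"]
        rid = decoy["donor"]
        lin = full_cohort.clone_truth
        same = [i for i in m.isolate_ids
                if meta.loc[i, "mat"] == meta.loc[rid, "mat"]
                and lin[i] != lin[rid] and i != rid]
        assert bg_iso in same
        bg = cp.background_blocks(m, rid, same, min_snps=1500)
        cand = cp.candidate_blocks(m, rid, decoy["recipient"], bg,
                                   min_snps=1500)
        overlapping = cand[(cand["chrom"] == decoy["chrom"])
                           & (cand["start_idx"] <= decoy["end_idx"])
                           & (cand["end_idx"] >= decoy["start_idx"])]
        assert overlapping.empty
        # the genuine candidates survive the exclusion
        for _, b in blocks[blocks["role"] == "candidate"].iterrows():
            if b["donor"] != rid:
                continue
            cand2 = cp.candidate_blocks(m, rid, b["recipient"], bg, 1500)
            hit = cand2[(cand2["chrom"] == b["chrom"])
                        & (cand2["start_idx"] == b["start_idx"])]
            assert len(hit) == 1


class TestCompareBlockCounts:
    def test_identical_groups(self):
        r = cp.compare_block_counts([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.pvalue == 1.0
        assert r.direction == "equal"

    def test_textbook_t_value(self):
        r = cp.compare_block_counts([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.statistic == pytest.approx(-1.0)
        assert r.pvalue == pytest.approx(0.3466, abs=2e-3)
        assert r.direction == "B>A"

    def test_zero_variance_unequal_means(self):
        r = cp.compare_block_counts([2, 2, 2], [5, 5, 5])
        assert r.pvalue == 0.0 and r.direction == "B>A"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cp.compare_block_counts([1], [2, 3])

    def test_enriched_donor_detected_across_seeds(self, tmp_path):
        # donor A's partners carry ~3x more planted blocks than donor B's
        def config(seed, blocks):
            return cp.SimConfig(
                n_chromosomes=2, chrom_length=300_000,
                n_isolates_per_epoch={1997: 10, 2007: 10, 2017: 10},
                n_founder_lineages=6, mutation_rate=3e-3,
                group_mutation_rate=3e-3, sweep=None, planted_blocks=blocks,
                seed=seed)

        pvals = []
        na, nb = [3, 4, 3, 4], [1, 1, 2, 1]
        for seed in range(5):
            probe = cp.simulate_cohort(config(100 + seed, []),
                                       tmp_path / f"p{seed}")
            m1 = [i for i in probe.meta.index
                  if probe.meta.loc[i, "mat"] == "MAT1-1"][:8]
            assert len(m1) == 8
            blocks = []
            for r, recip in enumerate(m1):
                donor = "Bb13" if r < 4 else "Bb17"
                n_b = na[r] if r < 4 else nb[r - 4]
                for b in range(n_b):
                    blocks.append(dict(donor=donor, recipient=recip,
                                       chrom="chr02",
                                       start_idx=50 + b * 1700,
                                       length=1600, role="candidate"))
            out = cp.simulate_cohort(config(100 + seed, blocks),
                                     tmp_path / f"c{seed}")
            counts_a = [len(cp.identical_runs(out.matrix, "Bb13", i, 1500))
                        for i in m1[:4]]
            counts_b = [len(cp.identical_runs(out.matrix, "Bb17", i, 1500))
                        for i in m1[4:]]
            pvals.append(cp.compare_block_counts(counts_a, counts_b).pvalue)
        assert all(p < 0.01 for p in pvals)


class TestFourGamete:
    def test_clonal_matrix_no_signal(self, clean_cohort):
        rmin = cp.four_gamete_rmin(clean_cohort.matrix, window=10 ** 9)
        assert (rmin["value"] == 0).all()

    def test_two_incompatible_loci(self):
        calls = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], np.int8)
        rmin = cp.four_gamete_rmin(make_matrix(calls), window=100)
        assert rmin["value"].iloc[0] == 1

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(59)

        def oracle(calls):
            S = calls.shape[1]
            pairs = []
            for i in range(S):
                for j in range(i + 1, S):
                    g = set()
                    for row in calls:
                        if row[i] != -1 and row[j] != -1:
                            g.add((row[i], row[j]))
                    if len(g) == 4:
                        pairs.append((i, j))
            # greedy stabbing, sorted by right end
            pairs.sort(key=lambda p: p[1])
            count, last = 0, -1
            for i, j in pairs:
                if last < i:
                    count += 1
                    last = j - 1
            return count

        for _ in range(100):
            n = int(rng.integers(4, 10))
            S = int(rng.integers(5, 20))
            calls = rng.choice([0, 1, -1], size=(n, S),
                               p=[0.45, 0.45, 0.1]).astype(np.int8)
            got = cp.four_gamete_rmin(make_matrix(calls), window=10 ** 6)
            assert got["value"].iloc[0] == oracle(calls)

    def test_too_few_isolates(self):
        with pytest.raises(ValueError):
            cp.four_gamete_rmin(make_matrix(np.zeros((3, 5), np.int8)))
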