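"""popstats: Tajima's D, Hudson F_ST, LD decay, DAF spectra vs oracles."""
import itertools

import numpy as np
import pytest

import clonepop as cp
from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_tajimas_d(calls):
    """Direct evaluation: exact pairwise differences + the 1989 constants."""
    n = calls.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    pi = np.mean([np.sum(calls[a] != calls[b]) for a, b in pairs])
    S = sum(1 for j in range(calls.shape[1])
            if 0 < calls[:, j].sum() < n)
    if S == 0:
        return np.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def brute_hudson_window(calls_a, calls_b):
    num_sum = den_sum = 0.0
    for j in range(calls_a.shape[1]):
        n1, n2 = calls_a.shape[0], calls_b.shape[0]
        p1 = calls_a[:, j].mean()
        p2 = calls_b[:, j].mean()
        num_sum += ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum if den_sum > 0 else np.nan


def brute_r2(x, y):
    pa, pb = x.mean(), y.mean()
    pab = (x & y).mean()
    d = pa * (1 - pa) * pb * (1 - pb)
    return np.nan if d == 0 else (pab - pa * pb) ** 2 / d


class TestTajimasD:
    def test_worked_example_four_haplotypes(self):
        calls = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]],
                         dtype=np.int8)
        d = cp.tajimas_d(make_matrix(calls), window=100)
        # pi = 10/6, theta_W = 3/a1, D ~ +0.168
        assert d["value"].iloc[0] == pytest.approx(0.16766, abs=1e-4)

    def test_no_segregating_sites_is_nan(self):
        calls = np.zeros((5, 3), dtype=np.int8)
        d = cp.tajimas_d(make_matrix(calls), window=100)
        assert np.isnan(d["value"].iloc[0])

    def test_requires_four_isolates(self):
        with pytest.raises(ValueError):
            cp.tajimas_d(make_matrix(np.zeros((3, 2), dtype=np.int8)))

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            S = int(rng.integers(1, 40))
            calls = rng.integers(0, 2, size=(n, S)).astype(np.int8)
            got = cp.tajimas_d(make_matrix(calls), window=10 ** 6)
            expect = brute_tajimas_d(calls)
            v = got["value"].iloc[0]
            assert (np.isnan(v) and np.isnan(expect)) or \
                v == pytest.approx(expect, abs=1e-10)

    def test_invariant_under_isolate_relabelling(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        d1 = cp.tajimas_d(make_matrix(calls), window=10 ** 6)["value"].iloc[0]
        perm = rng.permutation(8)
        d2 = cp.tajimas_d(make_matrix(calls[perm]), window=10 ** 6)["value"].iloc[0]
        assert d1 == pytest.approx(d2)

    def test_neutral_cohort_median_near_zero(self, neutral_matrix):
        d = cp.tajimas_d(neutral_matrix, window=5000)
        assert abs(d["value"].median(skipna=True)) < 0.3


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        calls = np.vstack([np.ones((3, 5)), np.zeros((3, 5))]).astype(np.int8)
        m = make_matrix(calls)
        fst, med = cp.hudson_fst(m, m.isolate_ids[:3], m.isolate_ids[3:],
                                 window=100)
        assert fst["value"].iloc[0] == pytest.approx(1.0)
        assert med == pytest.approx(1.0)

    def test_single_site_hand_value(self):
        # p1 = p2 = 0.5 with n1 = n2 = 10: N = -2*(0.25/9), Dn = 0.5
        half = np.concatenate([np.ones(5), np.zeros(5)]).astype(np.int8)
        m = make_matrix(np.concatenate([half, half])[:, None])
        fst, _ = cp.hudson_fst(m, m.isolate_ids[:10], m.isolate_ids[10:],
                               window=100)
        assert fst["value"].iloc[0] == pytest.approx(-2 * (0.25 / 9) / 0.5)

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            S = int(rng.integers(1, 25))
            a = rng.integers(0, 2, size=(n1, S)).astype(np.int8)
            b = rng.integers(0, 2, size=(n2, S)).astype(np.int8)
            m = make_matrix(np.vstack([a, b]))
            fst, _ = cp.hudson_fst(m, m.isolate_ids[:n1], m.isolate_ids[n1:],
                                   window=10 ** 6)
            expect = brute_hudson_window(a, b)
            v = fst["value"].iloc[0]
            assert (np.isnan(v) and np.isnan(expect)) or \
                v == pytest.approx(expect, abs=1e-10)

    def test_panmictic_split_median_near_zero(self):
        m, a, b = cp.simulate_split(12, 0, sequence_length=4e5,
                                    recombination_rate=1e-7, seed=7)
        _, med = cp.hudson_fst(m, a, b, window=5000)
        assert abs(med) < 0.05

    def test_wright_band_constant(self):
        assert cp.popstats.WRIGHT_BAND == (0.05, 0.15)


class TestLdDecay:
    def test_perfect_association(self):
        assert cp.pair_r2(np.array([1, 1, 0, 0], np.int8),
                          np.array([1, 1, 0, 0], np.int8)) == pytest.approx(1.0)

    def test_independent_loci(self):
        assert cp.pair_r2(np.array([1, 1, 0, 0], np.int8),
                          np.array([1, 0, 1, 0], np.int8)) == pytest.approx(0.0)

    def test_worked_example_one_ninth(self):
        x = np.array([1, 1, 0, 1], np.int8)
        y = np.array([1, 0, 1, 1], np.int8)
        assert cp.pair_r2(x, y) == pytest.approx(1 / 9)

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(4, 16))
            x = rng.integers(0, 2, n).astype(np.int8)
            y = rng.integers(0, 2, n).astype(np.int8)
            got = cp.pair_r2(x, y)
            expect = brute_r2(x.astype(bool), y.astype(bool))
            assert (np.isnan(got) and np.isnan(expect)) or \
                got == pytest.approx(expect, abs=1e-12)

    def test_curve_bounded_and_binned(self, clean_cohort):
        ld = cp.ld_decay(clean_cohort.matrix, max_dist=50_000,
                         subsample_n=10, seed=1)
        vals = ld.binned["mean_r2"].dropna()
        assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()
        assert (ld.binned["bin_hi"] - ld.binned["bin_lo"] == 499).all()
        assert len(ld.short_range) == 100

    def test_clonal_plateau_vs_recombining_decay(self, clean_cohort):
        ld_c = cp.ld_decay(clean_cohort.matrix, max_dist=100_000,
                           subsample_n=12, seed=1)
        rec = cp.simulate_neutral(12, sequence_length=2.5e5,
                                  mutation_rate=2e-7, recombination_rate=2e-7,
                                  seed=13)
        ld_r = cp.ld_decay(rec, max_dist=100_000, subsample_n=12, seed=1)

        def plateau_ratio(ld):
            b = ld.binned.dropna()
            far = b[b["bin_lo"] > 50_000]["mean_r2"].mean()
            return far / b["mean_r2"].iloc[0]

        assert plateau_ratio(ld_c) > 0.5       # clonal: LD never decays away
        assert plateau_ratio(ld_r) < plateau_ratio(ld_c)

    def test_subsample_too_large_rejected(self, clean_cohort):
        with pytest.raises(ValueError):
            cp.ld_decay(clean_cohort.matrix, subsample_n=10 ** 6)


class TestDafSpectrum:
    def test_single_site_cell(self):
        a = np.array([[1], [1], [1], [0]], np.int8)
        b = np.array([[1], [0], [0], [0]], np.int8)
        m = make_matrix(np.vstack([a, b]))
        spec = cp.daf_spectrum(m, m.isolate_ids[:4], m.isolate_ids[4:])
        assert spec.counts[3, 1] == 1
        assert spec.total == 1

    def test_identical_pops_diagonal(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 2, size=(5, 50)).astype(np.int8)
        m = make_matrix(np.vstack([calls, calls]))
        spec = cp.daf_spectrum(m, m.isolate_ids[:5], m.isolate_ids[5:])
        assert spec.counts.sum() == np.trace(spec.counts)

    def test_outgroup_polarization_and_skips(self):
        calls = np.array([[1, 1, -1],    # outgroup
                          [1, 0, 0], [0, 0, 1],
                          [1, 1, 0], [0, 0, 1]], np.int8)
        m = make_matrix(calls, ids=["og", "a1", "a2", "b1", "b2"])
        spec = cp.daf_spectrum(m, ["a1", "a2"], ["b1", "b2"],
                               polarization="og")
        # site 1: outgroup=1 so derived=0; site 3 unpolarizable
        assert spec.n_skipped == 1
        assert spec.total == 2
        with pytest.raises(KeyError):
            cp.daf_spectrum(m, ["a1"], ["b1"], polarization="nope")

    def test_off_diagonal_mass_grows_with_divergence(self):
        def offdiag_mass(split_time, seed):
            m, a, b = cp.simulate_split(8, split_time, sequence_length=1.5e5,
                                        seed=seed)
            spec = cp.daf_spectrum(m, a, b)
            c = spec.counts.astype(float)
            n1 = len(a)
            w = np.abs(np.subtract.outer(np.arange(n1 + 1) / n1,
                                         np.arange(n1 + 1) / n1))
            return (c * w).sum() / c.sum()

        masses = [offdiag_mass(t, seed=41) for t in (0, 20_000, 80_000)]
        assert masses[0] < masses[1] < masses[2]
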