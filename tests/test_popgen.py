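"""Windowed statistics, QC, and LD on dosage matrices."""

import math

import numpy as np
import pandas as pd
import pytest

from pigpan import popgen as pop
from pigpan.popgen import GenotypeMatrix, PopulationSpec


def _gm(dosages, positions=None, chrom="chr1", ref=None, alt=None, depth=30.0):
    dosages = np.asarray(dosages, dtype=float)
    n_var, n_ind = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions if positions is not None else np.arange(n_var) * 100,
            "id": [f"v{i}" for i in range(n_var)],
            "ref": ref if ref is not None else ["A"] * n_var,
            "alt": alt if alt is not None else ["G"] * n_var,
            "mean_depth": depth,
        }
    )
    return GenotypeMatrix(variants, [f"i{j}" for j in range(n_ind)], dosages)


class TestQcFilter:
    def test_maf_below_threshold_removed(self):
        # MAF 0.09: 9 alt alleles of 100
        d = np.zeros((1, 50))
        d[0, :9] = 1
        gm = _gm(d)
        filtered, report = pop.qc_filter(gm)
        assert filtered.n_variants == 0 and report["maf"] == 1

    def test_clean_variant_retained(self):
        d = np.tile([0.0, 2.0], (1, 10))
        filtered, report = pop.qc_filter(_gm(d))
        assert filtered.n_variants == 1 and report["removed"] == 0

    def test_one_failure_per_rule(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 40)).astype(float)
        gm = _gm(d)
        gm.variants.loc[0, "mean_depth"] = 2.0          # depth failure
        gm.dosages[1, :10] = np.nan                      # missing failure
        gm.dosages[2] = 0.0
        gm.dosages[2, 0] = 1.0                           # MAF 1/80 failure
        filtered, report = pop.qc_filter(gm)
        assert report["depth"] == 1 and report["missing"] == 1 and report["maf"] == 1
        assert filtered.n_variants == 7


class TestLd:
    def test_identical_and_mirrored_vectors(self):
        a = np.array([0, 1, 2, 0, 2], dtype=float)
        assert pop.ld_r2(a, a) == pytest.approx(1.0)
        assert pop.ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        a = np.array([0, 1, 2, 0], dtype=float)
        b = np.array([0, 1, 1, 0], dtype=float)
        r = np.corrcoef(a, b)[0, 1]
        assert pop.ld_r2(a, b) == pytest.approx(r * r)

    def test_monomorphic_is_nan_and_mismatch_is_error(self):
        a = np.array([1.0, 1.0, 1.0])
        assert math.isnan(pop.ld_r2(a, np.array([0.0, 1.0, 2.0])))
        with pytest.raises(ValueError):
            pop.ld_r2(a, np.array([0.0, 1.0]))

    def test_prune_keeps_independent_and_drops_duplicate(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(6, 100)).astype(float)
        d[3] = d[1]  # duplicated column -> r2 = 1
        gm = _gm(d)
        kept = pop.ld_prune(gm, r2_threshold=0.5)
        assert "v1" in kept and "v3" not in kept

    def test_prune_matches_brute_force_on_one_window(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(20, 80)).astype(float)
        d[5] = np.clip(d[4] + rng.integers(0, 2, 80), 0, 2)  # planted LD pair
        gm = _gm(d)
        kept = pop.ld_prune(gm, window=20, step=5, r2_threshold=0.1)
        removed = [f"v{i}" for i in range(20) if f"v{i}" not in kept]
        # brute force: every surviving pair must be below threshold
        idx = {v: i for i, v in enumerate(gm.variants["id"])}
        for a in kept:
            for b in kept:
                if a < b:
                    r2 = pop.ld_r2(gm.dosages[idx[a]], gm.dosages[idx[b]])
                    assert math.isnan(r2) or r2 <= 0.1
        assert removed  # the planted pair forces at least one removal


class TestWindowedStats:
    def test_site_pi_from_allele_frequency(self):
        # one site, p = 0.5, n = 10 chromosomes: pi = 2p(1-p) * n/(n-1)
        d = np.array([[1, 1, 1, 1, 1]], dtype=float)
        gm = _gm(d, positions=[10])
        track = pop.pi_windows(gm, {"chr1": 100}, window=100, step=100)
        assert track.values[0] * 100 == pytest.approx(0.5 * 10 / 9)

    def test_tstv_counts_sites(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (2, 1))
        gm = _gm(d, ref=["A", "C"], alt=["G", "A"])  # one Ts, one Tv
        track = pop.tstv_windows(gm, {"chr1": 1000}, window=1000, step=1000)
        assert track.values[0] == pytest.approx(1.0)

    def test_tajimas_d_zero_when_pi_equals_watterson(self):
        # n = 4 chromosomes, S = 11: 8 singletons + 3 doubletons gives
        # theta_pi = 8*(1/2) + 3*(2/3) = 6 = S/a1 with a1 = 11/6
        rows = [[1.0, 0.0]] * 8 + [[1.0, 1.0]] * 3
        gm = _gm(np.asarray(rows), positions=np.arange(11) * 10)
        track = pop.tajimas_d_windows(gm, {"chr1": 200}, window=200, step=200)
        assert track.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_tajimas_d_negative_with_excess_singletons(self):
        rows = [[1.0] + [0.0] * 9] * 20  # star-like: all singletons
        gm = _gm(np.asarray(rows), positions=np.arange(20) * 10)
        track = pop.tajimas_d_windows(gm, {"chr1": 300}, window=300, step=300)
        assert track.values[0] < 0

    def test_fst_fixed_difference_is_one(self):
        d = np.array([[0.0] * 10 + [2.0] * 10])
        gm = _gm(d)
        pops = PopulationSpec({f"i{j}": ("p1" if j < 10 else "p2") for j in range(20)})
        assert pop.fst_sites(gm, pops)[0] == pytest.approx(1.0)

    def test_fst_null_near_zero(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, size=(200, 200)).astype(float)
        gm = _gm(d)
        pops = PopulationSpec({f"i{j}": ("p1" if j < 100 else "p2") for j in range(200)})
        track = pop.fst_windows(gm, pops, {"chr1": 20_000}, window=20_000, step=20_000)
        assert abs(track.values[0]) < 0.05

    def test_fst_matches_direct_weir_cockerham_evaluation(self):
        rng = np.random.default_rng(4)
        n = 50
        d1 = rng.binomial(2, 0.2, size=(100, n)).astype(float)
        d2 = rng.binomial(2, 0.8, size=(100, n)).astype(float)
        d = np.concatenate([d1, d2], axis=1)
        gm = _gm(d)
        pops = PopulationSpec({f"i{j}": ("p1" if j < n else "p2") for j in range(2 * n)})
        a, b, c, _ = pop._wc_components(gm, pops)
        # direct site-by-site evaluation of the estimator for one site
        for s in (0, 17, 99):
            n1 = n2 = n
            p1 = d[s, :n].sum() / (2 * n1)
            p2 = d[s, n:].sum() / (2 * n2)
            h1 = np.mean(d[s, :n] == 1)
            h2 = np.mean(d[s, n:] == 1)
            nbar = (n1 + n2) / 2
            r = 2
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a_direct = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
            )
            b_direct = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            assert a[s] == pytest.approx(a_direct)
            assert b[s] == pytest.approx(b_direct)
            assert c[s] == pytest.approx(hbar / 2)

    def test_pi_and_fst_invariant_to_individual_order(self, genotypes_small):
        gm, pops, _ = genotypes_small
        lengths = {"chr1": 500_000}
        perm = list(np.random.default_rng(5).permutation(gm.individuals))
        gm2 = gm.subset_individuals(perm)
        t1 = pop.pi_windows(gm, lengths)
        t2 = pop.pi_windows(gm2, lengths)
        assert np.allclose(t1.values, t2.values, equal_nan=True)
        f1 = pop.fst_windows(gm, pops, lengths)
        f2 = pop.fst_windows(gm2, pops, lengths)
        assert np.allclose(f1.values, f2.values, equal_nan=True)


class TestTrackCorrelation:
    def _track(self, values):
        n = len(values)
        return pop.WindowTrack(
            100, 100, ["chr1"] * n, np.arange(n) * 100, np.arange(n) * 100 + 100, values
        )

    def test_perfect_and_anti_correlation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pop.track_correlation(self._track(a), self._track(a))
        assert r == pytest.approx(1.0)
        r, _ = pop.track_correlation(self._track(a), self._track(-a))
        assert r == pytest.approx(-1.0)

    def test_missing_aware_pairwise_complete(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([2.0, 4.0, 1.0, 8.0, np.nan])
        r, _ = pop.track_correlation(self._track(a), self._track(b))
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        a = np.array([1.0, 2.0, np.nan])
        with pytest.raises(ValueError, match="3"):
            pop.track_correlation(self._track(a), self._track(a))
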