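"""V_ST statistics, top-percentile scans, sweeps and overlap enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigpan import selection as sel
from pigpan.core import GenomicInterval
from pigpan.popgen import PopulationSpec, WindowTrack, pi_windows, fst_windows


def _brute_force_vst(dosages, labels):
    """Independent two-pass variance computation."""
    d = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(d)
    pooled = d[ok]
    v_t = np.mean((pooled - pooled.mean()) ** 2)
    num = tot = 0.0
    for p in set(labels.tolist()):
        vals = d[ok & (labels == p)]
        num += len(vals) * np.mean((vals - vals.mean()) ** 2)
        tot += len(vals)
    v_s = num / tot
    if v_t == 0:
        return None
    return (v_t - v_s) / v_t


class TestVst:
    def test_fixed_difference_is_one(self):
        r = sel.vst(np.array([0, 0, 0, 0, 2, 2, 2, 2], float), ["a"] * 4 + ["b"] * 4)
        assert (r.v_t, r.v_s, r.v_st) == (1.0, 0.0, 1.0)

    def test_identical_distributions_zero(self):
        d = np.array([0, 1, 2, 1, 0, 1, 2, 1], float)
        r = sel.vst(d, ["a"] * 4 + ["b"] * 4)
        assert r.v_st == pytest.approx(0.0)

    def test_worked_example(self):
        r = sel.vst(np.array([0, 1, 2, 1, 2, 2, 1, 2], float), ["a"] * 4 + ["b"] * 4)
        assert r.v_t == pytest.approx(0.484375)
        assert r.v_s == pytest.approx(0.34375)
        assert r.v_st == pytest.approx(9 / 31)

    def test_monomorphic_undefined(self):
        r = sel.vst(np.array([1, 1, 1, 1], float), ["a", "a", "b", "b"])
        assert not r.defined

    def test_population_entirely_missing_is_error(self):
        d = np.array([0, 1, np.nan, np.nan])
        with pytest.raises(ValueError, match="b"):
            sel.vst(d, ["a", "a", "b", "b"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 20, size=2)
        d = rng.integers(0, 3, size=n1 + n2).astype(float)
        labels = ["a"] * n1 + ["b"] * n2
        expected = _brute_force_vst(d, labels)
        r = sel.vst(d, labels)
        if expected is None:
            assert not r.defined
        else:
            assert r.v_st_raw == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_dosage_relabel(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=20).astype(float)
        labels = ["a"] * 10 + ["b"] * 10
        r1 = sel.vst(d, labels)
        r2 = sel.vst(2 - d, labels)
        if r1.defined:
            assert r1.v_st == pytest.approx(r2.v_st, abs=1e-12)


class TestVstScan:
    def test_rank_arithmetic_without_ties(self):
        rng = np.random.default_rng(1)
        n = 200
        d = rng.binomial(2, np.linspace(0.3, 0.7, n)[:, None], size=(n, 40)).astype(float)
        d[0, :20] = 0
        d[0, 20:] = 2  # one clean outlier
        variants = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n), "id": [f"s{i}" for i in range(n)],
             "ref": "A", "alt": "G", "mean_depth": 30.0}
        )
        from pigpan.popgen import GenotypeMatrix

        gm = GenotypeMatrix(variants, [f"i{j}" for j in range(40)], d)
        pops = PopulationSpec({f"i{j}": ("a" if j < 20 else "b") for j in range(40)})
        table, selected = sel.vst_scan(gm, pops, top_fraction=0.01)
        n_def = int(table["v_st"].notna().sum())
        assert len(selected) >= int(np.ceil(0.01 * n_def))
        assert "s0" in set(selected)

    def test_simulation_truth_sensitivity(self, genotypes_small):
        gm, pops, truth = genotypes_small
        table, selected = sel.vst_scan(gm, pops, top_fraction=0.02)
        planted = set(gm.variants.loc[truth.differentiated, "id"])
        sens = len(planted & set(selected)) / len(planted)
        assert sens >= 0.9


class TestSweepRegions:
    def _track(self, values, chrom="chr1"):
        n = len(values)
        starts = np.arange(n) * 10_000
        return WindowTrack(
            100_000, 10_000, [chrom] * n, starts, starts + 100_000, np.asarray(values, float)
        )

    def test_intersection_of_top_windows(self):
        rng = np.random.default_rng(0)
        fst = rng.uniform(0.0, 0.05, size=100)
        ratio_hi = rng.uniform(0.8, 1.2, size=100)
        lo = np.ones(100)
        fst[[10, 11, 50]] = 1.0       # top-5% F_ST: windows 10, 11, 50 (+2 noise)
        ratio_hi[[10, 11, 80]] = 9.0  # top-5% pi ratio: windows 10, 11, 80 (+2 noise)
        sweeps = sel.sweep_regions(
            self._track(fst), self._track(ratio_hi), self._track(lo), top_fraction=0.03
        )
        # only windows 10, 11 pass both thresholds; consecutive -> one region
        assert len(sweeps) == 1
        assert sweeps.regions[0].start == 100_000
        assert sweeps.regions[0].end == 210_000

    def test_no_window_passes_both(self):
        rng = np.random.default_rng(1)
        fst = rng.uniform(0.0, 0.05, size=60)
        pi1 = rng.uniform(0.8, 1.2, size=60)
        fst[5] = 1.0
        pi1[40] = 9.0
        sweeps = sel.sweep_regions(
            self._track(fst), self._track(pi1), self._track(np.ones(60)), 0.01
        )
        assert len(sweeps) == 0

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError, match="grid"):
            sel.sweep_regions(
                self._track(np.ones(10)), self._track(np.ones(9)), self._track(np.ones(9))
            )

    def test_planted_sweep_recovered(self):
        rng = np.random.default_rng(7)
        from pigpan import simulate as sim
        from pigpan.popgen import GenotypeMatrix

        gm, pops, _ = sim.simulate_population_genotypes(
            n_per_pop=(30, 30), n_loci=1000, differentiated_fraction=0.0, seed=11
        )
        # plant a sweep: loci 400-449 fixed-different and diversity lost in pop2
        d = gm.dosages.copy()
        d[400:450, :30] = rng.binomial(2, 0.5, size=(50, 30))
        d[400:450, 30:] = 2.0
        gm = GenotypeMatrix(gm.variants, gm.individuals, d)
        lengths = {"chr1": 1_000_000}
        members = {p: [i for i, q in pops.assignment.items() if q == p] for p in pops.populations}
        fst = fst_windows(gm, pops, lengths)
        pi1 = pi_windows(gm.subset_individuals(members["EUR"]), lengths)
        pi2 = pi_windows(gm.subset_individuals(members["ASN"]), lengths)
        sweeps = sel.sweep_regions(fst, pi1, pi2, top_fraction=0.05)
        planted = GenomicInterval("chr1", 400_000, 450_000)
        assert any(r.overlaps(planted) for r in sweeps.regions)


class TestSweepOverlapEnrichment:
    def _svs(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"id": [f"s{i}" for i in range(n)], "chrom": "chr1",
             "pos": rng.integers(0, 1_000_000, size=n)}
        )

    def test_whole_genome_sweep_gives_fold_one(self):
        svs = self._svs()
        sweeps = sel.SweepRegionSet([GenomicInterval("chr1", 0, 1_000_000)])
        out = sel.sweep_overlap_enrichment(
            pd.Index([f"s{i}" for i in range(20)]), svs, sweeps, n_perm=200, seed=1
        )
        assert out["fold"] == pytest.approx(1.0)
        assert out["p"] > 0.5

    def test_selected_inside_sweeps_is_significant(self):
        svs = self._svs(seed=3)
        sweeps = sel.SweepRegionSet([GenomicInterval("chr1", 0, 100_000)])
        inside = svs.loc[svs["pos"] < 100_000, "id"].head(15)
        out = sel.sweep_overlap_enrichment(pd.Index(inside), svs, sweeps, n_perm=1000, seed=2)
        assert out["p"] <= 0.01
        assert out["fold"] > 2

    def test_seed_reproducibility(self):
        svs = self._svs(seed=5)
        sweeps = sel.SweepRegionSet([GenomicInterval("chr1", 0, 300_000)])
        ids = pd.Index([f"s{i}" for i in range(30)])
        a = sel.sweep_overlap_enrichment(ids, svs, sweeps, n_perm=300, seed=9)
        b = sel.sweep_overlap_enrichment(ids, svs, sweeps, n_perm=300, seed=9)
        assert a == b

    def test_selected_not_subset_is_error(self):
        svs = self._svs()
        sweeps = sel.SweepRegionSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="subset"):
            sel.sweep_overlap_enrichment(pd.Index(["zzz"]), svs, sweeps)


class TestTagSvSearch:
    def _matrices(self):
        from pigpan.popgen import GenotypeMatrix

        rng = np.random.default_rng(4)
        inds = [f"i{j}" for j in range(40)]
        snp_d = rng.integers(0, 3, size=(5, 40)).astype(float)
        sv_d = rng.integers(0, 3, size=(6, 40)).astype(float)
        sv_d[2] = snp_d[1]  # planted perfect-LD pair
        snp_v = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(5) * 200_000,
             "id": [f"snp{i}" for i in range(5)], "ref": "A", "alt": "G",
             "mean_depth": 30.0}
        )
        sv_v = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(6) * 150_000 + 1000,
             "id": [f"sv{i}" for i in range(6)], "ref": "N", "alt": "<DEL>",
             "mean_depth": 30.0}
        )
        return GenotypeMatrix(sv_v, inds, sv_d), GenotypeMatrix(snp_v, inds, snp_d)

    def test_planted_pair_recovered_with_r2_one(self):
        sv_gm, snp_gm = self._matrices()
        out = sel.tag_sv_search(sv_gm, snp_gm, ["snp1"])
        assert ("snp1", "sv2") in set(zip(out["tag_snp"], out["sv_id"]))
        row = out[(out.tag_snp == "snp1") & (out.sv_id == "sv2")].iloc[0]
        assert row["r2"] == pytest.approx(1.0)

    def test_unknown_tag_warns_and_skips(self):
        sv_gm, snp_gm = self._matrices()
        with pytest.warns(UserWarning, match="missing_tag"):
            out = sel.tag_sv_search(sv_gm, snp_gm, ["missing_tag"])
        assert out.empty

    def test_window_restricts_candidates(self):
        sv_gm, snp_gm = self._matrices()
        out = sel.tag_sv_search(sv_gm, snp_gm, ["snp1"], window=1000)
        assert out.empty  # no SV within 1 kb of snp1
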