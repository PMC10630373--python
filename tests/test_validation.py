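"""Allele-frequency validation stage: correlations, regressions, Mantel,
focal regions, Ward clustering."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from bergscan import validation as vl
from bergscan.io_formats import GenotypeMatrix, PANEL_COLUMNS
from tests.conftest import make_variants


def panel_9():
    rows = [
        ("maxima", 12, 46.9, -2.1, 10.3, 57.0, -156.0, "large"),
        ("sanaka", 8, 44.9, -1.5, 9.8, 55.3, -162.7, "large"),
        ("rufina", 12, 27.5, 2.5, 13.5, 54.0, -130.3, "smaller"),
        ("merrilli", 8, 25.9, 3.9, 15.1, 55.0, -131.7, "smaller"),
        ("gouldii", 10, 19.8, 8.6, 16.5, 38.0, -122.8, "small"),
        ("heermanni", 8, 20.5, 8.3, 18.4, 37.5, -121.9, "small"),
        ("maxillaris", 6, 19.2, 8.9, 17.4, 38.2, -122.3, "small"),
        ("pusillula", 9, 17.9, 9.4, 16.8, 37.6, -122.1, "small"),
        ("samuelis", 6, 18.4, 9.1, 16.2, 38.1, -122.4, "small"),
    ]
    recs = []
    for name, n, mass, wt, st, lat, lon, cls in rows:
        for i in range(n):
            recs.append((f"{name}_{i}", name, mass, wt, st, lat, lon, cls))
    return pd.DataFrame(recs, columns=PANEL_COLUMNS)


class TestAlleleFreqs:
    def test_simple_frequency(self):
        d = np.array([[0, 1, 2]], dtype=np.int8)
        gm = GenotypeMatrix(d, ["a_1", "a_2", "a_3"])
        panel = pd.DataFrame(
            [("a_1", "x", 1, 0, 0, 0, 0, "large"),
             ("a_2", "x", 1, 0, 0, 0, 0, "large"),
             ("a_3", "x", 1, 0, 0, 0, 0, "large")],
            columns=PANEL_COLUMNS,
        )
        freqs = vl.subspecies_allele_freqs(gm, panel)
        assert freqs.loc[0, "x"] == pytest.approx(0.5)

    def test_all_missing_subspecies_is_na(self):
        d = np.array([[1, -1, -1]], dtype=np.int8)
        gm = GenotypeMatrix(d, ["a_1", "b_1", "b_2"])
        panel = pd.DataFrame(
            [("a_1", "x", 1, 0, 0, 0, 0, "large"),
             ("b_1", "y", 1, 0, 0, 0, 0, "small"),
             ("b_2", "y", 1, 0, 0, 0, 0, "small")],
            columns=PANEL_COLUMNS,
        )
        freqs = vl.subspecies_allele_freqs(gm, panel)
        assert np.isnan(freqs.loc[0, "y"]) and freqs.loc[0, "x"] == 0.5

    def test_pooling_conserves_counts(self, rng):
        panel = panel_9()
        n = len(panel)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 30)[:, None], (30, n)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = -1
        gm = GenotypeMatrix(d, panel["sample"].tolist())
        freqs = vl.subspecies_allele_freqs(gm, panel)
        merged = panel.copy()
        merged.loc[merged["subspecies"].isin(["maxima", "sanaka"]), "subspecies"] = "pool"
        pooled = vl.subspecies_allele_freqs(gm, merged)
        # pooled frequency equals the count-weighted mixture of the parts
        for i in range(30):
            counts = 0.0
            alt = 0.0
            for sub in ("maxima", "sanaka"):
                names = panel.loc[panel["subspecies"] == sub, "sample"]
                cols = gm.sample_index(names.tolist())
                dd = gm.dosage[i, cols]
                called = dd >= 0
                counts += 2 * called.sum()
                alt += dd[called].sum()
            expect = alt / counts if counts else np.nan
            assert pooled.loc[i, "pool"] == pytest.approx(expect, nan_ok=True)


class TestCorrelateAndSelect:
    def test_exact_proportionality_selected(self):
        panel = panel_9()
        means = vl.subspecies_means(panel)
        mass = means["mass_g"]
        freqs = pd.DataFrame({s: [m / 50.0] for s, m in mass.items()})
        assoc, selected = vl.correlate_and_select(freqs, panel)
        assert assoc.loc[0, "r_mass"] == pytest.approx(1.0)
        assert list(selected) == [0]
        # temperatures anticorrelate with mass in this panel
        assert assoc.loc[0, "r_winter_temp"] < -0.9

    def test_constant_frequency_skipped(self):
        panel = panel_9()
        freqs = pd.DataFrame({s: [0.5] for s in panel["subspecies"].unique()})
        assoc, selected = vl.correlate_and_select(freqs, panel)
        assert np.isnan(assoc.loc[0, "r_mass"]) and len(selected) == 0

    def test_sign_flip_on_allele_swap(self):
        panel = panel_9()
        means = vl.subspecies_means(panel)
        f = {s: m / 50.0 for s, m in means["mass_g"].items()}
        freqs = pd.DataFrame({s: [v] for s, v in f.items()})
        flipped = pd.DataFrame({s: [1 - v] for s, v in f.items()})
        a1, _ = vl.correlate_and_select(freqs, panel)
        a2, _ = vl.correlate_and_select(flipped, panel)
        assert a1.loc[0, "r_mass"] == pytest.approx(-a2.loc[0, "r_mass"])


class TestRegressions:
    def test_exact_line(self):
        x = np.linspace(0.1, 0.9, 9)
        res = vl.snp_regressions(x, 2 * x + 1)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)
        assert np.allclose(res["residuals"], 0, atol=1e-10)

    def test_df_structure_nine_points(self, rng):
        x = rng.random(9)
        res = vl.snp_regressions(x, rng.random(9))
        assert (res["df_num"], res["df_den"]) == (1, 7)

    def test_r_squared_equals_squared_pearson(self, rng):
        x, y = rng.random(15), rng.random(15)
        res = vl.snp_regressions(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert res["r_squared"] == pytest.approx(r**2, abs=1e-10)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            vl.snp_regressions(np.full(5, 0.3), np.arange(5.0))


class TestPerSiteFstSummary:
    def test_fixed_fraction_by_hand(self):
        from bergscan.outlier_candidates import ComparisonSpec

        # gene of 4 SNPs: 2 fixed differences, 1 shared polymorphism, 1
        # moderate difference -> fixed fraction 2/4
        d = np.array(
            [
                [0, 0, 0, 2, 2, 2],
                [2, 2, 2, 0, 0, 0],
                [1, 1, 1, 1, 1, 1],
                [0, 1, 0, 1, 0, 1],
            ],
            dtype=np.int8,
        )
        names = ["x_1", "x_2", "x_3", "y_1", "y_2", "y_3"]
        gm = GenotypeMatrix(d, names)
        panel = pd.DataFrame(
            [(n, n.split("_")[0], 1, 0, 0, 0, 0, "large") for n in names],
            columns=PANEL_COLUMNS,
        )
        variants = make_variants(4, spacing=10)
        genes = pd.DataFrame(
            [("g", "chr1", 0, 100, "+")],
            columns=["gene_id", "scaffold", "start", "end", "strand"],
        )
        comp = [ComparisonSpec("xy", ("x",), ("y",), "between_size")]
        out = vl.per_site_fst_summary(
            gm, panel, comp, np.arange(4), variants, genes
        )
        per_snp = out["per_snp"]["xy"].to_numpy()
        assert per_snp[0] == pytest.approx(1.0)
        assert per_snp[1] == pytest.approx(1.0)
        assert out["per_gene"]["fixed_frac_xy"].iloc[0] == pytest.approx(0.5)


class TestPartialMantel:
    def _dist(self, rng, k=9):
        m = rng.random((k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_identical_matrices_give_one(self, rng):
        a = self._dist(rng)
        c = self._dist(rng)
        res = vl.partial_mantel(a, a.copy(), c, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_confound_gives_near_zero(self, rng):
        # genetic distance equals geography (plus a little noise to avoid
        # the undefined |r|=1 case); phenotype independent -> the partial r
        # is centered on 0 (single draws scatter with only 36 pairs)
        vals = []
        for _ in range(200):
            c = self._dist(rng)
            a = c + 1e-5 * self._dist(rng)
            b = self._dist(rng)
            vals.append(
                vl._partial_r(vl._lower(a), vl._lower(b), vl._lower(c))
            )
        assert abs(np.mean(vals)) < 0.05

    def test_perfect_collinearity_rejected(self, rng):
        c = self._dist(rng)
        b = self._dist(rng)
        with pytest.raises(ValueError):
            vl.partial_mantel(c, b, c, n_perm=9, seed=0)

    def test_deterministic_under_seed(self, rng):
        a, b, c = self._dist(rng), self._dist(rng), self._dist(rng)
        r1 = vl.partial_mantel(a, b, c, n_perm=499, seed=7)
        r2 = vl.partial_mantel(a, b, c, n_perm=499, seed=7)
        assert (r1.r, r1.p_value) == (r2.r, r2.p_value)
        r3 = vl.partial_mantel(a, b, c, n_perm=499, seed=8)
        assert r3.r == r1.r  # statistic independent of the permutation seed

    def test_p_value_formula_bounds(self, rng):
        a, b, c = self._dist(rng), self._dist(rng), self._dist(rng)
        res = vl.partial_mantel(a, b, c, n_perm=199, seed=3)
        assert 1 / 200 <= res.p_value <= 1.0

    def test_observed_statistic_matches_vegan(self, rng, tmp_path):
        """Cross-check the partial correlation statistic against R vegan's
        mantel.partial on the same matrices."""
        a, b, c = self._dist(rng), self._dist(rng), self._dist(rng)
        for name, m in (("a", a), ("b", b), ("c", c)):
            np.savetxt(tmp_path / f"{name}.txt", m)
        script = tmp_path / "mantel.R"
        script.write_text(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            a <- as.dist(as.matrix(read.table(args[1])))
            b <- as.dist(as.matrix(read.table(args[2])))
            c <- as.dist(as.matrix(read.table(args[3])))
            res <- mantel.partial(a, b, c, permutations=9)
            cat(sprintf("%.12f", res$statistic))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "a.txt"),
             str(tmp_path / "b.txt"), str(tmp_path / "c.txt")],
            capture_output=True, text=True, check=True,
        )
        vegan_r = float(out.stdout.strip())
        res = vl.partial_mantel(a, b, c, n_perm=9, seed=0)
        assert res.r == pytest.approx(vegan_r, abs=1e-10)


class TestFocalRegion:
    def test_mid_contig_seven_snps(self):
        variants = make_variants(20, spacing=10)
        out = vl.focal_region_snps(variants, np.array([10]), flank=3)
        assert out.tolist() == [7, 8, 9, 10, 11, 12, 13]

    def test_contig_end_truncates(self):
        variants = make_variants(5, spacing=10)
        out = vl.focal_region_snps(variants, np.array([0]), flank=3)
        assert out.tolist() == [0, 1, 2, 3]

    def test_adjacent_focals_no_duplicates(self):
        variants = make_variants(10, spacing=10)
        out = vl.focal_region_snps(variants, np.array([4, 5]), flank=3)
        assert sorted(set(out.tolist())) == out.tolist()
        assert set(out.tolist()) == {1, 2, 3, 4, 5, 6, 7, 8}

    def test_respects_retained_subset(self):
        variants = make_variants(10, spacing=10)
        retained = np.array([0, 2, 4, 6, 8])
        out = vl.focal_region_snps(variants, np.array([4]), retained, flank=2)
        assert out.tolist() == [0, 2, 4, 6, 8]


class TestWardTree:
    def _clone_gm(self, rng, groups=3, per=4, sites=30):
        base = rng.binomial(2, 0.5, size=(sites, groups)).astype(np.int8)
        cols = []
        names = []
        for g in range(groups):
            for i in range(per):
                cols.append(base[:, g])
                names.append(f"g{g}_{i}")
        return GenotypeMatrix(np.column_stack(cols), names)

    def test_identical_samples_merge_first(self, rng):
        gm = self._clone_gm(rng, groups=2, per=2)
        out = vl.genotype_ward_tree(gm, make_variants(30, spacing=10), np.arange(30))
        Z = out["linkage"]
        assert Z[0, 2] == pytest.approx(0.0)

    def test_three_clone_groups_form_three_clades(self, rng):
        from scipy.cluster.hierarchy import fcluster

        gm = self._clone_gm(rng, groups=3, per=4)
        out = vl.genotype_ward_tree(gm, make_variants(30, spacing=10), np.arange(30))
        labels = fcluster(out["linkage"], t=3, criterion="maxclust")
        groups = [s.split("_")[0] for s in out["samples"]]
        mapping = {}
        for lab, grp in zip(labels, groups):
            mapping.setdefault(grp, set()).add(lab)
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == 3

    def test_merge_heights_nondecreasing(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 40)[:, None], (40, 10)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = -1
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(10)])
        out = vl.genotype_ward_tree(gm, make_variants(40, spacing=10), np.arange(40))
        heights = out["linkage"][:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_input_order_invariance(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 40)[:, None], (40, 8)).astype(np.int8)
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(8)])
        variants = make_variants(40, spacing=10)
        out1 = vl.genotype_ward_tree(gm, variants, np.arange(40))
        perm = rng.permutation(8)
        gm2 = gm.take_samples(perm)
        out2 = vl.genotype_ward_tree(gm2, variants, np.arange(40))
        np.testing.assert_allclose(
            np.sort(out1["linkage"][:, 2]), np.sort(out2["linkage"][:, 2]),
            atol=1e-9,
        )

    def test_newick_contains_all_samples(self, rng):
        gm = self._clone_gm(rng)
        out = vl.genotype_ward_tree(gm, make_variants(30, spacing=10), np.arange(30))
        for s in gm.samples:
            assert s in out["newick"]
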