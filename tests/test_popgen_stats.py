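"""Estimator correctness: Weir-Cockerham components, diversity, Tajima's D,
inbreeding, SFS projection."""

import math

import numpy as np
import pandas as pd
import pytest

from bergscan import popgen_stats as ps
from bergscan.io_formats import GenotypeMatrix, make_windows
from tests.conftest import make_variants


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Scalar textbook two-population Weir-Cockerham variance components,
    written independently of the package implementation (follows the
    original estimator definitions term by term)."""
    r = 2
    n_bar = (n1 + n2) / r
    c2 = ((n1 - n_bar) ** 2 + (n2 - n_bar) ** 2) / r  # squared CV numerator
    n_c = n_bar - c2 / n_bar  # equals (r n_bar - sum n^2/(r n_bar))/(r-1) at r=2
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    inner = p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


class TestSiteFst:
    def test_fixed_difference_is_one(self):
        *_, fst = ps.site_fst_components([10], [1.0], [0.0], [10], [0.0], [0.0])
        assert fst[0] == pytest.approx(1.0)

    def test_identical_heterozygous_populations_nonpositive(self):
        a, b, c, fst = ps.site_fst_components(
            [10], [0.5], [0.5], [10], [0.5], [0.5]
        )
        assert a[0] <= 0 and fst[0] <= 0

    def test_matches_independent_oracle(self, rng):
        n1 = rng.integers(2, 30, 100).astype(float)
        n2 = rng.integers(2, 30, 100).astype(float)
        p1 = rng.uniform(0.01, 0.99, 100)
        p2 = rng.uniform(0.01, 0.99, 100)
        h1 = rng.uniform(0, 1, 100) * 2 * np.minimum(p1, 1 - p1)
        h2 = rng.uniform(0, 1, 100) * 2 * np.minimum(p2, 1 - p2)
        a, b, c, _ = ps.site_fst_components(n1, p1, h1, n2, p2, h2)
        for i in range(100):
            ea, eb, ec = wc_oracle(n1[i], p1[i], h1[i], n2[i], p2[i], h2[i])
            assert a[i] == pytest.approx(ea, abs=1e-12)
            assert b[i] == pytest.approx(eb, abs=1e-12)
            assert c[i] == pytest.approx(ec, abs=1e-12)

    def test_symmetry_in_populations(self, rng):
        args = (
            [12], [0.3], [0.2], [7], [0.8], [0.1]
        )
        a1, b1, c1, f1 = ps.site_fst_components(*args)
        a2, b2, c2, f2 = ps.site_fst_components(*args[3:], *args[:3])
        assert f1[0] == pytest.approx(f2[0], abs=1e-14)


class TestWindowedFst:
    def _two_group_gm(self, rng, n_sites=60, m=6):
        d1 = rng.binomial(2, rng.uniform(0.1, 0.9, n_sites)[:, None], (n_sites, m))
        d2 = rng.binomial(2, rng.uniform(0.1, 0.9, n_sites)[:, None], (n_sites, m))
        d = np.hstack([d1, d2]).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = -1
        return GenotypeMatrix(d, [f"s{i}" for i in range(2 * m)])

    def test_ratio_of_averages_equals_component_sums(self, rng):
        gm = self._two_group_gm(rng)
        variants = make_variants(60)
        windows = make_windows({"chr1": 10_000}, size=10_000)
        g1, g2 = np.arange(6), np.arange(6, 12)
        track = ps.windowed_fst(gm, g1, g2, variants, windows)
        n1, p1, h1 = ps.group_site_counts(gm, g1)
        n2, p2, h2 = ps.group_site_counts(gm, g2)
        a, b, c, _ = ps.site_fst_components(n1, p1, h1, n2, p2, h2)
        denom = a + b + c
        ok = np.isfinite(denom) & (denom != 0)
        expected = np.nansum(a[ok]) / np.nansum(denom[ok])
        assert track["stat"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_all_fixed_differences_give_one(self):
        d = np.zeros((20, 10), dtype=np.int8)
        d[:, 5:] = 2
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(10)])
        track = ps.windowed_fst(
            gm, np.arange(5), np.arange(5, 10),
            make_variants(20), make_windows({"chr1": 3000}, 3000),
        )
        assert track["stat"].iloc[0] == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self, rng):
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 40)[:, None], (40, 6)).astype(np.int8)
        gm = GenotypeMatrix(np.hstack([base, base]), [f"s{i}" for i in range(12)])
        track = ps.windowed_fst(
            gm, np.arange(6), np.arange(6, 12),
            make_variants(40), make_windows({"chr1": 5000}, 5000),
        )
        assert track["stat"].iloc[0] <= 0

    def test_symmetric_and_empty_group_errors(self, rng):
        gm = self._two_group_gm(rng)
        variants = make_variants(60)
        windows = make_windows({"chr1": 10_000}, 10_000)
        t12 = ps.windowed_fst(gm, np.arange(6), np.arange(6, 12), variants, windows)
        t21 = ps.windowed_fst(gm, np.arange(6, 12), np.arange(6), variants, windows)
        assert t12["stat"].iloc[0] == pytest.approx(t21["stat"].iloc[0], abs=1e-14)
        with pytest.raises(ValueError):
            ps.windowed_fst(gm, np.array([], dtype=int), np.arange(6), variants, windows)


class TestDiversity:
    def test_pi_single_snp_per_bp(self):
        # one SNP, p = 0.5 over n = 4 alleles: 2*0.25*(4/3) / 50000
        d = np.array([[0, 2]], dtype=np.int8)
        gm = GenotypeMatrix(d, ["a", "b"])
        track = ps.windowed_pi(
            gm, [0, 1], make_variants(1), make_windows({"chr1": 50_000})
        )
        assert track["stat"].iloc[0] == pytest.approx((2 * 0.25 * 4 / 3) / 50_000)

    def test_pi_per_variant_site(self):
        d = np.array([[0, 2]], dtype=np.int8)
        gm = GenotypeMatrix(d, ["a", "b"])
        track = ps.windowed_pi(
            gm, [0, 1], make_variants(1), make_windows({"chr1": 50_000}),
            normalization="per_variant_site",
        )
        assert track["stat"].iloc[0] == pytest.approx(2 / 3)

    def test_pi_monomorphic_window_zero(self):
        d = np.zeros((5, 4), dtype=np.int8)
        gm = GenotypeMatrix(d, list("abcd"))
        track = ps.windowed_pi(
            gm, [0, 1, 2, 3], make_variants(5), make_windows({"chr1": 50_000})
        )
        assert track["stat"].iloc[0] == 0.0

    def test_dxy_fixed_and_half(self):
        d = np.array([[0, 0, 2, 2], [1, 1, 1, 1]], dtype=np.int8)
        gm = GenotypeMatrix(d, list("abcd"))
        track = ps.windowed_dxy(
            gm, [0, 1], [2, 3], make_variants(2),
            make_windows({"chr1": 50_000}), normalization="per_variant_site",
        )
        # site 1 fixed difference -> 1; site 2 p1=p2=0.5 -> 0.5
        assert track["stat"].iloc[0] == pytest.approx((1.0 + 0.5) / 2)

    def test_dxy_at_least_pooled_pi_identical_groups(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 50)[:, None], (50, 12)).astype(np.int8)
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(12)])
        variants = make_variants(50)
        windows = make_windows({"chr1": 10_000}, 10_000)
        dxy = ps.windowed_dxy(gm, np.arange(6), np.arange(6, 12), variants, windows,
                              normalization="per_variant_site")
        pi = ps.windowed_pi(gm, np.arange(12), variants, windows,
                            normalization="per_variant_site")
        assert dxy["stat"].iloc[0] >= pi["stat"].iloc[0] - 1e-12

    def test_dxy_symmetric(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 30)[:, None], (30, 8)).astype(np.int8)
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(8)])
        variants = make_variants(30)
        windows = make_windows({"chr1": 5000}, 5000)
        ab = ps.windowed_dxy(gm, np.arange(4), np.arange(4, 8), variants, windows)
        ba = ps.windowed_dxy(gm, np.arange(4, 8), np.arange(4), variants, windows)
        assert ab["stat"].iloc[0] == pytest.approx(ba["stat"].iloc[0], abs=1e-15)


def tajima_constants_oracle(n):
    """Brute-force constants from their defining sums."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, a2, c1 / a1, c2 / (a1**2 + a2)


class TestTajima:
    @pytest.mark.parametrize("n", [4, 10, 24])
    def test_constants_match_oracle(self, n):
        const = ps.tajima_constants(n)
        a1, a2, e1, e2 = tajima_constants_oracle(n)
        assert const.a1 == pytest.approx(a1, rel=1e-12)
        assert const.a2 == pytest.approx(a2, rel=1e-12)
        assert const.e1 == pytest.approx(e1, rel=1e-12)
        assert const.e2 == pytest.approx(e2, rel=1e-12)

    def test_single_site_value(self):
        # n = 4 alleles (2 diploids), one SNP at p = 0.5:
        # k-hat = 2*0.25*(4/3) = 2/3, S = 1, D = (k - 1/a1)/sqrt(e1)
        d = np.array([[1, 1]], dtype=np.int8)
        gm = GenotypeMatrix(d, ["a", "b"])
        track = ps.windowed_tajimas_d(
            gm, [0, 1], make_variants(1), make_windows({"chr1": 50_000})
        )
        a1, _, e1, _ = tajima_constants_oracle(4)
        expected = (2 / 3 - 1 / a1) / math.sqrt(e1)
        assert track["stat"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_window_is_na(self):
        d = np.zeros((3, 4), dtype=np.int8)
        gm = GenotypeMatrix(d, list("abcd"))
        track = ps.windowed_tajimas_d(
            gm, [0, 1, 2, 3], make_variants(3), make_windows({"chr1": 50_000})
        )
        assert np.isnan(track["stat"].iloc[0])


class TestIndividualFis:
    def test_homozygous_individual_approaches_one(self, rng):
        n_sites, m = 400, 20
        d = rng.binomial(2, 0.5, size=(n_sites, m)).astype(np.int8)
        d[:, 0] = np.where(rng.random(n_sites) < 0.5, 0, 2)  # fully homozygous
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(m)])
        fis = ps.individual_fis(gm)
        assert fis["fis"].iloc[0] > 0.9

    def test_heterozygous_individual_negative(self, rng):
        n_sites, m = 200, 20
        d = rng.binomial(2, 0.5, size=(n_sites, m)).astype(np.int8)
        d[:, 0] = 1
        gm = GenotypeMatrix(d, [f"s{i}" for i in range(m)])
        fis = ps.individual_fis(gm)
        assert fis["fis"].iloc[0] < 0

    def test_monomorphic_dataset_is_na(self):
        gm = GenotypeMatrix(np.zeros((10, 4), dtype=np.int8), list("abcd"))
        fis = ps.individual_fis(gm)
        assert fis["fis"].isna().all()


class TestProjectSfs:
    def test_identity(self, rng):
        phi = rng.random(9)
        np.testing.assert_allclose(ps.project_sfs(phi, 8), phi)

    def test_point_mass_table(self):
        phi = np.zeros(5)
        phi[2] = 1.0  # 2 of 4
        np.testing.assert_allclose(
            ps.project_sfs(phi, 2), [1 / 6, 4 / 6, 1 / 6], atol=1e-15
        )

    def test_mass_conserved(self, rng):
        phi = rng.random(13)
        assert ps.project_sfs(phi, 5).sum() == pytest.approx(phi.sum(), abs=1e-12)

    def test_composition_equals_direct(self, rng):
        phi = rng.random(13)
        via = ps.project_sfs(ps.project_sfs(phi, 8), 4)
        direct = ps.project_sfs(phi, 4)
        np.testing.assert_allclose(via, direct, atol=1e-10)

    def test_upward_projection_rejected(self):
        with pytest.raises(ValueError):
            ps.project_sfs(np.ones(5), 9)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.integers(min_value=4, max_value=24).flatmap(
        lambda n: st.tuples(
            st.lists(st.floats(0, 10, allow_nan=False), min_size=n + 1,
                     max_size=n + 1),
            st.integers(min_value=2, max_value=n),
        )
    )
)
def test_projection_mass_and_composition_properties(args):
    """Hypergeometric projection conserves mass for any non-negative
    spectrum, and projecting in two hops equals one hop."""
    spectrum, m = args
    phi = np.asarray(spectrum)
    proj = ps.project_sfs(phi, m)
    assert proj.sum() == pytest.approx(phi.sum(), abs=1e-10)
    assert (proj >= -1e-12).all()
    mid = (phi.size - 1 + m) // 2
    via = ps.project_sfs(ps.project_sfs(phi, mid), m)
    np.testing.assert_allclose(via, proj, atol=1e-10)
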