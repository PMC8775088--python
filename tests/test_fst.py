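"""Weir–Cockerham estimator, MAF computation, packing and scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import batchfst as bf
from batchfst.fst import assign_maf_bins

from _oracles import anova_theta


def random_tables(seed, n_tables=1000):
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        K = int(rng.integers(2, 7))
        n = int(rng.integers(2, 11))
        yield rng.multinomial(n, rng.dirichlet([1.0, 1.0, 1.0]), size=K)


class TestWeirCockerham:
    def test_matches_anova_oracle_on_random_tables(self):
        worst = 0.0
        checked = 0
        for counts in random_tables(seed=1):
            mine = bf.weir_cockerham_fst(bf.CenterAlleleTable(counts))
            ref = anova_theta(counts)
            assert np.isnan(mine) == np.isnan(ref)
            if not np.isnan(mine):
                worst = max(worst, abs(mine - ref))
                checked += 1
        assert checked > 500
        assert worst < 1e-10

    def test_complete_fixation_contrast_gives_one(self):
        counts = np.array([[0, 0, 5], [5, 0, 0], [5, 0, 0], [5, 0, 0]])
        assert bf.weir_cockerham_fst(bf.CenterAlleleTable(counts)) == pytest.approx(1.0)

    def test_identical_center_composition_not_positive(self):
        counts = np.array([[3, 1, 1]] * 4)
        assert bf.weir_cockerham_fst(bf.CenterAlleleTable(counts)) <= 0

    def test_monomorphic_site_undefined(self):
        counts = np.array([[5, 0, 0], [5, 0, 0]])
        assert np.isnan(bf.weir_cockerham_fst(bf.CenterAlleleTable(counts)))

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_of_centers_leaves_theta_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        counts = rng.multinomial(6, rng.dirichlet([1.0, 1.0, 1.0]), size=K)
        t1 = bf.weir_cockerham_fst(bf.CenterAlleleTable(counts))
        t2 = bf.weir_cockerham_fst(
            bf.CenterAlleleTable(counts[rng.permutation(K)])
        )
        if np.isnan(t1):
            assert np.isnan(t2)
        else:
            assert t1 == pytest.approx(t2, abs=1e-12)

    def test_vectorised_theta_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        labels = np.repeat(np.arange(4), 5)
        theta = bf.weir_cockerham_theta(G, labels)
        for v in range(50):
            counts = np.array(
                [
                    [
                        int((G[labels == k, v] == g).sum())
                        for g in (0, 1, 2)
                    ]
                    for k in range(4)
                ]
            )
            ref = bf.weir_cockerham_fst(bf.CenterAlleleTable(counts))
            if np.isnan(ref):
                assert np.isnan(theta[v])
            else:
                assert theta[v] == pytest.approx(ref, abs=1e-12)


class TestMafP:
    def test_single_copy(self):
        t = bf.CenterAlleleTable(np.array([[4, 1, 0], [5, 0, 0],
                                           [5, 0, 0], [5, 0, 0]]))
        p_ap, maf = bf.compute_maf_p(t)
        assert p_ap == pytest.approx(1 / 40)
        assert maf == pytest.approx(0.025)

    def test_fixed_alt_gives_zero_maf(self):
        t = bf.CenterAlleleTable(np.array([[0, 0, 5]] * 4))
        p_ap, maf = bf.compute_maf_p(t)
        assert p_ap == pytest.approx(1.0)
        assert maf == pytest.approx(0.0)

    def test_balanced_site_is_symmetry_point(self):
        t = bf.CenterAlleleTable(np.array([[0, 5, 0]] * 4))
        assert bf.compute_maf_p(t)[1] == pytest.approx(0.5)


class TestMaxFstPacking:
    def test_opposite_fixation_k2(self):
        assert bf.max_fst_given_maf(0.5, K=2, n=5) == pytest.approx(1.0)

    def test_quarter_maf_fills_one_center_of_four(self):
        # m = 10 copies fix center 1; the estimator on that configuration
        table = bf.packed_configuration(10, K=4, n=5)
        assert table.counts[0].tolist() == [0, 0, 5]
        assert bf.max_fst_given_maf(0.25, K=4, n=5) == pytest.approx(
            bf.weir_cockerham_fst(table)
        )

    def test_packed_configuration_scaled_fst_is_one(self):
        for K, n in [(2, 2), (4, 5), (3, 7), (6, 10)]:
            for m in range(1, K * n + 1):
                maf = m / (2 * K * n)
                fst_max = bf.max_fst_given_maf(maf, K, n)
                theta = bf.weir_cockerham_fst(bf.packed_configuration(m, K, n))
                if np.isfinite(fst_max) and fst_max > 0:
                    assert bf.scale_fst(theta, fst_max) == pytest.approx(
                        1.0, abs=1e-12
                    )
                else:
                    # degenerate designs where one copy cannot differentiate
                    assert theta == fst_max or abs(theta - fst_max) < 1e-15

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            bf.max_fst_given_maf(0.7, K=4, n=5)
        assert np.isnan(bf.max_fst_given_maf(0.0, K=4, n=5))


class TestScaleFst:
    @pytest.mark.parametrize(
        "raw,mx,expected", [(0.4, 0.4, 1.0), (-0.1, 0.4, 0.0), (0.2, 0.4, 0.5)]
    )
    def test_examples(self, raw, mx, expected):
        assert bf.scale_fst(raw, mx) == pytest.approx(expected)

    def test_undefined_maximum(self):
        assert np.isnan(bf.scale_fst(0.3, float("nan")))


class TestSubsample:
    def _meta(self):
        rows = []
        for center, size in zip("WXYZ", (30, 25, 5, 2)):
            for i in range(size):
                rows.append((f"{center}{i}", "P1", "C1", center))
        return pd.DataFrame(
            rows, columns=["sample", "pop", "super_pop", "center"]
        ).set_index("sample")

    def test_small_centers_excluded(self):
        sub = bf.subsample_centers(self._meta(), "P1", n=5, rng=0)
        assert sorted(sub["center"].unique()) == ["W", "X", "Y"]
        assert (sub.groupby("center").size() == 5).all()
        assert sub.attrs["excluded_centers"] == ["Z"]

    def test_seed_reproducibility(self):
        a = bf.subsample_centers(self._meta(), "P1", n=5, rng=123)
        b = bf.subsample_centers(self._meta(), "P1", n=5, rng=123)
        assert list(a.index) == list(b.index)

    def test_fewer_than_two_centers_rejected(self):
        meta = self._meta()
        with pytest.raises(ValueError):
            bf.subsample_centers(meta, "P1", n=40)


class TestMafSummary:
    def test_bins_are_half_open_with_closed_top(self):
        maf = np.array([0.0, 0.049, 0.05, 0.26, 0.45, 0.5])
        assert assign_maf_bins(maf).tolist() == [0.0, 0.0, 0.05, 0.25, 0.45, 0.45]

    def test_monotone_decreasing_means_give_rho_minus_one(self):
        rec = pd.DataFrame(
            {"maf_p": [0.1] * 3 + [0.2] * 3 + [0.3] * 3,
             "fst_scaled": [0.9] * 3 + [0.5] * 3 + [0.1] * 3}
        )
        *_, rho, _ = bf.summarize_by_maf(rec)
        assert rho == pytest.approx(-1.0)

    def test_constant_means_give_zero_rho(self):
        rec = pd.DataFrame({"maf_p": [0.1, 0.2, 0.3], "fst_scaled": [0.4] * 3})
        *_, rho, _ = bf.summarize_by_maf(rec)
        assert rho == 0.0

    def test_scan_emits_values_in_unit_interval(self, small_cohort):
        gm, meta = small_cohort.genotypes, small_cohort.metadata
        scan = bf.ScaledFstScan(n_permutations=2, random_state=0)
        scan.fit_from_cohort(gm, meta, "POP1")
        assert scan.records_["fst_scaled"].between(0, 1).all()
        assert scan.records_["maf_p"].between(0, 0.5).all()
        assert (scan.records_["fst_max"] > 0).all()
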