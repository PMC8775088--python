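"""Synthetic-cohort generator: determinism, error model, SFS properties."""

import numpy as np
import pytest
from scipy import stats

import batchfst as bf


def _spec(**kw):
    base = dict(
        n_variants=2000,
        n_populations=2,
        n_continents=1,
        samples_per_pop=50,
        seed=1,
    )
    base.update(kw)
    return bf.CohortSpec(**base)


class TestGenerateCohort:
    def test_no_error_process_leaves_truth_empty(self):
        c = bf.generate_cohort(_spec(center_error_rates={}))
        assert c.truth.error_created_variants.size == 0
        assert all(v == 0 for v in c.truth.per_center_errors.values())

    def test_same_seed_reproduces_identical_cohort(self):
        a = bf.generate_cohort(_spec(center_error_rates={"BI": 0.01}, seed=9))
        b = bf.generate_cohort(_spec(center_error_rates={"BI": 0.01}, seed=9))
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert a.genotypes.variants.equals(b.genotypes.variants)
        assert a.metadata.equals(b.metadata)
        assert np.array_equal(
            a.truth.error_variant_idx, b.truth.error_variant_idx
        )

    def test_error_rate_within_binomial_tolerance(self):
        # 5,000 variants x 200 samples, e_c = 0.01 for one center
        spec = _spec(
            n_variants=5000,
            n_populations=4,
            n_continents=2,
            samples_per_pop=50,
            center_error_rates={"BGI": 0.01},
            seed=3,
        )
        c = bf.generate_cohort(spec)
        n_eligible = c.truth.n_eligible_homref["BGI"]
        n_flips = c.truth.per_center_errors["BGI"]
        rate = n_flips / n_eligible
        sd = np.sqrt(0.01 * 0.99 / n_eligible)
        assert abs(rate - 0.01) < 3 * sd
        assert all(
            c.truth.per_center_errors[ctr] == 0 for ctr in ("BCM", "BI", "WUGSC")
        )

    def test_ac_flag_equals_alt_copy_sum(self, small_cohort):
        gm = small_cohort.genotypes
        assert np.array_equal(gm.recompute_ac(), gm.variants["ac"].to_numpy())

    def test_output_is_polymorphic(self, small_cohort):
        small_cohort.genotypes.validate()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            _spec(center_error_rates={"BCM": 1.5})
        with pytest.raises(ValueError):
            _spec(n_variants=0)
        with pytest.raises(ValueError):
            bf.CohortSpec(n_populations=1, n_continents=2)

    def test_center_with_zero_samples_rejected(self):
        w = np.zeros((1, 4))
        w[0, 0] = 1.0  # every sample to the first center
        with pytest.raises(ValueError, match="zero samples"):
            bf.generate_cohort(
                _spec(n_populations=1, center_assignment_weights=w)
            )


class TestSingletonExchangeability:
    def test_equal_error_rates_keep_centers_exchangeable(self):
        # Kruskal-Wallis across centers at alpha=0.01 rejects in <=5% of
        # replicates when no center-specific error process exists.
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            c = bf.generate_cohort(
                bf.CohortSpec(
                    n_variants=800,
                    n_populations=2,
                    n_continents=1,
                    samples_per_pop=30,
                    seed=10_000 + seed,
                )
            )
            counts = bf.count_singletons(c.genotypes)
            groups = [
                counts[(c.metadata["center"] == ctr).to_numpy()]
                for ctr in sorted(c.metadata["center"].unique())
            ]
            p = stats.kruskal(*groups).pvalue
            rejections += p < 0.01
        assert rejections <= 5

    def test_singletons_monotone_in_error_rate(self):
        # mean per-center singleton count non-decreasing in e_c, 10 replicates
        rates = [0.0, 0.001, 0.005, 0.01]
        means = []
        for e in rates:
            tot = 0.0
            for seed in range(10):
                c = bf.generate_cohort(
                    bf.CohortSpec(
                        n_variants=800,
                        n_populations=1,
                        n_continents=1,
                        samples_per_pop=60,
                        center_error_rates={"BCM": e},
                        seed=500 + seed,
                    )
                )
                counts = bf.count_singletons(c.genotypes)
                mask = (c.metadata["center"] == "BCM").to_numpy()
                tot += counts[mask].mean()
            means.append(tot / 10)
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestSprimeTable:
    def test_zero_fraction_gives_empty_table(self, small_cohort):
        t = bf.generate_sprime_table(small_cohort, 0.0, seed=1)
        assert t.empty

    def test_full_fraction_covers_every_variant_per_population(self, small_cohort):
        t = bf.generate_sprime_table(small_cohort, 1.0, seed=1)
        nv = small_cohort.genotypes.n_variants
        for pop, grp in t.groupby("POP"):
            assert len(grp) == nv
            assert grp["POS"].is_unique
        assert set(t["POP"]) == set(small_cohort.metadata["pop"])

    def test_fixed_seed_reproducible(self, small_cohort):
        a = bf.generate_sprime_table(small_cohort, 0.2, seed=5)
        b = bf.generate_sprime_table(small_cohort, 0.2, seed=5)
        assert a.equals(b)

    def test_fraction_out_of_range_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            bf.generate_sprime_table(small_cohort, 1.2, seed=0)
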