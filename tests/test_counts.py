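"""Rare-event counters against hand-enumerated expectations."""

import numpy as np
import pandas as pd
import pytest

import batchfst as bf

# Hand enumeration for the 10-variant fixture (samples A, B, C, D):
#   LoF: pos 700 only (three-way deleterious consensus, no hom-alt);
#        pos 800 excluded by the hom-alt rule, pos 900 lacks consensus.
#   benign: pos 1000 only (three-way benign consensus); counts ALT copies.
#   singletons: pos 100-500 (AC=1); carriers A, B, C, D, A.
#   derived singletons: pos 100 only (AA == REF); 200/300/400 have
#        degenerate AA codes, 500 has AA == ALT (ancestral ALT copy).
#   introgressed: POP1 gets ALT at 100 and ALT at 600; POP2 gets REF at
#        600 and ALT at 1000; rows at 99999 (unmatched) and 700 with a
#        foreign allele are skipped on read.
EXPECTED = pd.DataFrame(
    {
        "n_lof": [1, 0, 1, 0],
        "n_benign": [0, 0, 2, 1],
        "n_singletons": [2, 1, 1, 1],
        "n_derived_singletons": [1, 0, 0, 0],
        "n_introgressed": [1, 2, 4, 3],
    },
    index=pd.Index(list("ABCD"), name="sample"),
)


class TestHandFixture:
    def test_counts_match_hand_enumeration(self, hand_cohort):
        gm, meta, sprime = hand_cohort
        table = bf.build_count_table(gm, meta, sprime)
        got = table[EXPECTED.columns].astype(int)
        pd.testing.assert_frame_equal(got, EXPECTED)

    def test_lof_and_benign_sets_disjoint(self, hand_cohort):
        gm, _, _ = hand_cohort
        assert not set(bf.classify_lof(gm)) & set(bf.classify_benign(gm))

    def test_lof_rules(self, hand_cohort):
        gm, _, _ = hand_cohort
        pos = gm.variants["pos"].to_numpy()
        assert pos[bf.classify_lof(gm)].tolist() == [700]
        assert pos[bf.classify_benign(gm)].tolist() == [1000]


class TestSingletonRules:
    def _matrix(self, genotypes, aa=None, ref=None, alt=None):
        g = np.asarray(genotypes, dtype=np.int8)
        nv = g.shape[0]
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, nv + 1) * 10,
                "ref": ref or ["A"] * nv,
                "alt": alt or ["G"] * nv,
                "ac": np.where(g == -1, 0, g).sum(axis=1),
                "aa": aa or ["A"] * nv,
                "p1": "absent",
                "p2": "absent",
                "p3": "absent",
                "coding": False,
            }
        )
        return bf.GenotypeMatrix(
            samples=[f"s{i}" for i in range(g.shape[1])],
            variants=variants,
            genotypes=g,
        )

    def test_unique_carrier_scores_all_its_singletons(self):
        g = [[1, 0, 0]] * 4
        gm = self._matrix(g)
        assert bf.count_singletons(gm).tolist() == [4, 0, 0]

    def test_ac2_hom_alt_site_is_not_a_singleton(self):
        gm = self._matrix([[2, 0, 0]])
        assert bf.count_singletons(gm).tolist() == [0, 0, 0]

    def test_singleton_conservation(self, small_cohort):
        gm = small_cohort.genotypes
        n_singleton_variants = int((gm.variants["ac"] == 1).sum())
        assert bf.count_singletons(gm).sum() == n_singleton_variants

    def test_derived_requires_ancestral_equal_ref(self):
        gm = self._matrix(
            [[1, 0], [0, 1], [1, 0]],
            aa=["A", ".", "G"],  # derived / no-alignment / ALT ancestral
        )
        assert bf.count_derived_singletons(gm).tolist() == [1, 0]

    def test_aa_matching_neither_allele_excluded(self):
        gm = self._matrix([[1, 0]], aa=["T"])
        assert bf.count_derived_singletons(gm).tolist() == [0, 0]

    def test_aa_comparison_case_insensitive(self):
        gm = self._matrix([[1, 0]], aa=["a"])
        assert bf.count_derived_singletons(gm).tolist() == [1, 0]

    def test_derived_bounded_by_singletons(self, small_cohort):
        gm = small_cohort.genotypes
        assert (
            bf.count_derived_singletons(gm) <= bf.count_singletons(gm)
        ).all()


class TestIntrogressed:
    def test_dosage_of_introgressed_allele(self, hand_cohort):
        gm, meta, _ = hand_cohort
        # het for an ALT-introgressed allele -> 1; hom -> 2; other pop -> 0
        sp = {("1", 600, "POP1"): "T"}
        assert bf.count_introgressed(gm, sp, meta).tolist() == [0, 2, 0, 0]
        sp = {("1", 600, "POP2"): "G"}  # REF introgressed
        assert bf.count_introgressed(gm, sp, meta).tolist() == [0, 0, 2, 2]


class TestMonotoneUnderErrors:
    def test_center_mean_singletons_track_error_rate(self):
        rates = [0.0, 0.005, 0.01]
        means = []
        for e in rates:
            acc = 0.0
            for seed in range(10):
                c = bf.generate_cohort(
                    bf.CohortSpec(
                        n_variants=600,
                        n_populations=1,
                        n_continents=1,
                        samples_per_pop=40,
                        center_error_rates={"BI": e},
                        seed=900 + seed,
                    )
                )
                counts = bf.count_singletons(c.genotypes)
                acc += counts[(c.metadata["center"] == "BI").to_numpy()].mean()
            means.append(acc / 10)
        assert means == sorted(means)
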