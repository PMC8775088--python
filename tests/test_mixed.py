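"""Mixed-model center contrast: recovery, nulls, and an lme4 cross-check."""

import subprocess

import numpy as np
import pytest

import batchfst as bf


class TestCenterEffectModel:
    def test_recovers_known_multiplicative_effect(self):
        # exp(0.13) effect on one center, 500 samples
        counts = bf.simulate_count_table(
            center_log_effects={"BI": 0.13}, seed=11
        )
        res = bf.fit_center_mixed_model(counts, "n_singletons")
        beta = res.coefficients.loc["center[BI]", "coef"]
        assert abs(beta - 0.13) <= 0.3 * 0.13
        assert res.lrt_p < 0.01
        assert res.lrt_stat >= 0
        assert res.lrt_df == 3

    def test_reference_center_is_alphabetically_first(self):
        counts = bf.simulate_count_table(seed=2)
        res = bf.fit_center_mixed_model(counts, "n_singletons")
        assert res.reference_center == "BCM"
        assert "center[BCM]" not in res.coefficients.index

    def test_null_counts_give_large_p(self):
        counts = bf.simulate_count_table(seed=3)
        res = bf.fit_center_mixed_model(counts, "n_singletons")
        assert res.lrt_p > 1e-4  # no effect injected

    def test_constant_response_degenerates_cleanly(self):
        counts = bf.simulate_count_table(seed=4)
        counts["n_singletons"] = 100
        res = bf.fit_center_mixed_model(counts, "n_singletons")
        centers = [t for t in res.coefficients.index if t != "Intercept"]
        assert all(res.coefficients.loc[t, "coef"] == 0 for t in centers)
        assert res.vc_continent == 0 and res.vc_population == 0

    def test_zero_counts_policies(self):
        counts = bf.simulate_count_table(seed=5)
        counts.iloc[0, counts.columns.get_loc("n_singletons")] = 0
        with pytest.raises(ValueError, match="add_one"):
            bf.fit_center_mixed_model(counts, "n_singletons",
                                      zero_policy="error")
        res = bf.fit_center_mixed_model(counts, "n_singletons")
        assert res.n_dropped_zero == 1
        res1 = bf.fit_center_mixed_model(counts, "n_singletons",
                                         zero_policy="add_one")
        assert res1.n_dropped_zero == 0

    def test_center_missing_from_a_population_excluded(self):
        counts = bf.simulate_count_table(seed=6)
        # center present in only one population must not enter the contrast
        extra = counts.iloc[:3].copy()
        extra.index = [f"X{i}" for i in range(3)]
        extra["center"] = "RAREC"
        extra["pop"] = counts["pop"].iloc[0]
        res = bf.fit_center_mixed_model(
            __import__("pandas").concat([counts, extra]), "n_singletons"
        )
        assert "RAREC" not in res.centers_used

    def test_sklearn_param_interface(self):
        est = bf.CenterEffectModel(zero_policy="add_one")
        assert est.get_params()["zero_policy"] == "add_one"
        est.set_params(zero_policy="drop")
        assert est.zero_policy == "drop"


class TestAgainstLme4:
    def test_fixed_effects_match_lme4(self, tmp_path):
        counts = bf.simulate_count_table(
            center_log_effects={"BI": 0.13},
            pops_per_continent=3,
            samples_per_pop=30,
            seed=11,
        )
        res = bf.fit_center_mixed_model(counts, "n_singletons")
        csv = tmp_path / "counts.csv"
        counts.reset_index().to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "d$logS <- log(d$n_singletons)\n"
            "m <- lmer(logS ~ center + (1|super_pop/pop), data=d, REML=FALSE)\n"
            "fe <- fixef(m)\n"
            "cat(sprintf('%s=%.10f\\n', names(fe), fe))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout
        ref = dict(line.strip().split("=") for line in out.strip().splitlines())
        pairs = {
            "Intercept": "(Intercept)",
            "center[BGI]": "centerBGI",
            "center[BI]": "centerBI",
            "center[WUGSC]": "centerWUGSC",
        }
        for term, rname in pairs.items():
            assert res.coefficients.loc[term, "coef"] == pytest.approx(
                float(ref[rname]), abs=5e-3
            )
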