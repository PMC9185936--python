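"""Line x tester ANOVA and combining-ability estimator checks.

The independent oracle for sums of squares is statsmodels' sequential
(Type I) anova_lm on the identical model formula; the implementation
itself builds its own nested least-squares fits.
"""

import numpy as np
import pandas as pd
import pytest

from lxt.combining_ability import (
    AnovaTable,
    anova_line_by_tester,
    estimate_gca_sca,
    estimate_variance_components,
    repeatability,
    significance_code,
)
from lxt.synthetic_data import TrialSimConfig, simulate_trial

from conftest import small_trial_config, yield_only_spec


def _toy_frame(cell_values: dict[tuple[str, str], float], reps=2, envs=("E1",)):
    rows = []
    for env in envs:
        for rep in range(1, reps + 1):
            for (line, tester), val in cell_values.items():
                rows.append(
                    {
                        "environment": env,
                        "condition": "non_infested",
                        "replicate": rep,
                        "block": "B1",
                        "entry": f"{line}x{tester}",
                        "entry_role": "testcross",
                        "line": line,
                        "tester": tester,
                        "yield": val,
                    }
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_df_match_closed_forms(self):
        # complete blocks: no aliasing between block and treatment spaces
        cfg = small_trial_config(seed=7, lattice_blocks=1, lattice_block_size=60)
        frame, _ = simulate_trial(cfg)
        an = anova_line_by_tester(frame, "yield", "non_infested")
        l, t, e, r = cfg.n_lines, cfg.n_testers, 2, cfg.replicates
        assert an.balanced
        assert an.df("environment") == e - 1
        assert an.df("rep_in_env") == e * (r - 1)
        assert an.df("block_in_rep_env") == 0
        assert an.df("line_gca") == l - 1
        assert an.df("tester_gca") == t - 1
        assert an.df("line_x_tester_sca") == (l - 1) * (t - 1)
        assert an.df("hybrid") == l * t - 1
        assert an.df("line_x_env") == (l - 1) * (e - 1)
        assert an.df("hybrid_x_env") == (l * t - 1) * (e - 1)
        assert an.df("error") == (l * t - 1) * e * (r - 1)
        total_df = int(an.table["df"].sum()) - an.df("hybrid") - an.df("hybrid_x_env")
        assert total_df == an.n_obs - 1

    def test_lattice_df_total_and_hybrid_partition(self, small_trial):
        # incomplete blocks absorb df sequentially; totals still add up
        _, frame, _ = small_trial
        an = anova_line_by_tester(frame, "yield", "non_infested")
        total_df = int(an.table["df"].sum()) - an.df("hybrid") - an.df("hybrid_x_env")
        assert total_df == an.n_obs - 1
        assert an.df("hybrid") == (
            an.df("line_gca") + an.df("tester_gca") + an.df("line_x_tester_sca")
        )

    def test_zero_sca_zero_noise_gives_zero_sca_ss(self):
        traits = yield_only_spec(
            sigma2_sca=0.0,
            sigma2_error=0.0,
            sigma2_sca_env=0.0,
            sigma2_line_env=0.0,
            sigma2_tester_env=0.0,
        )
        cfg = small_trial_config(seed=5, traits=traits)
        frame, _ = simulate_trial(cfg)
        an = anova_line_by_tester(frame, "yield", "non_infested")
        assert an.ss("line_x_tester_sca") == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sequential_ss_match_nested_regression_oracle(self, seed):
        """Every reported SS equals the residual-SS difference of the
        corresponding nested least-squares fits (statsmodels OLS)."""
        import statsmodels.formula.api as smf

        cfg = small_trial_config(seed=seed, n_lines=4)
        frame, _ = simulate_trial(cfg)
        sub = frame[
            (frame["condition"] == "infested") & (frame["entry_role"] == "testcross")
        ].rename(columns={"yield": "y"}).copy()
        sub["rep_id"] = sub["environment"] + ":" + sub["replicate"].astype(str)
        sub["block_id"] = sub["rep_id"] + ":" + sub["block"]
        sub["hyb_id"] = sub["line"] + ":" + sub["tester"]
        sub["le_id"] = sub["line"] + "@" + sub["environment"]
        sub["te_id"] = sub["tester"] + "@" + sub["environment"]
        sub["lte_id"] = sub["hyb_id"] + "@" + sub["environment"]
        terms = [
            ("C(environment)", "environment"),
            ("C(rep_id)", "rep_in_env"),
            ("C(block_id)", "block_in_rep_env"),
            ("C(line)", "line_gca"),
            ("C(tester)", "tester_gca"),
            ("C(hyb_id)", "line_x_tester_sca"),
            ("C(le_id)", "line_x_env"),
            ("C(te_id)", "tester_x_env"),
            ("C(lte_id)", "line_x_tester_x_env"),
        ]
        an = anova_line_by_tester(frame, "yield", "infested")
        scale = an.ss("environment") + 1.0
        rhs, prev = "1", smf.ols("y ~ 1", data=sub).fit()
        for patsy_term, ours in terms:
            rhs = f"{rhs} + {patsy_term}"
            fit = smf.ols(f"y ~ {rhs}", data=sub).fit()
            ss = prev.ssr - fit.ssr
            df = int(prev.df_resid - fit.df_resid)
            assert an.ss(ours) == pytest.approx(ss, rel=1e-8, abs=1e-8 * scale), ours
            assert an.df(ours) == df, ours
            prev = fit
        assert an.ss("error") == pytest.approx(prev.ssr, rel=1e-8, abs=1e-8 * scale)
        assert an.df("error") == int(prev.df_resid)

    def test_hybrid_ss_additivity_balanced(self, small_trial):
        _, frame, _ = small_trial
        for condition in ("infested", "non_infested"):
            an = anova_line_by_tester(frame, "yield", condition)
            parts = ["line_gca", "tester_gca", "line_x_tester_sca"]
            assert an.ss("hybrid") == pytest.approx(
                sum(an.ss(p) for p in parts), rel=1e-8
            )
            env_parts = ["line_x_env", "tester_x_env", "line_x_tester_x_env"]
            assert an.ss("hybrid_x_env") == pytest.approx(
                sum(an.ss(p) for p in env_parts), rel=1e-8
            )

    def test_single_environment_omits_env_interactions(self):
        cfg = small_trial_config(seed=9, environments={"non_infested": 1})
        frame, _ = simulate_trial(cfg)
        an = anova_line_by_tester(frame, "yield", "non_infested")
        assert "line_x_env" not in an.table.index
        assert any("single environment" in n for n in an.notes)

    def test_unbalanced_core_flags_and_still_fits(self, small_trial):
        _, frame, _ = small_trial
        sub = frame[frame["condition"] == "non_infested"]
        drop_one = sub[sub["entry_role"] == "testcross"].index[:1]
        an = anova_line_by_tester(frame.drop(index=drop_one), "yield", "non_infested")
        assert not an.balanced
        assert np.isfinite(an.ms("error"))


class TestEffects:
    def test_additive_toy_table(self):
        frame = _toy_frame(
            {("L1", "T1"): 10, ("L1", "T2"): 12, ("L2", "T1"): 14, ("L2", "T2"): 16}
        )
        res = estimate_gca_sca(frame, "yield", "non_infested")
        assert res.grand_mean == pytest.approx(13)
        assert res.gca_line["L1"] == pytest.approx(-2)
        assert res.gca_line["L2"] == pytest.approx(2)
        assert res.gca_tester["T1"] == pytest.approx(-1)
        assert res.gca_tester["T2"] == pytest.approx(1)
        assert np.allclose(res.sca.to_numpy(), 0.0, atol=1e-12)
        assert res.hsgca.loc["L1", "T1"] == pytest.approx(-2)

    @pytest.mark.parametrize("condition", ["infested", "non_infested"])
    def test_centering_identities(self, small_trial, condition):
        _, frame, _ = small_trial
        res = estimate_gca_sca(frame, "yield", condition)
        assert res.gca_line.sum() == pytest.approx(0, abs=1e-8)
        assert res.gca_tester.sum() == pytest.approx(0, abs=1e-8)
        assert np.allclose(res.sca.sum(axis=0), 0, atol=1e-8)
        assert np.allclose(res.sca.sum(axis=1), 0, atol=1e-8)
        # two testers: exact antisymmetry of tester GCA and of SCA columns
        t1, t2 = res.gca_tester.index
        assert res.gca_tester[t1] == pytest.approx(-res.gca_tester[t2])
        assert np.allclose(res.sca[t1], -res.sca[t2], atol=1e-8)

    def test_noise_free_truth_recovery_is_exact(self):
        traits = yield_only_spec(
            sigma2_env=0.0,
            sigma2_rep=0.0,
            sigma2_block=0.0,
            sigma2_line_env=0.0,
            sigma2_tester_env=0.0,
            sigma2_sca_env=0.0,
            sigma2_error=0.0,
        )
        cfg = small_trial_config(seed=13, traits=traits)
        frame, truth = simulate_trial(cfg)
        res = estimate_gca_sca(frame, "yield", "non_infested")
        t = truth["non_infested"]["yield"]
        assert np.allclose(res.gca_line[t["gca_line"].index], t["gca_line"], atol=1e-9)
        assert np.allclose(
            res.sca.loc[t["sca"].index, t["sca"].columns], t["sca"], atol=1e-9
        )

    def test_recovery_correlation_matches_analytic_attenuation(self):
        """Observed truth-recovery correlation for line GCA agrees with the
        attenuation sqrt(s2_g / (s2_g + V)) predicted from the noise that
        does not cancel in the line marginal mean."""
        corrs = []
        cfg0 = TrialSimConfig(seed=0)
        spec = cfg0.traits["yield"]
        e = cfg0.environments["non_infested"]
        n_plots = cfg0.n_testers * e * cfg0.replicates
        v = (
            spec.sigma2_error * (1 - 1 / cfg0.n_lines) / n_plots
            + spec.sigma2_block * (1 - 1 / cfg0.lattice_blocks) / n_plots
        )
        rho = np.sqrt(spec.sigma2_gca_line / (spec.sigma2_gca_line + v))
        for seed in range(6):
            frame, truth = simulate_trial(TrialSimConfig(seed=seed))
            res = estimate_gca_sca(frame, "yield", "non_infested")
            tg = truth["non_infested"]["yield"]["gca_line"]
            corrs.append(np.corrcoef(res.gca_line[tg.index], tg)[0, 1])
        se = (1 - rho**2) / np.sqrt((cfg0.n_lines - 3) * len(corrs))
        assert np.mean(corrs) == pytest.approx(rho, abs=4 * se + 0.02)

    def test_se_formulas_and_significance(self, small_trial):
        cfg, frame, _ = small_trial
        an = anova_line_by_tester(frame, "yield", "non_infested")
        res = estimate_gca_sca(frame, "yield", "non_infested", anova=an)
        r, e = an.n_rep, an.n_env
        mse = an.ms("error")
        assert res.se_gca_line == pytest.approx(np.sqrt(mse / (r * e * cfg.n_testers)))
        assert res.se_gca_tester == pytest.approx(np.sqrt(mse / (r * e * cfg.n_lines)))
        assert res.se_sca == pytest.approx(np.sqrt(mse / (r * e)))
        assert ((res.p_gca_line >= 0) & (res.p_gca_line <= 1)).all()

    def test_zero_error_df_returns_effects_without_inference(self):
        frame = _toy_frame(
            {("L1", "T1"): 10, ("L1", "T2"): 12, ("L2", "T1"): 14, ("L2", "T2"): 16},
            reps=1,
        )
        res = estimate_gca_sca(frame, "yield", "non_infested")
        assert res.gca_line["L2"] == pytest.approx(2)
        assert np.isnan(res.se_gca_line)


def _make_anova_table(ms: dict[str, float], df: dict[str, int], e, r, l, t):
    rows = {
        src: {"df": df.get(src, 1), "ss": ms[src] * df.get(src, 1), "ms": ms[src],
              "f": np.nan, "p": np.nan}
        for src in ms
    }
    return AnovaTable(
        trait="yield",
        condition="non_infested",
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_env=e,
        n_rep=r,
        n_lines=l,
        n_testers=t,
        n_obs=l * t * e * r,
        balanced=True,
    )


class TestVarianceComponents:
    def _table(self, **ms_overrides):
        ms = dict(
            line_gca=50.0,
            tester_gca=40.0,
            line_x_tester_sca=20.0,
            line_x_env=10.0,
            tester_x_env=8.0,
            line_x_tester_x_env=6.0,
            hybrid=40.0,
            hybrid_x_env=8.0,
            error=4.0,
        )
        ms.update(ms_overrides)
        df = dict(line_gca=19, tester_gca=1, line_x_tester_sca=19, error=100)
        return _make_anova_table(ms, df, e=4, r=2, l=20, t=2)

    def test_null_sca_when_ms_equal(self):
        an = self._table(line_x_tester_sca=6.0)  # equals the three-way MS
        vc = estimate_variance_components(an)
        assert vc.sigma2_sca == 0.0

    def test_moment_formulas(self):
        an = self._table()
        vc = estimate_variance_components(an)
        r, e, l, t = 2, 4, 20, 2
        assert vc.sigma2_sca == pytest.approx((20.0 - 6.0) / (r * e))
        assert vc.sigma2_gca_line == pytest.approx((50.0 - 10.0) / (r * e * t))
        assert vc.sigma2_gca_tester == pytest.approx((40.0 - 8.0) / (r * e * l))
        assert vc.sigma2_sca_x_env == pytest.approx((6.0 - 4.0) / r)
        # F = 1 (both parents fully inbred): additive = 2 x summed GCA
        assert vc.sigma2_a == pytest.approx(2 * (vc.sigma2_gca_line + vc.sigma2_gca_tester))
        assert vc.sigma2_d == pytest.approx(vc.sigma2_sca)
        assert 0 <= vc.h2_narrow <= 1

    def test_negative_estimates_truncated_and_flagged(self):
        an = self._table(line_x_tester_sca=2.0)  # below the three-way MS
        vc = estimate_variance_components(an)
        assert vc.sigma2_sca == 0.0
        assert "sigma2_sca" in vc.truncated

    def test_h2_decreases_with_error(self):
        # pin every variance component by shifting the MS chain with the
        # error MS, so only the residual term in the denominator moves
        h2s = []
        for v in (1.0, 4.0, 16.0):
            lte = v + 2.0
            ms = dict(
                error=v,
                line_x_tester_x_env=lte,
                line_x_env=lte + 4.0,
                tester_x_env=lte + 2.0,
                line_x_tester_sca=lte + 14.0,
                line_gca=lte + 4.0 + 40.0,
                tester_gca=lte + 2.0 + 128.0,
            )
            h2s.append(estimate_variance_components(self._table(**ms)).h2_narrow)
        assert h2s[0] > h2s[1] > h2s[2]

    def test_f_coefficient_changes_scaling(self):
        an = self._table()
        vc0 = estimate_variance_components(an, f_coefficient=0.0)
        vc1 = estimate_variance_components(an, f_coefficient=1.0)
        assert vc0.sigma2_a == pytest.approx(2 * vc1.sigma2_a)
        assert vc0.sigma2_d == pytest.approx(4 * vc1.sigma2_d)


class TestRepeatability:
    def _table(self, ms_h, ms_he, mse):
        ms = dict(hybrid=ms_h, hybrid_x_env=ms_he, error=mse,
                  line_gca=1, tester_gca=1, line_x_tester_sca=1,
                  line_x_env=1, tester_x_env=1, line_x_tester_x_env=1)
        return _make_anova_table(ms, {}, e=4, r=2, l=20, t=2)

    def test_zero_when_hybrid_ms_equals_interaction(self):
        assert repeatability(self._table(8.0, 8.0, 4.0)) == 0.0

    def test_limit_to_one_as_noise_vanishes(self):
        r_small = repeatability(self._table(100.0, 1e-9, 1e-9))
        assert r_small == pytest.approx(1.0, abs=1e-6)

    def test_matches_plug_in_truth_on_simulation(self):
        """R over simulated trials agrees with the plug-in true value.

        Uses complete blocks and zero block variance so the expected
        mean squares compose exactly from the configured components;
        the hybrid stratum mixes line, tester and cross effects with the
        weights of the factorial decomposition."""

        def composite(l, t, s_l, s_t, s_lt):
            return (
                t * (l - 1) * s_l + l * (t - 1) * s_t + (l - 1) * (t - 1) * s_lt
            ) / (l * t - 1)

        l, e = 20, 4

        def make_cfg(seed):
            return small_trial_config(
                seed=seed,
                n_lines=l,
                environments={"non_infested": e},
                lattice_blocks=1,
                lattice_block_size=60,
                traits=yield_only_spec(sigma2_block=0.0),
            )

        cfg0 = make_cfg(0)
        spec = cfg0.traits["yield"]
        t, r = cfg0.n_testers, cfg0.replicates
        s2_h = composite(
            l, t, spec.sigma2_gca_line, spec.sigma2_gca_tester, spec.sigma2_sca
        )
        s2_he = composite(
            l, t, spec.sigma2_line_env, spec.sigma2_tester_env, spec.sigma2_sca_env
        )
        # the generator draws G x E exactly centered over environments, so
        # the interaction cancels from entry means and the moment estimator
        # of the hybrid component over-corrects by s2_he/e
        num = s2_h - s2_he / e
        r_plug = num / (num + s2_he / e + spec.sigma2_error / (r * e))
        vals = []
        for seed in range(20):
            frame, _ = simulate_trial(make_cfg(100 + seed))
            an = anova_line_by_tester(frame, "yield", "non_infested")
            vals.append(repeatability(an))
        # tolerance covers Monte-Carlo error plus the small-sample
        # (Jensen) bias of a ratio of mean squares at ~39 df
        assert np.mean(vals) == pytest.approx(r_plug, abs=0.08)


def test_significance_ladder_codes():
    assert significance_code(0.2) == ""
    assert significance_code(0.03) == "*"
    assert significance_code(0.005) == "**"
    assert significance_code(5e-4) == "***"
    assert significance_code(5e-5) == "†"
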