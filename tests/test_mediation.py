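"""Counterfactual mediation: closed-form checks, Monte-Carlo oracle,
moderation and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import lcpain as lp
from lcpain.mediation import Effect, MediationResult, MediationSpec


def linear_system(n, a, b, c, seed, sd_m=1.0, sd_y=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    m = a * x + rng.normal(0, sd_m, n)
    y = c * x + b * m + rng.normal(0, sd_y, n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


class TestLinearHarness:
    def test_acme_equals_product_of_coefficients(self):
        a, b, c = 0.8, 0.5, 0.3
        df = linear_system(5000, a, b, c, seed=0)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             control=0.0, treat=2.0, n_boot=60, n_sims=5,
                             seed=1, outcome_family="linear")
        res = lp.mediate(df, spec)
        assert res.acme.point == pytest.approx(a * b * 2.0, abs=0.1)
        assert res.ade.point == pytest.approx(c * 2.0, abs=0.1)

    def test_acme_plus_ade_equals_total_exactly_under_identity_link(self):
        df = linear_system(800, 0.6, 0.4, 0.2, seed=2)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             control=0.0, treat=1.0, n_boot=20, n_sims=3,
                             seed=3, outcome_family="linear")
        res = lp.mediate(df, spec)
        assert res.acme.point + res.ade.point == pytest.approx(
            res.total.point, abs=1e-10)

    def test_zero_mediator_effect_gives_null_acme(self):
        df = linear_system(3000, a=0.8, b=0.0, c=0.4, seed=4)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             control=0.0, treat=1.0, n_boot=100, n_sims=5,
                             seed=5, outcome_family="linear")
        res = lp.mediate(df, spec)
        assert res.acme.ci_low < 0.0 < res.acme.ci_high
        assert abs(res.acme.point) < 0.05


class TestLogisticOutcome:
    def test_estimate_matches_large_sample_monte_carlo_oracle(self):
        a, b, c, b0 = 0.7, 0.5, 0.3, -0.5
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(0, 1, n)
        m = a * x + rng.normal(0, 1, n)
        y = (rng.uniform(size=n) < expit(b0 + c * x + b * m)).astype(float)
        df = pd.DataFrame({"x": x, "m": m, "y": y})

        # oracle: true ACME from the generating model by brute Monte Carlo
        big = 10**6
        r2 = np.random.default_rng(7)
        eps = r2.normal(0, 1, big)
        x0, x1 = 0.0, 1.0
        m0 = a * x0 + eps
        m1 = a * x1 + r2.normal(0, 1, big)
        acme_true = 0.5 * (
            np.mean(expit(b0 + c * x1 + b * m1) - expit(b0 + c * x1 + b * m0))
            + np.mean(expit(b0 + c * x0 + b * m1) - expit(b0 + c * x0 + b * m0))
        )
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             control=0.0, treat=1.0, n_boot=150, n_sims=10,
                             seed=8)
        res = lp.mediate(df, spec)
        assert abs(res.acme.point - acme_true) < 3 * res.acme.se

    def test_same_seed_is_bit_reproducible(self):
        df = linear_system(400, 0.5, 0.5, 0.2, seed=9)
        df["yb"] = (df["y"] > 0).astype(float)
        spec = MediationSpec(exposure="x", mediator="m", outcome="yb",
                             control=0.0, treat=1.0, n_boot=30, seed=10)
        r1, r2 = lp.mediate(df, spec), lp.mediate(df, spec)
        assert r1.acme == r2.acme
        assert r1.ade == r2.ade
        assert r1.total == r2.total

    def test_single_bootstrap_returns_points_without_intervals(self):
        df = linear_system(300, 0.5, 0.5, 0.2, seed=11)
        df["yb"] = (df["y"] > 0).astype(float)
        spec = MediationSpec(exposure="x", mediator="m", outcome="yb",
                             control=0.0, treat=1.0, n_boot=1, seed=12)
        res = lp.mediate(df, spec)
        assert res.acme.ci_low is None and res.acme.p is None
        assert np.isfinite(res.acme.point)

    def test_independent_confounders_leave_acme_unchanged(self):
        # sequential-ignorability plumbing: pure-noise confounders
        df = linear_system(3000, 0.7, 0.5, 0.3, seed=13)
        rng = np.random.default_rng(113)
        df["c1"] = rng.normal(size=len(df))
        df["c2"] = rng.normal(size=len(df))
        eta = -0.3 + 0.4 * df["x"] + 0.6 * df["m"]
        df["yb"] = (rng.uniform(size=len(df)) < expit(eta)).astype(float)
        base = lp.mediate(df, MediationSpec(
            exposure="x", mediator="m", outcome="yb", control=0.0, treat=1.0,
            n_boot=1, n_sims=40, seed=14))
        adj = lp.mediate(df, MediationSpec(
            exposure="x", mediator="m", outcome="yb", confounders=("c1", "c2"),
            control=0.0, treat=1.0, n_boot=1, n_sims=40, seed=14))
        assert adj.acme.point == pytest.approx(base.acme.point, abs=0.02)

    def test_non_binary_outcome_rejected(self):
        df = linear_system(100, 0.5, 0.5, 0.2, seed=15)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             control=0.0, treat=1.0, n_boot=5, seed=16)
        with pytest.raises(ValueError, match="binary"):
            lp.mediate(df, spec)


class TestModeratedMediation:
    def _moderated_data(self, n, interaction, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        w = rng.normal(0, 1, n)
        m = 0.7 * x + rng.normal(0, 1, n)
        eta = -0.3 + 0.3 * x + 0.6 * m + 0.1 * w + interaction * m * w
        y = (rng.uniform(size=n) < expit(eta)).astype(float)
        return pd.DataFrame({"x": x, "w": w, "m": m, "y": y})

    def test_zero_interaction_gives_equal_acme_across_levels(self):
        df = self._moderated_data(4000, interaction=0.0, seed=17)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             moderator="w", moderator_levels=(-1.0, 0.0, 1.0),
                             control=0.0, treat=1.0, n_boot=1, n_sims=40,
                             seed=18)
        res = lp.moderated_mediate(df, spec)
        points = [res[w].acme.point for w in (-1.0, 0.0, 1.0)]
        assert max(points) - min(points) < 0.06

    def test_negative_interaction_makes_acme_decrease_in_moderator(self):
        df = self._moderated_data(6000, interaction=-0.5, seed=19)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             moderator="w", moderator_levels=(-1.0, 0.0, 1.0),
                             control=0.0, treat=1.0, n_boot=1, n_sims=40,
                             seed=20)
        res = lp.moderated_mediate(df, spec)
        points = [res[w].acme.point for w in (-1.0, 0.0, 1.0)]
        assert points[0] > points[1] > points[2]

    def test_default_levels_are_mean_and_plus_minus_sd(self):
        df = self._moderated_data(500, interaction=0.0, seed=21)
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             moderator="w", control=0.0, treat=1.0,
                             n_boot=1, seed=22)
        res = lp.moderated_mediate(df, spec)
        mu, sd = df["w"].mean(), df["w"].std(ddof=1)
        assert sorted(res) == pytest.approx([mu - sd, mu, mu + sd])

    def test_constant_moderator_rejected(self):
        df = self._moderated_data(100, interaction=0.0, seed=23)
        df["w"] = 1.0
        spec = MediationSpec(exposure="x", mediator="m", outcome="y",
                             moderator="w", control=0.0, treat=1.0,
                             n_boot=1, seed=24)
        with pytest.raises(ValueError, match="no variance"):
            lp.moderated_mediate(df, spec)


def _mk_result(acme, se, n_boot=100):
    eff = lambda v, s: Effect(point=v, ci_low=v - 2 * s, ci_high=v + 2 * s,
                              p=0.5, se=s)
    return MediationResult(
        acme=eff(acme, se), ade=eff(0.1, se), total=eff(acme + 0.1, se),
        prop_mediated=eff(0.5, se), acme_control=acme, acme_treated=acme,
        ade_control=0.1, ade_treated=0.1, contrast=(0.0, 1.0),
        n_boot=n_boot, seed=0,
    )


class TestPooling:
    def test_identical_results_pool_to_themselves(self):
        pooled = lp.pool_mediation([_mk_result(0.2, 0.05)] * 3)
        assert pooled.acme.point == pytest.approx(0.2)
        assert pooled.acme.se == pytest.approx(0.05)

    def test_rubin_arithmetic(self):
        pooled = lp.pool_mediation([_mk_result(0.1, 0.1), _mk_result(0.3, 0.1)])
        assert pooled.acme.point == pytest.approx(0.2)
        # T = W + (1 + 1/2) B = 0.01 + 1.5 * 0.02 = 0.04
        assert pooled.acme.se ** 2 == pytest.approx(0.04)

    def test_null_mediation_pooled_interval_covers_zero(self):
        df_base = linear_system(1200, a=0.8, b=0.0, c=0.3, seed=25)
        df_base["yb"] = (df_base["y"] > 0).astype(float)
        results = []
        for i in range(4):  # emulate imputed replicates via noise in X copies
            df = df_base.copy()
            spec = MediationSpec(exposure="x", mediator="m", outcome="yb",
                                 control=0.0, treat=1.0, n_boot=60,
                                 seed=30 + i)
            results.append(lp.mediate(df, spec))
        pooled = lp.pool_mediation(results)
        assert pooled.acme.ci_low < 0.0 < pooled.acme.ci_high

    def test_inconsistent_specs_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            lp.pool_mediation([_mk_result(0.1, 0.1, n_boot=100),
                               _mk_result(0.1, 0.1, n_boot=50)])

    def test_pooling_requires_at_least_two(self):
        with pytest.raises(ValueError):
            lp.pool_mediation([_mk_result(0.1, 0.1)])
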