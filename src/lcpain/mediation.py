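"""Counterfactual causal mediation of the SED -> allostatic load -> chronic
pain pathway.

The estimator follows the potential-outcomes decomposition: a linear
mediator model M ~ X + C and a logistic outcome model Y ~ X + M + C (Y a
binary dummy contrasting one pain category against no pain).  For each
treatment contrast (x0, x1) the counterfactual mediator values M(x0),
M(x1) are *simulated* from the fitted mediator model including residual
noise (plug-in means would bias effects under the nonlinear outcome
link), and effects are averages of predicted outcome probabilities:

    ACME(x) = E[ Y(x, M(x1)) - Y(x, M(x0)) ]
    ADE(x)  = E[ Y(x1, M(x)) - Y(x0, M(x)) ]
    total   = E[ Y(x1, M(x1)) - Y(x0, M(x0)) ]

reported as the average of the two treatment-arm versions.  Uncertainty
comes from a nonparametric bootstrap (refit both models per resample)
with percentile confidence intervals.  Moderated mediation adds the
moderator and its product with the mediator to the outcome model and
evaluates the effects with the moderator fixed at chosen levels.  Results
across multiply-imputed datasets pool with Rubin's rules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .missing_data import pool_rubin

__all__ = [
    "MediationSpec",
    "Effect",
    "MediationResult",
    "mediate",
    "moderated_mediate",
    "pool_mediation",
]


@dataclass(frozen=True)
class MediationSpec:
    """Specification of one mediation analysis.

    ``control`` / ``treat`` are the exposure contrast (x0, x1); ``None``
    defaults to (sample mean, mean + 1 SD).  ``outcome_family`` is
    ``"logistic"`` for the binary dummy outcomes of the pain analysis and
    ``"linear"`` for an identity-link harness (in which ACME + ADE equals
    the total effect exactly).
    """

    exposure: str
    mediator: str
    outcome: str
    confounders: tuple[str, ...] = ()
    control: float | None = None
    treat: float | None = None
    moderator: str | None = None
    moderator_levels: tuple[float, ...] | None = None
    n_boot: int = 500
    n_sims: int = 10
    seed: int = 0
    outcome_family: str = "logistic"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.control is not None and self.control == self.treat:
            raise ValueError("treatment contrast requires control != treat")
        if self.outcome_family not in ("logistic", "linear"):
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")


@dataclass(frozen=True)
class Effect:
    point: float
    ci_low: float | None
    ci_high: float | None
    p: float | None
    se: float | None  # bootstrap standard error


@dataclass
class MediationResult:
    acme: Effect
    ade: Effect
    total: Effect
    prop_mediated: Effect
    acme_control: float
    acme_treated: float
    ade_control: float
    ade_treated: float
    contrast: tuple[float, float]
    n_boot: int
    seed: int
    moderator_level: float | None = None
    unstable_proportion: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("acme", "ade", "total", "prop_mediated"):
            e: Effect = getattr(self, name)
            rows.append({
                "effect": name, "estimate": e.point, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "p": e.p,
                "moderator_level": self.moderator_level,
                "n_boot": self.n_boot, "seed": self.seed,
            })
        return pd.DataFrame(rows)


def _fit_models(df: pd.DataFrame, spec: MediationSpec):
    """Fit mediator (OLS) and outcome (logit or OLS) models; returns
    coefficient mappings and the mediator residual SD."""
    import statsmodels.api as sm

    conf = list(spec.confounders)
    med_cols = [spec.exposure] + conf
    out_cols = [spec.exposure, spec.mediator] + conf
    if spec.moderator is not None:
        med_cols = med_cols + [spec.moderator]
        out_cols = out_cols + [spec.moderator]

    xm = sm.add_constant(df[med_cols].astype(float), has_constant="add")
    med_fit = sm.OLS(df[spec.mediator].astype(float), xm).fit()
    resid_sd = float(np.sqrt(med_fit.scale))

    xo = sm.add_constant(df[out_cols].astype(float), has_constant="add")
    if spec.moderator is not None:
        xo[f"{spec.mediator}:{spec.moderator}"] = (
            df[spec.mediator].astype(float) * df[spec.moderator].astype(float)
        )
    yv = df[spec.outcome].astype(float)
    if spec.outcome_family == "logistic":
        uniq = set(np.unique(yv))
        if not uniq <= {0.0, 1.0}:
            raise ValueError("logistic outcome must be binary 0/1")
        out_fit = sm.Logit(yv, xo).fit(method="newton", maxiter=100, disp=0)
        if np.abs(out_fit.params).max() > 30:
            raise ValueError("outcome model unstable (possible separation)")
    else:
        out_fit = sm.OLS(yv, xo).fit()
    return dict(med_fit.params), dict(out_fit.params), resid_sd


def _predict_outcome(out_par: dict, spec: MediationSpec, df: pd.DataFrame,
                     x: float, m: np.ndarray, w: float | None) -> np.ndarray:
    eta = np.full(len(df), out_par["const"])
    eta += out_par[spec.exposure] * x
    eta += out_par[spec.mediator] * m
    for c in spec.confounders:
        eta += out_par[c] * df[c].to_numpy(dtype=float)
    if spec.moderator is not None:
        eta += out_par[spec.moderator] * w
        eta += out_par[f"{spec.mediator}:{spec.moderator}"] * m * w
    return expit(eta) if spec.outcome_family == "logistic" else eta


def _mediator_mean(med_par: dict, spec: MediationSpec, df: pd.DataFrame,
                   x: float, w: float | None) -> np.ndarray:
    mu = np.full(len(df), med_par["const"])
    mu += med_par[spec.exposure] * x
    for c in spec.confounders:
        mu += med_par[c] * df[c].to_numpy(dtype=float)
    if spec.moderator is not None:
        mu += med_par[spec.moderator] * w
    return mu


def _effects_once(df: pd.DataFrame, spec: MediationSpec, x0: float, x1: float,
                  w: float | None, rng: np.random.Generator) -> dict[str, float]:
    med_par, out_par, resid_sd = _fit_models(df, spec)
    mu0 = _mediator_mean(med_par, spec, df, x0, w)
    mu1 = _mediator_mean(med_par, spec, df, x1, w)
    acc = {k: 0.0 for k in ("acme0", "acme1", "ade0", "ade1", "total")}
    n = len(df)
    for _ in range(spec.n_sims):
        m0 = mu0 + rng.normal(0.0, resid_sd, size=n)
        m1 = mu1 + rng.normal(0.0, resid_sd, size=n)
        y00 = _predict_outcome(out_par, spec, df, x0, m0, w)
        y01 = _predict_outcome(out_par, spec, df, x0, m1, w)
        y10 = _predict_outcome(out_par, spec, df, x1, m0, w)
        y11 = _predict_outcome(out_par, spec, df, x1, m1, w)
        acc["acme0"] += float(np.mean(y01 - y00))
        acc["acme1"] += float(np.mean(y11 - y10))
        acc["ade0"] += float(np.mean(y10 - y00))
        acc["ade1"] += float(np.mean(y11 - y01))
        acc["total"] += float(np.mean(y11 - y00))
    return {k: v / spec.n_sims for k, v in acc.items()}


def _percentile_effect(point: float, draws: np.ndarray) -> Effect:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    frac_le = float(np.mean(draws <= 0.0))
    frac_ge = float(np.mean(draws >= 0.0))
    p = min(2.0 * min(frac_le, frac_ge), 1.0)
    return Effect(point=point, ci_low=float(lo), ci_high=float(hi), p=p,
                  se=float(draws.std(ddof=1)) if draws.size > 1 else None)


def _resolve_contrast(df: pd.DataFrame, spec: MediationSpec) -> tuple[float, float]:
    if spec.control is not None and spec.treat is not None:
        return float(spec.control), float(spec.treat)
    x = df[spec.exposure].astype(float)
    return float(x.mean()), float(x.mean() + x.std(ddof=1))


def _run(df: pd.DataFrame, spec: MediationSpec, w: float | None) -> MediationResult:
    df = df.reset_index(drop=True)
    x0, x1 = _resolve_contrast(df, spec)
    rng = np.random.default_rng(spec.seed)
    point = _effects_once(df, spec, x0, x1, w, rng)

    def combine(e: dict[str, float]) -> tuple[float, float, float]:
        acme = 0.5 * (e["acme0"] + e["acme1"])
        ade = 0.5 * (e["ade0"] + e["ade1"])
        return acme, ade, e["total"]

    acme_pt, ade_pt, tot_pt = combine(point)
    unstable = abs(tot_pt) < 1e-10
    prop_pt = acme_pt / tot_pt if not unstable else np.nan

    if spec.n_boot == 1:
        mk = lambda v: Effect(point=v, ci_low=None, ci_high=None, p=None, se=None)
        return MediationResult(
            acme=mk(acme_pt), ade=mk(ade_pt), total=mk(tot_pt), prop_mediated=mk(prop_pt),
            acme_control=point["acme0"], acme_treated=point["acme1"],
            ade_control=point["ade0"], ade_treated=point["ade1"],
            contrast=(x0, x1), n_boot=1, seed=spec.seed, moderator_level=w,
            unstable_proportion=unstable,
        )

    n = len(df)
    draws = {k: [] for k in ("acme", "ade", "total", "prop")}
    failures = 0
    for _ in range(spec.n_boot):
        idx = rng.integers(0, n, size=n)
        sample = df.iloc[idx].reset_index(drop=True)
        try:
            e = _effects_once(sample, spec, x0, x1, w, rng)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        a, d, t = combine(e)
        draws["acme"].append(a)
        draws["ade"].append(d)
        draws["total"].append(t)
        draws["prop"].append(a / t if abs(t) > 1e-10 else np.nan)
    if failures > 0.2 * spec.n_boot:
        raise RuntimeError(
            f"{failures}/{spec.n_boot} bootstrap refits failed; model too "
            "unstable for resampling inference"
        )
    arr = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
    prop_draws = arr["prop"][~np.isnan(arr["prop"])]
    return MediationResult(
        acme=_percentile_effect(acme_pt, arr["acme"]),
        ade=_percentile_effect(ade_pt, arr["ade"]),
        total=_percentile_effect(tot_pt, arr["total"]),
        prop_mediated=(_percentile_effect(prop_pt, prop_draws)
                       if prop_draws.size else
                       Effect(prop_pt, None, None, None, None)),
        acme_control=point["acme0"], acme_treated=point["acme1"],
        ade_control=point["ade0"], ade_treated=point["ade1"],
        contrast=(x0, x1), n_boot=spec.n_boot, seed=spec.seed,
        moderator_level=w, unstable_proportion=unstable,
    )


def mediate(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Unmoderated counterfactual mediation on one complete dataset."""
    if spec.moderator is not None:
        raise ValueError("spec carries a moderator; use moderated_mediate")
    return _run(data, spec, w=None)


def moderated_mediate(data: pd.DataFrame,
                      spec: MediationSpec) -> dict[float, MediationResult]:
    """Mediation with the moderator fixed at each requested level.

    The outcome model adds the moderator and its product with the
    mediator; the mediator model adds the moderator as a covariate.
    Default evaluation levels are the sample mean and mean +/- 1 SD of the
    moderator.
    """
    if spec.moderator is None:
        raise ValueError("spec has no moderator")
    if spec.moderator not in data.columns:
        raise ValueError(f"moderator {spec.moderator!r} absent from data")
    if data[spec.moderator].std(ddof=0) == 0:
        raise ValueError("moderator has no variance (collinear with constant)")
    levels = spec.moderator_levels
    if levels is None:
        wv = data[spec.moderator].astype(float)
        mu, sd = wv.mean(), wv.std(ddof=1)
        levels = (mu - sd, mu, mu + sd)
    return {float(w): _run(data, spec, w=float(w)) for w in levels}


def pool_mediation(results: Sequence[MediationResult]) -> MediationResult:
    """Pool mediation results across imputed datasets with Rubin's rules.

    The bootstrap variance of each effect serves as the within-imputation
    variance; the proportion mediated is recomputed from the pooled ACME
    and total effect.
    """
    if len(results) < 2:
        raise ValueError("pooling requires >= 2 results")
    levels = {r.moderator_level for r in results}
    boots = {r.n_boot for r in results}
    if len(levels) > 1 or len(boots) > 1:
        raise ValueError("inconsistent specs across results")
    pooled = {}
    for name in ("acme", "ade", "total"):
        effs = [getattr(r, name) for r in results]
        if any(e.se is None for e in effs):
            raise ValueError("pooling requires bootstrap variances (n_boot > 1)")
        pe = pool_rubin([e.point for e in effs], [e.se ** 2 for e in effs])
        z = pe.estimate / pe.se if pe.se > 0 else np.nan
        from scipy import stats as _st
        pfun = (_st.norm.sf if np.isinf(pe.df) else
                lambda v: _st.t.sf(v, pe.df))
        pooled[name] = Effect(point=pe.estimate, ci_low=pe.ci_low,
                              ci_high=pe.ci_high,
                              p=float(2.0 * pfun(abs(z))), se=pe.se)
    tot = pooled["total"].point
    unstable = abs(tot) < 1e-10
    prop = pooled["acme"].point / tot if not unstable else np.nan
    r0 = results[0]
    return MediationResult(
        acme=pooled["acme"], ade=pooled["ade"], total=pooled["total"],
        prop_mediated=Effect(prop, None, None, None, None),
        acme_control=float(np.mean([r.acme_control for r in results])),
        acme_treated=float(np.mean([r.acme_treated for r in results])),
        ade_control=float(np.mean([r.ade_control for r in results])),
        ade_treated=float(np.mean([r.ade_treated for r in results])),
        contrast=r0.contrast, n_boot=r0.n_boot, seed=r0.seed,
        moderator_level=r0.moderator_level, unstable_proportion=unstable,
    )
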