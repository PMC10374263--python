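"""Confounder-adjusted regression models for the cohort analyses.

Chronic-pain categories (no pain / low-interference / high-interference;
no pain / 0-2 sites / 3+ sites) are modeled with multinomial logistic
regression reporting odds ratios against the no-pain reference; the
allostatic-load count is modeled with NB2 negative-binomial regression
reporting incidence-rate ratios.  Both report Wald 95% confidence
intervals on the exponentiated scale.  Numerical fitting is delegated to
statsmodels; this module owns the design construction (dummy coding,
interactions) and the tidy reporting contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DesignSpec",
    "RegressionResult",
    "add_interaction",
    "build_design",
    "fit_multinomial",
    "fit_negative_binomial",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class DesignSpec:
    """Declarative model design.

    ``categorical`` lists confounders to one-hot encode (reference level =
    first sorted level, dropped).  ``reference`` names the outcome
    reference category for multinomial fits.
    """

    outcome: str
    exposures: tuple[str, ...]
    confounders: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    categorical: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        overlap = set(self.exposures) & set(self.confounders)
        if overlap:
            raise ValueError(f"terms cannot be both exposure and confounder: {overlap}")
        terms = set(self.exposures) | set(self.confounders)
        for a, b in self.interactions:
            if a not in terms or b not in terms:
                raise ValueError(f"interaction ({a}, {b}) lacks a main effect")


@dataclass
class RegressionResult:
    """Tidy fit summary: one row per (outcome level,) term."""

    model: str                      # "multinomial" | "negative_binomial"
    table: pd.DataFrame             # level, term, coef, se, exp_coef, ci_low, ci_high, p
    loglik: float
    nobs: int
    alpha: float | None = None      # NB2 dispersion
    levels: tuple[str, ...] = ()

    def term(self, term: str, level: str | None = None) -> pd.Series:
        """Look up one coefficient row."""
        t = self.table
        mask = t["term"] == term
        if level is not None:
            mask &= t["level"] == level
        rows = t[mask]
        if len(rows) != 1:
            raise KeyError(f"term {term!r} (level {level!r}) matched {len(rows)} rows")
        return rows.iloc[0]


def add_interaction(spec: DesignSpec, a: str, b: str) -> DesignSpec:
    """Append an a*b product term; both main effects must be in the design."""
    if a == b:
        raise ValueError("interaction of a term with itself")
    terms = set(spec.exposures) | set(spec.confounders)
    if a not in terms or b not in terms:
        missing = {a, b} - terms
        raise ValueError(f"main effect(s) missing from design: {sorted(missing)}")
    return dataclasses.replace(spec, interactions=spec.interactions + ((a, b),))


def build_design(data: pd.DataFrame, spec: DesignSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Build (outcome, design matrix with constant) from a tidy table."""
    cols = list(spec.exposures) + list(spec.confounders)
    missing = [c for c in cols + [spec.outcome] if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent from data: {missing}")
    parts = []
    for c in cols:
        if c in spec.categorical:
            dummies = pd.get_dummies(data[c], prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(data[[c]].astype(float))
    x = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)
    for a, b in spec.interactions:
        if a in spec.categorical or b in spec.categorical:
            raise ValueError("interactions between dummy-coded terms are not supported")
        x[f"{a}:{b}"] = data[a].astype(float) * data[b].astype(float)
    x = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy(dtype=float))
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return data[spec.outcome], x


def _wald_rows(level: str, terms: Sequence[str], coefs: np.ndarray,
               ses: np.ndarray) -> list[dict]:
    rows = []
    for term, c, s in zip(terms, coefs, ses):
        z = c / s if s > 0 else np.nan
        rows.append({
            "level": level, "term": term, "coef": c, "se": s,
            "exp_coef": np.exp(c),
            "ci_low": np.exp(c - _Z975 * s),
            "ci_high": np.exp(c + _Z975 * s),
            "p": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
        })
    return rows


def fit_multinomial(data: pd.DataFrame, spec: DesignSpec) -> RegressionResult:
    """Multinomial logistic fit; one coefficient block per non-reference
    outcome level, odds ratios with Wald 95% CIs."""
    y, x = build_design(data, spec)
    levels = sorted(map(str, y.unique()))
    if spec.reference is not None:
        if spec.reference not in levels:
            raise ValueError(f"reference level {spec.reference!r} not present")
        levels = [spec.reference] + [v for v in levels if v != spec.reference]
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 levels")
    codes = y.astype(str).map({v: i for i, v in enumerate(levels)}).to_numpy()
    model = sm.MNLogit(codes, x.to_numpy(dtype=float))
    try:
        fit = model.fit(method="newton", maxiter=200, disp=0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - data dependent
        raise ValueError(f"multinomial fit failed (possible separation): {exc}")
    if not np.isfinite(fit.params).all() or np.abs(fit.params).max() > 30:
        raise ValueError(
            "multinomial fit unstable: extreme coefficients suggest complete "
            f"separation (max |coef| = {np.abs(fit.params).max():.1f})"
        )
    rows: list[dict] = []
    terms = list(x.columns)
    ses = np.asarray(fit.bse)
    params = np.asarray(fit.params)
    for j, level in enumerate(levels[1:]):
        rows.extend(_wald_rows(level, terms, params[:, j], ses[:, j]))
    return RegressionResult(
        model="multinomial", table=pd.DataFrame(rows), loglik=float(fit.llf),
        nobs=int(fit.nobs), levels=tuple(levels),
    )


def fit_negative_binomial(data: pd.DataFrame, spec: DesignSpec) -> RegressionResult:
    """NB2 negative-binomial fit (log link, estimated dispersion alpha);
    incidence-rate ratios with Wald 95% CIs."""
    y, x = build_design(data, spec)
    yv = y.to_numpy(dtype=float)
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError("count outcome must be non-negative integers")
    model = sm.NegativeBinomial(yv, x.to_numpy(dtype=float), loglike_method="nb2")
    fit = model.fit(method="bfgs", maxiter=500, disp=0)
    if not fit.mle_retvals.get("converged", True):
        fit = model.fit(method="nm", maxiter=5000, disp=0)
    params = np.asarray(fit.params)
    ses = np.asarray(fit.bse)
    terms = list(x.columns)
    rows = _wald_rows("count", terms, params[: len(terms)], ses[: len(terms)])
    alpha = float(params[-1])
    return RegressionResult(
        model="negative_binomial", table=pd.DataFrame(rows),
        loglik=float(fit.llf), nobs=int(fit.nobs), alpha=alpha,
        levels=("count",),
    )
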