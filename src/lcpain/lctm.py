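"""Latent-class trajectory modeling (LCTM) of period SED scores.

A K-class finite mixture of linear growth curves over three time points
(childhood = 0, first adulthood wave = 1, second adulthood wave = 2):

    y_i | class k  ~  N( beta0_k + beta1_k * t_i,  V_i )

with V_i = sigma^2 I plus optional random-intercept and/or random-slope
variance components (shared across classes, diagonal covariance), and
covariate-free class weights pi_k.  Fitting is by EM with multiple seeded
starts (k-means on per-id OLS intercept/slope pairs, jittered), a
generalized M-step for the variance components, and restarts on class
collapse.  Model comparison uses AIC, BIC, sample-size-adjusted BIC
(effective n = (n+2)/24) and relative entropy, with a minimum-class-share
screen, mirroring standard practice for group-based trajectory models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "TrajectorySpec",
    "TrajectoryFit",
    "ClassAssignment",
    "fit_lctm",
    "information_criteria",
    "relative_entropy",
    "select_model",
    "fit_table",
    "assign_classes",
]

RandomEffects = Literal["none", "intercept", "slope", "intercept_slope"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TrajectorySpec:
    """Configuration of one trajectory model fit."""

    n_classes: int = 1
    random_effects: RandomEffects = "none"
    transform: Literal["identity", "sqrt"] = "identity"
    standardized: bool = True
    max_iter: int = 500
    tol: float = 1e-6
    n_starts: int = 10
    seed: int = 0
    max_restarts: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= 5:
            raise ValueError("n_classes must be between 1 and 5")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.random_effects not in ("none", "intercept", "slope", "intercept_slope"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")

    @property
    def n_random(self) -> int:
        return {"none": 0, "intercept": 1, "slope": 1, "intercept_slope": 2}[
            self.random_effects
        ]

    @property
    def npm(self) -> int:
        """Free-parameter count: 2K fixed effects + (K-1) weights + residual
        variance + random-effect variances."""
        return 2 * self.n_classes + (self.n_classes - 1) + 1 + self.n_random


@dataclass
class TrajectoryFit:
    spec: TrajectorySpec
    loglik: float
    npm: int
    aic: float
    bic: float
    sabic: float
    entropy: float
    class_shares: np.ndarray        # (K,)
    posteriors: np.ndarray          # (n, K)
    beta: np.ndarray                # (K, 2): intercept, slope per class
    sigma2: float
    random_effect_vars: dict[str, float]
    converged: bool
    n: int
    ids: np.ndarray
    loglik_path: list[float] = field(default_factory=list)
    selection_warning: bool = False


@dataclass(frozen=True)
class ClassAssignment:
    ids: np.ndarray
    labels: np.ndarray  # 1-based modal class, ordered by descending baseline mean


def information_criteria(loglik: float, npm: int, n: int) -> tuple[float, float, float]:
    """AIC, BIC and sample-size-adjusted BIC.

    SABIC replaces n in the BIC penalty with the effective sample size
    (n + 2) / 24.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if npm < 0:
        raise ValueError("npm must be >= 0")
    aic = -2.0 * loglik + 2.0 * npm
    bic = -2.0 * loglik + npm * np.log(n)
    sabic = -2.0 * loglik + npm * np.log((n + 2.0) / 24.0)
    return float(aic), float(bic), float(sabic)


def relative_entropy(posteriors: np.ndarray) -> float:
    """Relative entropy of a posterior classification matrix.

    1 - sum_i sum_k (-tau_ik ln tau_ik) / (n ln K), clipped to [0, 1];
    a one-class model has entropy 1 by convention (perfect assignment).
    """
    tau = np.asarray(posteriors, dtype=float)
    if tau.ndim != 2:
        raise ValueError("posteriors must be a 2-D (n x K) matrix")
    n, k = tau.shape
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    if k == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tau > 0, -tau * np.log(tau), 0.0)
    e = 1.0 - terms.sum() / (n * np.log(k))
    return float(np.clip(e, 0.0, 1.0))


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------

class _Collapse(Exception):
    """Raised when a class empties or a variance degenerates mid-EM."""


def _prepare(data: pd.DataFrame) -> tuple[np.ndarray, list[dict]]:
    """Group long-format (id, time, score) rows into observation patterns.

    Returns the sorted unique ids and a list of patterns, each holding the
    time vector, stacked score matrix and the row indices (into the id
    vector) of the respondents sharing that pattern.
    """
    req = {"id", "time", "score"}
    if not req.issubset(data.columns):
        raise ValueError(f"long table must have columns {sorted(req)}")
    if data["score"].isna().any() or not np.isfinite(data["score"]).all():
        raise ValueError("scores must be finite")
    ids = np.sort(data["id"].unique())
    idx_of = {v: i for i, v in enumerate(ids)}
    groups: dict[tuple, list[tuple[int, np.ndarray]]] = {}
    for rid, grp in data.groupby("id"):
        grp = grp.sort_values("time")
        t = tuple(grp["time"].to_numpy(dtype=float))
        groups.setdefault(t, []).append((idx_of[rid], grp["score"].to_numpy(dtype=float)))
    patterns = []
    for t, members in groups.items():
        rows = np.array([m[0] for m in members])
        y = np.vstack([m[1] for m in members])
        tv = np.asarray(t)
        patterns.append({
            "t": tv,
            "X": np.column_stack([np.ones_like(tv), tv]),
            "Y": y,
            "rows": rows,
        })
    return ids, patterns


def _cov(pattern: dict, sigma2: float, sb0: float, sb1: float) -> np.ndarray:
    t = pattern["t"]
    m = t.size
    v = sigma2 * np.eye(m)
    if sb0 > 0:
        v += sb0 * np.ones((m, m))
    if sb1 > 0:
        v += sb1 * np.outer(t, t)
    return v


def _class_logpdf(patterns: list[dict], beta: np.ndarray, sigma2: float,
                  sb0: float, sb1: float, n: int) -> np.ndarray:
    """Per-id, per-class multivariate-normal log density (n x K)."""
    k = beta.shape[0]
    out = np.empty((n, k))
    for p in patterns:
        v = _cov(p, sigma2, sb0, sb1)
        chol = np.linalg.cholesky(v)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        m = p["t"].size
        for j in range(k):
            resid = p["Y"] - p["X"] @ beta[j]          # (n_p, m)
            z = np.linalg.solve(chol, resid.T)          # (m, n_p)
            quad = (z ** 2).sum(axis=0)
            out[p["rows"], j] = -0.5 * (m * _LOG2PI + logdet + quad)
    return out


def _suff_stats(patterns: list[dict], tau: np.ndarray) -> list[dict]:
    """Per-pattern, per-class weighted sufficient statistics for the M-step."""
    k = tau.shape[1]
    stats = []
    for p in patterns:
        tau_p = tau[p["rows"]]                          # (n_p, K)
        s1 = tau_p.sum(axis=0)                          # (K,)
        sy = tau_p.T @ p["Y"]                           # (K, m)
        syy = np.einsum("ij,im,il->jml", tau_p, p["Y"], p["Y"])  # (K, m, m)
        stats.append({"X": p["X"], "t": p["t"], "s1": s1, "sy": sy, "syy": syy,
                      "m": p["t"].size, "pattern": p})
    return stats


def _profile_beta(stats: list[dict], vinvs: list[np.ndarray], k: int) -> np.ndarray:
    beta = np.empty((k, 2))
    for j in range(k):
        a = np.zeros((2, 2))
        b = np.zeros(2)
        for st, vinv in zip(stats, vinvs):
            xtvi = st["X"].T @ vinv
            a += st["s1"][j] * (xtvi @ st["X"])
            b += xtvi @ st["sy"][j]
        beta[j] = np.linalg.solve(a, b)
    return beta


def _q_value(stats: list[dict], theta: np.ndarray, spec: TrajectorySpec,
             k: int) -> tuple[float, np.ndarray]:
    """Expected complete-data negative log-likelihood (up to the weight term)
    at variance parameters exp(theta), with class means profiled out."""
    sigma2, sb0, sb1 = _unpack_theta(theta, spec)
    vinvs, logdets = [], []
    for st in stats:
        v = _cov(st["pattern"], sigma2, sb0, sb1)
        vinv = np.linalg.inv(v)
        sign, logdet = np.linalg.slogdet(v)
        if sign <= 0:
            return np.inf, np.empty((k, 2))
        vinvs.append(vinv)
        logdets.append(logdet)
    beta = _profile_beta(stats, vinvs, k)
    q = 0.0
    for st, vinv, logdet in zip(stats, vinvs, logdets):
        for j in range(k):
            mu = st["X"] @ beta[j]
            # E tau * (y-mu)' Vinv (y-mu) from sufficient stats
            quad = (
                np.trace(vinv @ st["syy"][j])
                - 2.0 * mu @ (vinv @ st["sy"][j])
                + st["s1"][j] * (mu @ vinv @ mu)
            )
            q += 0.5 * (st["s1"][j] * (st["m"] * _LOG2PI + logdet) + quad)
    return q, beta


def _unpack_theta(theta: np.ndarray, spec: TrajectorySpec) -> tuple[float, float, float]:
    sigma2 = float(np.exp(theta[0]))
    sb0 = sb1 = 0.0
    if spec.random_effects == "intercept":
        sb0 = float(np.exp(theta[1]))
    elif spec.random_effects == "slope":
        sb1 = float(np.exp(theta[1]))
    elif spec.random_effects == "intercept_slope":
        sb0 = float(np.exp(theta[1]))
        sb1 = float(np.exp(theta[2]))
    return sigma2, sb0, sb1


def _pack_theta(sigma2: float, sb0: float, sb1: float, spec: TrajectorySpec) -> np.ndarray:
    parts = [np.log(max(sigma2, 1e-12))]
    if spec.random_effects in ("intercept", "intercept_slope"):
        parts.append(np.log(max(sb0, 1e-12)))
    if spec.random_effects in ("slope", "intercept_slope"):
        parts.append(np.log(max(sb1, 1e-12)))
    return np.array(parts)


def _ols_features(patterns: list[dict], n: int) -> np.ndarray:
    """Per-id OLS (intercept, slope); slope 0 when a single observation."""
    feats = np.zeros((n, 2))
    for p in patterns:
        x, y = p["X"], p["Y"]
        if x.shape[0] >= 2:
            coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
            feats[p["rows"], 0] = coef[0]
            feats[p["rows"], 1] = coef[1]
        else:
            feats[p["rows"], 0] = y[:, 0]
    return feats


def _init_tau(feats: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered k-means on (intercept, slope) features -> soft one-hot."""
    from sklearn.cluster import KMeans

    n = feats.shape[0]
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    jittered = feats + rng.normal(0.0, 0.1 * scale, size=feats.shape)
    if k == 1:
        return np.ones((n, 1))
    km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(jittered)
    tau = np.full((n, k), 0.05 / max(k - 1, 1))
    tau[np.arange(n), labels] = 0.95
    return tau / tau.sum(axis=1, keepdims=True)


def _em_once(patterns: list[dict], spec: TrajectorySpec, n: int,
             rng: np.random.Generator) -> dict:
    k = spec.n_classes
    feats = _ols_features(patterns, n)
    tau = _init_tau(feats, k, rng)

    # initial parameters from the hard clustering
    pi = tau.mean(axis=0)
    resid_var = max(float(np.var(feats[:, 0])) * 0.5, 1e-4)
    theta = _pack_theta(resid_var, 0.1 * resid_var, 0.1 * resid_var, spec)
    stats = _suff_stats(patterns, tau)
    _, beta = _q_value(stats, theta, spec, k)

    loglik = -np.inf
    path: list[float] = []
    converged = False
    for _ in range(spec.max_iter):
        sigma2, sb0, sb1 = _unpack_theta(theta, spec)
        logpdf = _class_logpdf(patterns, beta, sigma2, sb0, sb1, n)
        logw = logpdf + np.log(np.maximum(pi, 1e-300))
        norm = logsumexp(logw, axis=1)
        new_loglik = float(norm.sum())
        tau = np.exp(logw - norm[:, None])
        if new_loglik + 1e-8 < loglik:
            raise _Collapse("log-likelihood decreased")  # numerical breakdown
        delta = new_loglik - loglik
        loglik = new_loglik
        path.append(loglik)
        if delta < spec.tol and len(path) > 1:
            converged = True
            break
        # M-step
        pi = tau.mean(axis=0)
        if np.any(pi < 0.5 / n):
            raise _Collapse("class share collapsed")
        stats = _suff_stats(patterns, tau)
        res = minimize(lambda th: _q_value(stats, th, spec, k)[0], theta,
                       method="Nelder-Mead",
                       options={"maxiter": 80, "xatol": 1e-8, "fatol": 1e-10})
        if np.isfinite(res.fun) and res.fun <= _q_value(stats, theta, spec, k)[0]:
            theta = res.x
        _, beta = _q_value(stats, theta, spec, k)
        sigma2, _, _ = _unpack_theta(theta, spec)
        if sigma2 < 1e-10:
            raise _Collapse("residual variance degenerated")

    sigma2, sb0, sb1 = _unpack_theta(theta, spec)
    return {"loglik": loglik, "pi": pi, "beta": beta, "tau": tau,
            "sigma2": sigma2, "sb0": sb0, "sb1": sb1,
            "converged": converged, "path": path}


def fit_lctm(data: pd.DataFrame, spec: TrajectorySpec) -> TrajectoryFit:
    """Fit a K-class trajectory mixture to long-format (id, time, score) data.

    Runs ``spec.n_starts`` seeded EM starts and keeps the best final
    log-likelihood; degenerate runs (empty class, collapsed variance)
    trigger fresh restarts up to ``spec.max_restarts`` extra attempts.
    Classes in the returned fit are relabeled in descending order of the
    fitted baseline (t = 0) mean so labels are reproducible.
    """
    work = data.copy()
    if spec.transform == "sqrt":
        if (work["score"] < 0).any():
            raise ValueError("sqrt transform requires non-negative scores")
        work["score"] = np.sqrt(work["score"].to_numpy(dtype=float))
    ids, patterns = _prepare(work)
    n = ids.size
    if spec.n_classes > n:
        raise ValueError("more classes than respondents")

    ss = np.random.SeedSequence(spec.seed)
    best: dict | None = None
    attempts = spec.n_starts + spec.max_restarts
    done = 0
    any_nonconverged = False
    for child in ss.spawn(attempts):
        if done >= spec.n_starts and best is not None:
            break
        rng = np.random.default_rng(child)
        try:
            run = _em_once(patterns, spec, n, rng)
        except _Collapse:
            continue
        done += 1
        any_nonconverged |= not run["converged"]
        if best is None or run["loglik"] > best["loglik"]:
            best = run
    if best is None:
        raise RuntimeError(
            "all EM starts degenerated; reduce n_classes or simplify the model"
        )

    # reproducible labels: descending baseline fitted mean
    order = np.argsort(-best["beta"][:, 0], kind="stable")
    beta = best["beta"][order]
    pi = best["pi"][order]
    tau = best["tau"][:, order]

    npm = spec.npm
    aic, bic, sabic = information_criteria(best["loglik"], npm, n)
    re_vars = {}
    if spec.random_effects in ("intercept", "intercept_slope"):
        re_vars["intercept"] = best["sb0"]
    if spec.random_effects in ("slope", "intercept_slope"):
        re_vars["slope"] = best["sb1"]
    return TrajectoryFit(
        spec=spec, loglik=best["loglik"], npm=npm, aic=aic, bic=bic, sabic=sabic,
        entropy=relative_entropy(tau), class_shares=tau.mean(axis=0),
        posteriors=tau, beta=beta, sigma2=best["sigma2"],
        random_effect_vars=re_vars, converged=best["converged"], n=n, ids=ids,
        loglik_path=list(best["path"]),
    )


def select_model(fits: Sequence[TrajectoryFit], min_share: float = 0.05) -> TrajectoryFit:
    """Pick the preferred trajectory model.

    Fits with any class share below ``min_share`` (or an empty class) are
    discarded; survivors are ranked by lower BIC, then lower AIC, then
    lower SABIC, then higher entropy.  If no candidate survives the share
    screen, the best-BIC fit is returned with ``selection_warning=True``.
    """
    if not fits:
        raise ValueError("no candidate fits")
    ok = [f for f in fits
          if f.class_shares.min() >= min_share and (f.class_shares > 0).all()]
    key = lambda f: (f.bic, f.aic, f.sabic, -f.entropy)
    if ok:
        return min(ok, key=key)
    best = min(fits, key=lambda f: f.bic)
    return dataclasses.replace(best, selection_warning=True)


def fit_table(fits: Sequence[TrajectoryFit]) -> pd.DataFrame:
    """Model-comparison table (one row per fit) in the standard layout:
    class count, log-likelihood, convergence, parameter count, AIC/BIC/
    SABIC, entropy and per-class percentage shares."""
    kmax = max(f.spec.n_classes for f in fits)
    rows = []
    for f in fits:
        row = {
            "n_classes": f.spec.n_classes,
            "random_effects": f.spec.random_effects,
            "transform": f.spec.transform,
            "standardized": f.spec.standardized,
            "loglik": f.loglik,
            "conv": int(f.converged),
            "npm": f.npm,
            "aic": f.aic,
            "bic": f.bic,
            "sabic": f.sabic,
            "entropy": f.entropy,
        }
        for j in range(kmax):
            row[f"pct_class{j + 1}"] = (
                100.0 * f.class_shares[j] if j < f.spec.n_classes else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assign_classes(fit: TrajectoryFit) -> ClassAssignment:
    """Modal posterior class per respondent (ties -> lowest class index)."""
    labels = np.argmax(fit.posteriors, axis=1) + 1
    return ClassAssignment(ids=fit.ids, labels=labels)
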