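"""Seeded generator of MIDUS-like synthetic cohorts with known ground truth.

The generator emulates the statistical structure of the study cohort so
that every pipeline stage is testable without the restricted survey data:

1. a latent 3-class SED trajectory (high-to-low 45.7%, stable-low 36.8%,
   medium-to-high 17.5%), linear in time on the standardized 0-2 scale;
2. period SED scores decomposed into valid item codes (childhood welfare
   item binary 0/2) whose sum reproduces the rounded raw score exactly;
3. an allostatic-load count drawn negative-binomially with log-mean
   increasing in total SED (default rate ratio 1.02 per SED unit), either
   stored directly or realized as 27 biomarker values positioned inside /
   outside their published risk regions so index scoring round-trips;
4. chronic-pain categories from multinomial/conditional logits with the
   study's headline effect sizes as default coefficients (OR 1.15 per
   recent-SED unit and 3.22 for the worsening class on high-interference
   pain; 3.06 for the worsening class, 1.19 per AL unit, 1.69 per
   childhood-SED unit and a 0.95 AL x childhood-SED interaction on 3+
   pain sites), with interference items and site flags filled in
   consistently with the drawn category;
5. independent standard-normal confounders (zero effects by default) and
   optional MCAR item missingness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .indices import (
    ADULT_ITEMS,
    BIOMARKERS,
    CHILDHOOD_ITEMS,
    SITE_NAMES,
    Cutpoint,
    CutpointConfig,
    default_cutpoints,
)

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "inject_missingness",
           "write_cohort"]

_LN = math.log


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of the synthetic cohort.

    Class order is (high-to-low, stable-low, medium-to-high); trajectory
    means are (t=0, t=2) endpoints on the standardized 0-2 SED scale,
    linear in between.  Intercepts are calibrated so the default cohort
    approximates the study's outcome mix (mean AL about 6.7; roughly 64%
    no pain, 24% low-interference, 12% high-interference; 37% of painful
    respondents with 3+ sites).
    """

    n: int = 593
    seed: int = 0
    class_shares: tuple[float, float, float] = (0.457, 0.368, 0.175)
    class_means: tuple[tuple[float, float], ...] = ((1.4, 0.5), (0.4, 0.4), (0.8, 1.5))
    within_sd: float = 0.2
    al_mode: Literal["biomarker", "count"] = "biomarker"
    al_baseline_mean: float = 5.25          # mean AL count at zero total SED
    log_irr_al: float = _LN(1.02)           # per total-SED unit
    al_alpha: float = 0.2                   # NB2 dispersion
    cp_low_intercept: float = -0.97
    cp_high_intercept: float = -2.46
    cp_high_sed_m2: float = _LN(1.15)       # per raw MIDUS-2 SED unit
    cp_low_class_mh: float = 0.0
    cp_high_class_mh: float = _LN(3.22)     # medium-to-high class indicator
    cp_sites_intercept: float = -2.55
    cp_sites_class_mh: float = _LN(3.06)
    cp_sites_al: float = _LN(1.19)          # per AL unit
    cp_sites_childsed: float = _LN(1.69)    # per childhood raw SED unit
    cp_sites_interaction: float = _LN(0.95)  # AL x childhood SED
    n_confounders: int = 5
    conf_effects_al: tuple[float, ...] | None = None     # on the AL log-mean
    conf_effects_sites: tuple[float, ...] | None = None  # on the 3+-sites logit
    missing_rate: float = 0.0               # MCAR rate applied to confounders

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.class_shares) - 1.0) > 1e-8:
            raise ValueError("class shares must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for eff in (self.conf_effects_al, self.conf_effects_sites):
            if eff is not None and len(eff) != self.n_confounders:
                raise ValueError("confounder effect vector length mismatch")


class Cohort(NamedTuple):
    data: pd.DataFrame    # respondent table in the scoring CSV schema
    truth: pd.DataFrame   # ground-truth side table (class labels, latent scores)
    config: CohortConfig


# --------------------------------------------------------------------------
# item-code decomposition
# --------------------------------------------------------------------------

def _distribute(total: int, n_items: int, rng: np.random.Generator) -> list[int]:
    """Randomly split ``total`` points over ``n_items`` codes each <= 2."""
    codes = [0] * n_items
    remaining = total
    while remaining > 0:
        open_idx = [i for i, c in enumerate(codes) if c < 2]
        codes[int(rng.choice(open_idx))] += 1
        remaining -= 1
    return codes


def _decompose_childhood(raw: int, rng: np.random.Generator) -> dict[str, int]:
    if not 0 <= raw <= 8:
        raise ValueError(f"childhood raw score {raw} outside [0, 8]")
    if raw > 6:
        welfare = 2
    elif raw >= 2 and rng.random() < 0.3:
        welfare = 2
    else:
        welfare = 0
    others = _distribute(raw - welfare, 3, rng)
    items = [i for i in CHILDHOOD_ITEMS if i != "welfare"]
    out = dict(zip(items, others))
    out["welfare"] = welfare
    return out


def _decompose_adult(raw: int, rng: np.random.Generator) -> dict[str, int]:
    if not 0 <= raw <= 12:
        raise ValueError(f"adult raw score {raw} outside [0, 12]")
    return dict(zip(ADULT_ITEMS, _distribute(raw, 6, rng)))


# --------------------------------------------------------------------------
# biomarker realization
# --------------------------------------------------------------------------

def _biomarker_value(cp: Cutpoint, risk: bool, rng: np.random.Generator) -> float:
    if cp.direction == "upper":
        h = cp.high
        return rng.uniform(h, 1.5 * h) if risk else rng.uniform(0.5 * h, 0.95 * h)
    if cp.direction == "lower":
        lo = cp.low
        return rng.uniform(0.5 * lo, lo) if risk else rng.uniform(1.05 * lo, 1.5 * lo)
    lo, hi = cp.low, cp.high
    if risk:
        if rng.random() < 0.5:
            return rng.uniform(0.5 * lo, lo)
        return rng.uniform(hi, 1.2 * hi)
    pad = 0.05 * (hi - lo)
    return rng.uniform(lo + pad, hi - pad)


# --------------------------------------------------------------------------
# chronic-pain fill-in
# --------------------------------------------------------------------------

def _draw_interference(high: bool, rng: np.random.Generator) -> np.ndarray:
    """Five 0-10 items whose mean lies in the band of the drawn category
    (<= 4 for low, > 4 for high), by rejection sampling."""
    while True:
        items = rng.uniform(0.0, 10.0, size=5)
        mean = items.mean()
        if (mean > 4.0) == high:
            return np.round(items, 1)


def _softmax_draw(eta: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a category index from multinomial-logit linear predictors
    (reference category prepended with eta = 0)."""
    full = np.concatenate([[0.0], eta])
    full -= full.max()
    p = np.exp(full)
    p /= p.sum()
    return int(rng.choice(len(full), p=p))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a synthetic cohort; fully deterministic under a fixed seed."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    cuts = default_cutpoints()

    classes = rng.choice(3, size=n, p=np.asarray(cfg.class_shares))

    # standardized SED per period, clipped to [0, 2]
    times = np.array([0.0, 1.0, 2.0])
    std_sed = np.empty((n, 3))
    for k, (start, end) in enumerate(cfg.class_means):
        rows = classes == k
        mean_t = start + (end - start) * times / 2.0
        std_sed[rows] = mean_t + rng.normal(0.0, cfg.within_sd, size=(rows.sum(), 3))
    std_sed = np.clip(std_sed, 0.0, 2.0)

    raw_child = np.rint(std_sed[:, 0] * 4).astype(int)
    raw_m1 = np.rint(std_sed[:, 1] * 6).astype(int)
    raw_m2 = np.rint(std_sed[:, 2] * 6).astype(int)
    total_sed = raw_child + raw_m1 + raw_m2

    conf = rng.normal(0.0, 1.0, size=(n, cfg.n_confounders))
    eff_al = np.asarray(cfg.conf_effects_al or [0.0] * cfg.n_confounders)
    eff_sites = np.asarray(cfg.conf_effects_sites or [0.0] * cfg.n_confounders)

    # allostatic load: NB2 via gamma-Poisson mixture
    log_mu = _LN(cfg.al_baseline_mean) + cfg.log_irr_al * total_sed + conf @ eff_al
    mu = np.exp(log_mu)
    if cfg.al_alpha > 1e-8:
        lam = rng.gamma(shape=1.0 / cfg.al_alpha, scale=mu * cfg.al_alpha)
    else:
        lam = mu
    al = np.minimum(rng.poisson(lam), 27).astype(int)

    is_mh = (classes == 2).astype(float)

    rows = []
    truth_rows = []
    for i in range(n):
        row: dict[str, object] = {"id": i + 1}

        if cfg.al_mode == "biomarker":
            risk_set = set(rng.choice(27, size=al[i], replace=False).tolist())
            for j, name in enumerate(BIOMARKERS):
                row[name] = _biomarker_value(cuts[name], j in risk_set, rng)
        else:
            row["al_score"] = al[i]

        child_codes = _decompose_childhood(int(raw_child[i]), rng)
        for item, code in child_codes.items():
            row[f"sed_childhood_{item}"] = code
        for period, raw in (("midus1", raw_m1[i]), ("midus2", raw_m2[i])):
            for item, code in _decompose_adult(int(raw), rng).items():
                row[f"sed_{period}_{item}"] = code

        eta_low = cfg.cp_low_intercept + cfg.cp_low_class_mh * is_mh[i]
        eta_high = (cfg.cp_high_intercept
                    + cfg.cp_high_sed_m2 * raw_m2[i]
                    + cfg.cp_high_class_mh * is_mh[i])
        cat = _softmax_draw(np.array([eta_low, eta_high]), rng)
        has_cp = cat != 0
        row["cp_has"] = int(has_cp)
        if has_cp:
            items = _draw_interference(high=(cat == 2), rng=rng)
            for j, v in enumerate(items, start=1):
                row[f"cp_int_{j}"] = v
            eta_ge3 = (cfg.cp_sites_intercept
                       + cfg.cp_sites_class_mh * is_mh[i]
                       + cfg.cp_sites_al * al[i]
                       + cfg.cp_sites_childsed * raw_child[i]
                       + cfg.cp_sites_interaction * al[i] * raw_child[i]
                       + float(conf[i] @ eff_sites))
            ge3 = rng.uniform() < 1.0 / (1.0 + np.exp(-eta_ge3))
            count = int(rng.integers(3, 10)) if ge3 else int(
                rng.choice([0, 1, 2], p=[0.05, 0.475, 0.475]))
            flagged = set(rng.choice(9, size=count, replace=False).tolist())
            for j, s in enumerate(SITE_NAMES):
                row[f"cp_site_{s}"] = int(j in flagged)
        else:
            for j in range(1, 6):
                row[f"cp_int_{j}"] = np.nan
            for s in SITE_NAMES:
                row[f"cp_site_{s}"] = 0
            ge3 = False
            count = 0

        for j in range(cfg.n_confounders):
            row[f"conf_{j + 1}"] = conf[i, j]
        rows.append(row)

        truth_rows.append({
            "id": i + 1,
            "true_class": int(classes[i]) + 1,
            "true_std_sed_t0": std_sed[i, 0],
            "true_std_sed_t1": std_sed[i, 1],
            "true_std_sed_t2": std_sed[i, 2],
            "true_sed_childhood": int(raw_child[i]),
            "true_sed_midus1": int(raw_m1[i]),
            "true_sed_midus2": int(raw_m2[i]),
            "true_sed_total": int(total_sed[i]),
            "true_al": int(al[i]),
            "true_cp_cat": ("no_pain", "low", "high")[cat],
            "true_sites_cat": "no_pain" if not has_cp else ("ge3" if ge3 else "le2"),
        })

    data = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    if cfg.missing_rate > 0:
        conf_cols = [f"conf_{j + 1}" for j in range(cfg.n_confounders)]
        data = inject_missingness(data, cfg.missing_rate, conf_cols,
                                  seed=int(rng.integers(2**31 - 1)))
    return Cohort(data=data, truth=truth, config=cfg)


def inject_missingness(table: pd.DataFrame, rate: float,
                       columns: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Blank each scoped cell independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for c in columns:
        if c not in out.columns:
            raise ValueError(f"column {c!r} absent from table")
        mask = rng.uniform(size=len(out)) < rate
        out.loc[mask, c] = np.nan
    return out


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write cohort.csv, truth.csv and a config echo (config.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(directory / "cohort.csv", index=False)
    cohort.truth.to_csv(directory / "truth.csv", index=False)
    (directory / "config.json").write_text(
        json.dumps(asdict(cohort.config), indent=2, default=list)
    )
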