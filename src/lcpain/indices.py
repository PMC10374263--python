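"""Deterministic index construction: allostatic load, cumulative
socioeconomic disadvantage, and chronic-pain outcome categories.

Allostatic load (AL) is operationalized as a count of biomarkers falling in
a high-risk quartile region, over a fixed panel of 27 biomarkers spanning
seven physiological systems (HPA axis, sympathetic and parasympathetic
nervous system, cardiovascular, glucose and lipid metabolism,
inflammation).  The default cut-points are the published high-risk quartile
thresholds from the MIDUS 2 biomarker sample; alternatively they can be
re-derived as empirical quartiles of any biomarker sample.

Socioeconomic disadvantage (SED) is a cumulative index: each indicator is
coded 0 (no disadvantage), 1 (mild/moderate) or 2 (severe) and summed
within a life period — childhood (4 items, range 0-8) and each adulthood
wave (6 items, range 0-12); the life-course total ranges 0-32.

Chronic pain (CP) is characterized by an interference index (mean of five
0-10 items) categorized as no pain / low (<=4) / high (>4), and by a count
of up to nine painful body sites categorized as no pain / 0-2 sites / 3+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "Cutpoint",
    "CutpointConfig",
    "ALIndex",
    "SedItems",
    "PeriodSED",
    "CPOutcome",
    "default_cutpoints",
    "load_cutpoints",
    "save_cutpoints",
    "score_al",
    "derive_cutpoints",
    "score_sed_period",
    "score_sed_total",
    "transform_sed",
    "categorize_cp",
    "score_cohort",
    "CHILDHOOD_ITEMS",
    "ADULT_ITEMS",
    "SITE_NAMES",
]

Direction = Literal["upper", "lower", "two_sided"]

#: The 27 biomarkers of the AL panel, grouped by physiological system in
#: the canonical reporting order.
BIOMARKERS: tuple[str, ...] = (
    # HPA axis
    "dheas", "urine_cortisol",
    # sympathetic nervous system
    "urine_epinephrine", "urine_norepinephrine", "urine_dopamine",
    # parasympathetic nervous system
    "hfhrv", "lfhrv", "rmssd", "sdrr",
    # cardiovascular
    "resting_hr", "sbp", "dbp",
    # metabolic - glucose
    "fasting_glucose", "hba1c", "homa_ir",
    # metabolic - lipids
    "triglycerides", "whr", "bmi", "ldl", "hdl",
    # inflammation
    "crp", "il6", "tnf_alpha", "fibrinogen", "se_selectin", "icam1", "igf1",
)

CHILDHOOD_ITEMS: tuple[str, ...] = (
    "father_education", "mother_education", "welfare", "father_occupation",
)
ADULT_ITEMS: tuple[str, ...] = (
    "income_needs", "education", "financial_rating",
    "money_needs", "bill_difficulty", "occupation",
)
SITE_NAMES: tuple[str, ...] = (
    "head", "neck", "back", "arms", "legs", "shoulders", "hips", "knees", "other",
)

# Published high-risk quartile cut-points of the MIDUS 2 biomarker sample.
# direction: "upper" -> at risk when value >= high; "lower" -> value <= low;
# "two_sided" -> value <= low or value >= high.  Boundaries inclusive.
_DEFAULT_TABLE: dict[str, tuple[Direction, float | None, float | None]] = {
    "dheas": ("two_sided", 51.0, 141.0),
    "urine_cortisol": ("two_sided", 6.70, 19.0),
    "urine_epinephrine": ("upper", None, 2.46),
    "urine_norepinephrine": ("upper", None, 32.96),
    "urine_dopamine": ("upper", None, 182.96),
    "hfhrv": ("lower", 55.90, None),
    "lfhrv": ("lower", 103.40, None),
    "rmssd": ("lower", 12.02, None),
    "sdrr": ("lower", 23.27, None),
    "resting_hr": ("upper", None, 79.80),
    "sbp": ("upper", None, 144.0),
    "dbp": ("upper", None, 82.0),
    "fasting_glucose": ("upper", None, 105.0),
    "hba1c": ("upper", None, 6.24),
    "homa_ir": ("upper", None, 4.36),
    "triglycerides": ("upper", None, 156.0),
    "whr": ("upper", None, 0.97),
    "bmi": ("upper", None, 33.03),
    "ldl": ("upper", None, 127.0),
    "hdl": ("lower", 43.0, None),
    "crp": ("upper", None, 3.66),
    "il6": ("upper", None, 1.23),
    "tnf_alpha": ("upper", None, 2.51),
    "fibrinogen": ("upper", None, 399.0),
    "se_selectin": ("upper", None, 51.88),
    "icam1": ("upper", None, 335.19),
    "igf1": ("upper", None, 157.0),
}


@dataclass(frozen=True)
class Cutpoint:
    """Risk region for one biomarker.

    ``upper`` flags values ``>= high``, ``lower`` flags ``<= low``,
    ``two_sided`` flags either tail; boundaries are inclusive.
    """

    direction: Direction
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.direction == "upper":
            if self.high is None or self.low is not None:
                raise ValueError("upper cutpoint carries a high threshold only")
        elif self.direction == "lower":
            if self.low is None or self.high is not None:
                raise ValueError("lower cutpoint carries a low threshold only")
        elif self.direction == "two_sided":
            if self.low is None or self.high is None:
                raise ValueError("two_sided cutpoint carries both thresholds")
            if not self.low < self.high:
                raise ValueError("two_sided cutpoint requires low < high")
        else:
            raise ValueError(f"unknown direction {self.direction!r}")

    def at_risk(self, value: float) -> bool:
        if self.direction == "upper":
            return value >= self.high
        if self.direction == "lower":
            return value <= self.low
        return value <= self.low or value >= self.high


@dataclass(frozen=True)
class CutpointConfig:
    """Per-biomarker risk thresholds; the default carries all 27 entries."""

    cutpoints: Mapping[str, Cutpoint]

    def __post_init__(self) -> None:
        unknown = set(self.cutpoints) - set(BIOMARKERS)
        if unknown:
            raise ValueError(f"unknown biomarker(s) in config: {sorted(unknown)}")

    def __getitem__(self, name: str) -> Cutpoint:
        return self.cutpoints[name]

    def __iter__(self):
        return iter(self.cutpoints)

    def __len__(self) -> int:
        return len(self.cutpoints)


def default_cutpoints() -> CutpointConfig:
    """The fixed published quartile cut-point configuration (27 entries)."""
    return CutpointConfig(
        {name: Cutpoint(d, lo, hi) for name, (d, lo, hi) in _DEFAULT_TABLE.items()}
    )


def save_cutpoints(config: CutpointConfig, path: str | Path) -> None:
    """Write a cut-point configuration as a plain-text CSV."""
    rows = [
        {
            "biomarker": name,
            "direction": cp.direction,
            "low": "" if cp.low is None else cp.low,
            "high": "" if cp.high is None else cp.high,
        }
        for name, cp in config.cutpoints.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cutpoints(path: str | Path) -> CutpointConfig:
    df = pd.read_csv(path)
    cps = {}
    for _, row in df.iterrows():
        lo = None if pd.isna(row.get("low")) else float(row["low"])
        hi = None if pd.isna(row.get("high")) else float(row["high"])
        cps[str(row["biomarker"])] = Cutpoint(str(row["direction"]), lo, hi)
    return CutpointConfig(cps)


@dataclass(frozen=True)
class ALIndex:
    """Allostatic-load index: count of biomarkers in their risk region."""

    score: int
    flags: Mapping[str, bool]
    n_scored: int  # denominator actually used (27 unless available-case)

    def __post_init__(self) -> None:
        if self.score != sum(self.flags.values()):
            raise ValueError("score must equal the number of true flags")


def score_al(
    panel: Mapping[str, float],
    config: CutpointConfig | None = None,
    *,
    missing: Literal["error", "available"] = "error",
) -> ALIndex:
    """Count biomarkers whose value falls in the high-risk region.

    Parameters
    ----------
    panel
        Mapping of biomarker name to value; ``NaN``/``None`` marks missing.
    config
        Cut-point configuration; defaults to the published quartile table.
    missing
        ``"error"`` (default) raises on a missing scored biomarker;
        ``"available"`` scores over the non-missing subset and records the
        denominator in ``n_scored``.
    """
    if config is None:
        config = default_cutpoints()
    flags: dict[str, bool] = {}
    n_scored = 0
    for name in config:
        raw = panel.get(name)
        value = float("nan") if raw is None else float(raw)
        if math.isnan(value):
            if missing == "error":
                raise ValueError(f"missing biomarker {name!r} (no skip policy)")
            continue
        flags[name] = config[name].at_risk(value)
        n_scored += 1
    return ALIndex(score=int(sum(flags.values())), flags=flags, n_scored=n_scored)


def derive_cutpoints(
    panels: pd.DataFrame | Iterable[Mapping[str, float]],
    mode: Literal["fixed_table", "sample_quartile"] = "fixed_table",
    *,
    min_n: int = 8,
) -> CutpointConfig:
    """Return cut-points either as the fixed published constants or as
    empirical 25th/75th percentiles of the supplied biomarker sample.

    ``sample_quartile`` keeps each biomarker's published risk direction
    (DHEA-S and urine cortisol two-sided; HRV measures and HDL lower; all
    others upper) and uses linearly interpolated quantiles.
    """
    if mode == "fixed_table":
        return default_cutpoints()
    if mode != "sample_quartile":
        raise ValueError(f"unknown mode {mode!r}")
    df = panels if isinstance(panels, pd.DataFrame) else pd.DataFrame(list(panels))
    cps: dict[str, Cutpoint] = {}
    for name, (direction, _, _) in _DEFAULT_TABLE.items():
        if name not in df.columns:
            raise ValueError(f"biomarker {name!r} absent from sample")
        values = df[name].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"biomarker {name!r} is all-missing")
        if values.size < min_n:
            raise ValueError(
                f"biomarker {name!r}: {values.size} non-missing values; "
                f"need at least {min_n} for sample quartiles"
            )
        q25, q75 = np.percentile(values, [25.0, 75.0])  # linear interpolation
        if direction == "upper":
            cps[name] = Cutpoint("upper", None, float(q75))
        elif direction == "lower":
            cps[name] = Cutpoint("lower", float(q25), None)
        else:
            if not q25 < q75:
                # degenerate sample: collapse to a one-sided upper rule at
                # the common value so the config stays valid
                cps[name] = Cutpoint("upper", None, float(q75))
            else:
                cps[name] = Cutpoint("two_sided", float(q25), float(q75))
    return CutpointConfig(cps)


# ---------------------------------------------------------------------------
# SED scoring
# ---------------------------------------------------------------------------

_PERIOD_ITEMS: dict[str, tuple[str, ...]] = {
    "childhood": CHILDHOOD_ITEMS,
    "midus1": ADULT_ITEMS,
    "midus2": ADULT_ITEMS,
}


@dataclass(frozen=True)
class SedItems:
    """Coded disadvantage items for one life period.

    Codes are 0 (no disadvantage), 1 (mild/moderate), 2 (severe); the
    childhood welfare item is binary and can only take 0 or 2.
    """

    period: Literal["childhood", "midus1", "midus2"]
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        items = _PERIOD_ITEMS.get(self.period)
        if items is None:
            raise ValueError(f"unknown period {self.period!r}")
        if len(self.codes) != len(items):
            raise ValueError(
                f"{self.period} expects {len(items)} item codes, got {len(self.codes)}"
            )
        for item, code in zip(items, self.codes):
            valid = (0, 2) if item == "welfare" else (0, 1, 2)
            if code not in valid:
                raise ValueError(f"invalid code {code!r} for item {item!r}")

    @property
    def items(self) -> tuple[str, ...]:
        return _PERIOD_ITEMS[self.period]


@dataclass(frozen=True)
class PeriodSED:
    """Cumulative SED for one period: raw sum and per-item standardized score."""

    period: str
    raw: int
    item_count: int

    @property
    def standardized(self) -> float:
        return self.raw / self.item_count


def score_sed_period(items: SedItems) -> PeriodSED:
    """Sum the coded indicators of one period (childhood 0-8, adulthood 0-12)."""
    return PeriodSED(period=items.period, raw=int(sum(items.codes)),
                     item_count=len(items.codes))


def score_sed_total(childhood: PeriodSED, m1: PeriodSED, m2: PeriodSED) -> int:
    """Life-course cumulative SED: sum of the three period indices (0-32)."""
    expected = ("childhood", "midus1", "midus2")
    got = (childhood.period, m1.period, m2.period)
    if got != expected:
        raise ValueError(f"periods must be {expected} in order, got {got}")
    return childhood.raw + m1.raw + m2.raw


def transform_sed(value: float, mode: Literal["identity", "sqrt"] = "identity") -> float:
    """Optional skew-reducing transform applied to SED scores."""
    if value < 0:
        raise ValueError("SED scores are non-negative")
    if mode == "identity":
        return float(value)
    if mode == "sqrt":
        return math.sqrt(value)
    raise ValueError(f"unknown transform {mode!r}")


# ---------------------------------------------------------------------------
# Chronic-pain categorization
# ---------------------------------------------------------------------------

InterferenceCat = Literal["no_pain", "low", "high"]
SitesCat = Literal["no_pain", "le2", "ge3"]


@dataclass(frozen=True)
class CPOutcome:
    has_cp: bool
    interference_items: tuple[float, ...] | None
    site_flags: tuple[bool, ...] | None
    interference_index: float | None
    interference_category: InterferenceCat
    sites_count: int | None
    sites_category: SitesCat


def categorize_cp(
    has_cp: bool,
    interference_items: Sequence[float] | None = None,
    site_flags: Sequence[bool] | None = None,
) -> CPOutcome:
    """Categorize a chronic-pain report.

    Interference is the mean of five 0-10 items, categorized as low
    (index <= 4) or high (> 4); widespreadness is the count of nine body
    sites, categorized as 0-2 versus 3 or more.  Respondents without
    chronic pain are ``no_pain`` in both dimensions.  A respondent with
    chronic pain but no flagged listed site is counted literally (0 sites,
    category ``le2``).
    """
    if not has_cp:
        return CPOutcome(False, None, None, None, "no_pain", None, "no_pain")
    if interference_items is None:
        raise ValueError("chronic pain reported but interference items missing")
    items = tuple(float(v) for v in interference_items)
    if len(items) != 5:
        raise ValueError("interference requires exactly 5 items")
    for v in items:
        if math.isnan(v):
            raise ValueError("chronic pain reported but interference item missing")
        if not 0.0 <= v <= 10.0:
            raise ValueError(f"interference item {v} outside [0, 10]")
    index = sum(items) / 5.0
    icat: InterferenceCat = "low" if index <= 4.0 else "high"
    flags = tuple(bool(f) for f in (site_flags or ()))
    if site_flags is not None and len(flags) != len(SITE_NAMES):
        raise ValueError(f"expected {len(SITE_NAMES)} site flags")
    count = int(sum(flags))
    scat: SitesCat = "le2" if count <= 2 else "ge3"
    return CPOutcome(True, items, flags or None, index, icat, count, scat)


# ---------------------------------------------------------------------------
# Cohort-level scoring (CSV schema bridge)
# ---------------------------------------------------------------------------

def _sed_columns(period: str) -> list[str]:
    return [f"sed_{period}_{item}" for item in _PERIOD_ITEMS[period]]


def score_cohort(
    df: pd.DataFrame,
    cutpoints: CutpointConfig | None = None,
    *,
    missing_biomarkers: Literal["error", "available"] = "error",
) -> pd.DataFrame:
    """Score a cohort table into analysis variables.

    Expects one row per respondent with biomarker columns named as in
    ``BIOMARKERS``, SED item columns ``sed_<period>_<item>``, and CP
    columns ``cp_has``, ``cp_int_1..5``, ``cp_site_<name>``.  Missing
    cells are empty/NaN.  Returns a DataFrame indexed like the input with
    columns ``al_score``, per-period raw and standardized SED, the
    life-course total, and the two CP categorizations.
    """
    if cutpoints is None:
        cutpoints = default_cutpoints()
    out = pd.DataFrame(index=df.index)

    has_bio = all(b in df.columns for b in BIOMARKERS)
    if has_bio:
        scores = []
        for _, row in df[list(BIOMARKERS)].iterrows():
            scores.append(
                score_al(row.to_dict(), cutpoints, missing=missing_biomarkers).score
            )
        out["al_score"] = scores
    elif "al_score" in df.columns:
        out["al_score"] = df["al_score"].astype(int)
    else:
        raise ValueError("cohort has neither biomarker columns nor al_score")

    periods = ("childhood", "midus1", "midus2")
    for period in periods:
        cols = _sed_columns(period)
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing SED columns: {missing_cols}")
        raws = []
        for _, row in df[cols].iterrows():
            sed = score_sed_period(
                SedItems(period, tuple(int(v) for v in row.to_numpy()))
            )
            raws.append(sed.raw)
        out[f"sed_{period}_raw"] = raws
        out[f"sed_{period}_std"] = out[f"sed_{period}_raw"] / len(cols)
    out["sed_total"] = sum(out[f"sed_{p}_raw"] for p in periods)

    icats, scats, indices, counts = [], [], [], []
    int_cols = [f"cp_int_{i}" for i in range(1, 6)]
    site_cols = [f"cp_site_{s}" for s in SITE_NAMES]
    for _, row in df.iterrows():
        has_cp = bool(row["cp_has"])
        if has_cp:
            items = [float(row[c]) for c in int_cols]
            flags = [bool(row[c]) for c in site_cols]
            cp = categorize_cp(True, items, flags)
        else:
            cp = categorize_cp(False)
        icats.append(cp.interference_category)
        scats.append(cp.sites_category)
        indices.append(cp.interference_index)
        counts.append(cp.sites_count)
    out["cp_interference_index"] = indices
    out["cp_sites_count"] = counts
    out["cp_interference_cat"] = icats
    out["cp_sites_cat"] = scats
    return out
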