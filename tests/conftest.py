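import numpy as np
import pandas as pd
import pytest

import lcpain as lp

# Independent transcription of the published high-risk thresholds, used as
# a brute-force oracle against the packaged configuration.  "u" = at risk
# when >= value, "l" = at risk when <= value, "b" = either tail.
ORACLE_THRESHOLDS = {
    "dheas": ("b", 51, 141),
    "urine_cortisol": ("b", 6.70, 19),
    "urine_epinephrine": ("u", 2.46),
    "urine_norepinephrine": ("u", 32.96),
    "urine_dopamine": ("u", 182.96),
    "hfhrv": ("l", 55.90),
    "lfhrv": ("l", 103.40),
    "rmssd": ("l", 12.02),
    "sdrr": ("l", 23.27),
    "resting_hr": ("u", 79.80),
    "sbp": ("u", 144),
    "dbp": ("u", 82),
    "fasting_glucose": ("u", 105),
    "hba1c": ("u", 6.24),
    "homa_ir": ("u", 4.36),
    "triglycerides": ("u", 156),
    "whr": ("u", 0.97),
    "bmi": ("u", 33.03),
    "ldl": ("u", 127),
    "hdl": ("l", 43),
    "crp": ("u", 3.66),
    "il6": ("u", 1.23),
    "tnf_alpha": ("u", 2.51),
    "fibrinogen": ("u", 399),
    "se_selectin": ("u", 51.88),
    "icam1": ("u", 335.19),
    "igf1": ("u", 157),
}


def oracle_al_score(panel: dict) -> int:
    """Brute-force flag count applying each threshold independently."""
    score = 0
    for name, rule in ORACLE_THRESHOLDS.items():
        v = panel[name]
        if rule[0] == "u":
            score += v >= rule[1]
        elif rule[0] == "l":
            score += v <= rule[1]
        else:
            score += (v <= rule[1]) or (v >= rule[2])
    return int(score)


SAFE_PANEL = {
    "dheas": 90, "urine_cortisol": 10, "urine_epinephrine": 1.0,
    "urine_norepinephrine": 20, "urine_dopamine": 100, "hfhrv": 200,
    "lfhrv": 200, "rmssd": 30, "sdrr": 40, "resting_hr": 60, "sbp": 120,
    "dbp": 70, "fasting_glucose": 90, "hba1c": 5.0, "homa_ir": 2.0,
    "triglycerides": 100, "whr": 0.8, "bmi": 24, "ldl": 100, "hdl": 60,
    "crp": 1.0, "il6": 1.0, "tnf_alpha": 2.0, "fibrinogen": 300,
    "se_selectin": 40, "icam1": 250, "igf1": 120,
}

RISK_PANEL = {
    "dheas": 200, "urine_cortisol": 25, "urine_epinephrine": 5.0,
    "urine_norepinephrine": 50, "urine_dopamine": 200, "hfhrv": 10,
    "lfhrv": 50, "rmssd": 5, "sdrr": 10, "resting_hr": 90, "sbp": 160,
    "dbp": 95, "fasting_glucose": 200, "hba1c": 8.0, "homa_ir": 6.0,
    "triglycerides": 200, "whr": 1.1, "bmi": 40, "ldl": 160, "hdl": 30,
    "crp": 5.0, "il6": 3.0, "tnf_alpha": 4.0, "fibrinogen": 450,
    "se_selectin": 60, "icam1": 400, "igf1": 200,
}


def random_panels(n: int, seed: int) -> list[dict]:
    """Random panels spanning both sides of every threshold."""
    rng = np.random.default_rng(seed)
    panels = []
    for _ in range(n):
        panel = {}
        for name, rule in ORACLE_THRESHOLDS.items():
            anchor = rule[1] if rule[0] != "b" else 0.5 * (rule[1] + rule[2])
            panel[name] = float(anchor * rng.uniform(0.3, 1.9))
        panels.append(panel)
    return panels


@pytest.fixture
def safe_panel():
    return dict(SAFE_PANEL)


@pytest.fixture
def risk_panel():
    return dict(RISK_PANEL)


@pytest.fixture(scope="session")
def small_cohort():
    """A default-condition cohort, count-mode AL, for fast model tests."""
    return lp.generate_cohort(lp.CohortConfig(n=800, seed=11, al_mode="count"))


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    scores = lp.score_cohort(small_cohort.data)
    scores.insert(0, "id", small_cohort.data["id"].to_numpy())
    return scores
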