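"""Score allostatic load, cumulative SED and chronic-pain categories for a
single respondent.

The AL index counts biomarkers in their published high-risk quartile
region (0-27); period SED sums 0/1/2 item codes (childhood 0-8, adult
waves 0-12, life course 0-32); pain is categorized by interference
(mean of five 0-10 items, low <= 4 < high) and by site count (0-2 vs 3+).
"""

import lcpain as lp
from lcpain.indices import SedItems

# a mostly healthy panel with elevated glucose and inflammation
panel = {
    "dheas": 90, "urine_cortisol": 10, "urine_epinephrine": 1.0,
    "urine_norepinephrine": 20, "urine_dopamine": 100, "hfhrv": 200,
    "lfhrv": 200, "rmssd": 30, "sdrr": 40, "resting_hr": 60, "sbp": 120,
    "dbp": 70, "fasting_glucose": 110, "hba1c": 5.0, "homa_ir": 2.0,
    "triglycerides": 100, "whr": 0.8, "bmi": 24, "ldl": 100, "hdl": 60,
    "crp": 4.0, "il6": 1.0, "tnf_alpha": 2.0, "fibrinogen": 300,
    "se_selectin": 40, "icam1": 250, "igf1": 120,
}
al = lp.score_al(panel)
flagged = [k for k, v in al.flags.items() if v]
print(f"AL index: {al.score} / 27 (flagged: {', '.join(flagged)})")

child = lp.score_sed_period(SedItems("childhood", (1, 1, 0, 1)))
m1 = lp.score_sed_period(SedItems("midus1", (0, 1, 1, 0, 0, 1)))
m2 = lp.score_sed_period(SedItems("midus2", (1, 1, 2, 1, 0, 1)))
total = lp.score_sed_total(child, m1, m2)
print(f"SED: childhood {child.raw}/8, wave1 {m1.raw}/12, wave2 {m2.raw}/12, "
      f"life course {total}/32 (standardized childhood {child.standardized:.2f})")

cp = lp.categorize_cp(True, (5, 6, 7, 3, 9),
                      [s in ("back", "knees") for s in
                       ("head", "neck", "back", "arms", "legs", "shoulders",
                        "hips", "knees", "other")])
print(f"CP: interference index {cp.interference_index:.1f} -> "
      f"{cp.interference_category}; {cp.sites_count} sites -> {cp.sites_category}")
# A score of 2 here means exactly two physiological systems were flagged
# at risk; the pain report is high-interference but not widespread.
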