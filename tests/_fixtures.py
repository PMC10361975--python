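"""Hand-written 12-sample visit-level fixture with known missing
patterns, exercising every cleaning rule including both 50 % boundary
cases.  All expected counts below are computed by hand from the rows.

Fate of each sample (observation window 2014-2015, outcome 2016-2018):

* S01 fully observed; HbA1c 6.5 / FPG 126 in 2017 -> label 1 (both
  thresholds met exactly).
* S02 fully observed; 6.4 / 125 in 2016 -> label 0 (below both).
* S03 observed only in 2014 -> dropped by the observation filter.
* S04 HbA1c measured in the outcome window but FPG never -> excluded at
  outcome extraction.
* S05 three visits in 2014 (FPG 100/110/120 -> mean 110, UP -,-,+ ->
  mode (-)); 7.0 / 150 in 2016 -> label 1.
* S06 two visits in 2014 with UP tied (-),(+) -> tie breaks to (-).
* S07 five of ten surviving cells observed (exactly half) -> retained.
* S08 four of ten surviving cells observed -> dropped.
* S09-S12 fillers tuning the feature missing fractions.

Feature missingness over the 10 samples x 2 observation years reaching
the feature filter (S03, S04 already gone): FPG 10/20 = 50 % -> removed
(boundary), Hb 9/20 = 45 % -> kept, UP 7/20 -> kept, Age/Sex/HbA1c
2/20 -> kept.  Survivors: Age, Sex, HbA1c, Hb, UP; encoded width
3 x 2 years + Sex + Age = 8.
"""

import numpy as np
import pandas as pd

FIXTURE_FEATURES = ["Age", "Sex", "HbA1c", "Hb", "FPG", "UP"]

EXPECTED = {
    "aggregated_samples": 12,
    "after_observation_filter": 11,
    "after_outcome_extraction": 10,
    "positives": {"S01", "S05"},
    "features_before": 6,
    "features_after": 5,
    "removed_features": {"FPG"},
    "after_sample_filter": 9,
    "dropped_samples": {"S03", "S04", "S08"},
    "encoded_width": 8,
}


def _row(sid, year, visit=1, age=np.nan, sex=None, hba1c=np.nan,
         hb=np.nan, fpg=np.nan, up=None):
    return {"sample_id": sid, "institution": "fixture", "year": year,
            "visit_index": visit, "Age": age, "Sex": sex, "HbA1c": hba1c,
            "Hb": hb, "FPG": fpg, "UP": up}


def fixture_visits() -> pd.DataFrame:
    rows = [
        # S01: everything observed; exact-threshold outcome in 2017.
        _row("S01", 2014, age=60, sex="M", hba1c=5.6, hb=13.0, fpg=95, up="(-)"),
        _row("S01", 2015, age=61, sex="M", hba1c=5.7, hb=13.1, fpg=96, up="(-)"),
        _row("S01", 2017, hba1c=6.5, fpg=126.0),
        # S02: everything observed; below both thresholds.
        _row("S02", 2014, age=55, sex="F", hba1c=5.4, hb=12.0, fpg=90, up="(-)"),
        _row("S02", 2015, age=56, sex="F", hba1c=5.5, hb=12.1, fpg=91, up="(+)"),
        _row("S02", 2016, hba1c=6.4, fpg=125.0),
        # S03: 2014 only -> fails the observation filter.
        _row("S03", 2014, age=70, sex="M", hba1c=5.9, hb=14.0, fpg=100, up="(-)"),
        _row("S03", 2017, hba1c=7.0, fpg=150.0),
        # S04: HbA1c in the outcome window but FPG never measured.
        _row("S04", 2014, age=65, sex="F", hba1c=5.8, hb=13.5, up="(-)"),
        _row("S04", 2015, age=66, sex="F", hba1c=5.9, hb=13.6, up="(-)"),
        _row("S04", 2016, hba1c=7.2),
        _row("S04", 2018, hba1c=7.5),
        # S05: three 2014 visits exercising mean and mode aggregation.
        _row("S05", 2014, 1, age=50, sex="M", hba1c=5.5, hb=15.0, fpg=100, up="(-)"),
        _row("S05", 2014, 2, fpg=110, up="(-)"),
        _row("S05", 2014, 3, fpg=120, up="(+)"),
        _row("S05", 2015, age=51, sex="M", hba1c=5.6, hb=np.nan, up="(-)"),
        _row("S05", 2016, hba1c=7.0, fpg=150.0),
        # S06: tied 2014 UP mode -> most benign category wins.
        _row("S06", 2014, 1, age=45, sex="F", hba1c=5.2, hb=12.5, up="(-)"),
        _row("S06", 2014, 2, up="(+)"),
        _row("S06", 2015, age=46, sex="F", hba1c=5.3, hb=12.6, up="(-)"),
        _row("S06", 2018, hba1c=5.0, fpg=90.0),
        # S07: exactly half of the surviving cells (5/10) -> retained.
        _row("S07", 2014, age=58, sex="M", hba1c=5.5, hb=13.2, up="(-)"),
        _row("S07", 2015, fpg=99),  # passes the observation filter via FPG
        _row("S07", 2017, hba1c=5.5, fpg=100.0),
        # S08: 4/10 surviving cells -> dropped by the sample filter.
        _row("S08", 2014, age=59, sex="F", hba1c=5.6, hb=13.3),
        _row("S08", 2015, fpg=98),
        _row("S08", 2017, hba1c=5.5, fpg=100.0),
        # S09-S12: fillers with chosen missing patterns.
        _row("S09", 2014, age=62, sex="M", hba1c=5.7),
        _row("S09", 2015, age=63, sex="M", hba1c=5.8),
        _row("S09", 2016, hba1c=5.9, fpg=101.0),
        _row("S10", 2014, age=48, sex="F", hba1c=5.3),
        _row("S10", 2015, age=49, sex="F", hba1c=5.4, up="(-)"),
        _row("S10", 2016, hba1c=5.5, fpg=95.0),
        _row("S11", 2014, age=52, sex="M", hba1c=5.5, fpg=97, up="(-)"),
        _row("S11", 2015, age=53, sex="M", hba1c=5.6),
        _row("S11", 2016, hba1c=5.7, fpg=99.0),
        _row("S12", 2014, age=67, sex="F", hba1c=5.9, hb=13.8, fpg=102, up="(-)"),
        _row("S12", 2015, age=68, sex="F", hba1c=6.0, hb=13.9, fpg=103, up="(-)"),
        _row("S12", 2016, hba1c=6.1, fpg=104.0),
    ]
    return pd.DataFrame(rows)
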