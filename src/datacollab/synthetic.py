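"""Synthetic two-institution health-checkup cohorts.

Generates visit-level records that mimic the statistical structure of two
real-world data sources: a municipal specified-health-checkup programme
(one checkup per person per year, fasting glucose and urinary glucose
rarely measured) and a university-hospital examination history (several
visits per year, casual glucose and creatinine rarely measured).  Each
person carries a latent diabetes-onset class; class-conditional feature
distributions default to published cohort statistics, and glycaemia in
the outcome window 2016--2018 is constructed so that the diagnostic rule
(HbA1c >= 6.5 % and FPG >= 126 mg/dl on one occasion) recovers the
generating class exactly.

Features are drawn independently given the class.  Missingness is
completely at random per value.  Quantitative values are clipped at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    FEATURE_NAMES,
    FPG_THRESHOLD,
    HBA1C_THRESHOLD,
    get_feature,
)

OBSERVATION_YEARS: tuple[int, ...] = (2014, 2015)
OUTCOME_YEARS: tuple[int, ...] = (2016, 2017, 2018)
DEFAULT_YEARS: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)

VISIT_COLUMNS = ("sample_id", "institution", "year", "visit_index")


@dataclass(frozen=True)
class VisitModel:
    """Number of measurement occasions per person per year.

    ``fixed``: exactly ``round(mean)`` visits.  ``poisson``: 1 plus a
    Poisson draw with rate ``mean - 1``, i.e. at least one visit per year
    with the stated mean.
    """

    kind: str = "fixed"
    mean: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "poisson"):
            raise ValueError(f"unknown visit model kind {self.kind!r}")
        if self.mean < 1:
            raise ValueError("visit model mean must be >= 1")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, int(round(self.mean)), dtype=int)
        return 1 + rng.poisson(self.mean - 1.0, size=n)


@dataclass(frozen=True)
class FeatureSpec:
    """Class-conditional generating distribution of one feature.

    For quantitative features ``mean``/``sd`` hold (negative, positive)
    class values; for qualitative features ``freqs`` holds per-class
    category frequencies in the order of the feature's category scale.
    """

    kind: str  # quantitative | ordinal | binary
    mean: tuple[float, float] | None = None
    sd: tuple[float, float] | None = None
    freqs: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.kind == "quantitative":
            if self.mean is None or self.sd is None:
                raise ValueError("quantitative spec needs mean and sd")
            if any(s <= 0 for s in self.sd):
                raise ValueError("standard deviations must be > 0")
        else:
            if self.freqs is None:
                raise ValueError("qualitative spec needs category freqs")
            for fr in self.freqs:
                if abs(sum(fr) - 1.0) > 1e-8:
                    raise ValueError("category frequencies must sum to 1")
                if any(p < 0 for p in fr):
                    raise ValueError("category frequencies must be >= 0")


@dataclass(frozen=True)
class InstitutionProfile:
    """Generating profile of one institution's cohort."""

    name: str
    n_samples: int
    feature_specs: dict[str, FeatureSpec]
    prevalence: float
    years: tuple[int, ...] = DEFAULT_YEARS
    visit_model: VisitModel = VisitModel("fixed", 1.0)
    drift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        unknown = set(self.feature_specs) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in profile: {sorted(unknown)}")

    def with_overrides(self, **kwargs) -> "InstitutionProfile":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """Visit-level records plus the generating (latent) outcome class."""

    visits: pd.DataFrame
    true_labels: pd.Series  # index: sample_id, values in {0, 1}

    @property
    def n_samples(self) -> int:
        return len(self.true_labels)


def default_profiles() -> tuple[InstitutionProfile, InstitutionProfile]:
    """Default checkup and hospital profiles.

    Class-conditional means/SDs of the eleven features retained in the
    reference cohorts come from their published 2015 statistics
    (e.g. checkup positives: HbA1c 6.4 (0.4); checkup negatives: Age
    64.5 (6.8); hospital positives: HbA1c 7.0 (0.9)).  Fasting glucose,
    casual glucose, creatinine and urinary glucose are not tabulated
    there (removed for high missingness), so plausible clinical values
    are used; their missing rates are set so that the 50 % feature filter
    removes FPG and urinary glucose from the checkup data and casual
    glucose and creatinine from the hospital data.
    """
    checkup_specs = {
        "Age": FeatureSpec("quantitative", (64.5, 66.5), (6.8, 3.8), missing_rate=0.02),
        "Sex": FeatureSpec("binary",
                           freqs=((650 / 1356, 706 / 1356), (16 / 43, 27 / 43))),
        "HbA1c": FeatureSpec("quantitative", (5.8, 6.4), (0.4, 0.4), missing_rate=0.05),
        "Hb": FeatureSpec("quantitative", (12.0, 14.5), (1.1, 1.1), missing_rate=0.05),
        "FPG": FeatureSpec("quantitative", (98.0, 135.0), (12.0, 25.0), missing_rate=0.60),
        "CBG": FeatureSpec("quantitative", (110.0, 150.0), (25.0, 40.0), missing_rate=0.30),
        "RBC": FeatureSpec("quantitative", (457.9, 476.9), (34.9, 34.2), missing_rate=0.05),
        "UG": FeatureSpec("ordinal",
                          freqs=((0.95, 0.03, 0.01, 0.007, 0.003),
                                 (0.55, 0.15, 0.12, 0.10, 0.08)),
                          missing_rate=0.55),
        "UP": FeatureSpec("ordinal",
                          freqs=((1279 / 1356, 77 / 1356, 0.0, 0.0, 0.0),
                                 (40 / 43, 3 / 43, 0.0, 0.0, 0.0)),
                          missing_rate=0.05),
        "HDL-C": FeatureSpec("quantitative", (63.7, 57.8), (15.3, 14.4), missing_rate=0.05),
        "LDL-C": FeatureSpec("quantitative", (121.5, 117.7), (26.8, 25.0), missing_rate=0.05),
        "AST": FeatureSpec("quantitative", (23.4, 24.3), (5.6, 6.4), missing_rate=0.05),
        "GGT": FeatureSpec("quantitative", (29.3, 34.9), (19.3, 23.2), missing_rate=0.05),
        "Scr": FeatureSpec("quantitative", (0.75, 0.80), (0.20, 0.30), missing_rate=0.20),
        "Hct": FeatureSpec("quantitative", (42.1, 43.6), (2.9, 2.6), missing_rate=0.05),
    }
    hospital_specs = {
        "Age": FeatureSpec("quantitative", (58.8, 65.0), (18.8, 13.5), missing_rate=0.05),
        "Sex": FeatureSpec("binary",
                           freqs=((600 / 1293, 693 / 1293), (83 / 209, 126 / 209))),
        "HbA1c": FeatureSpec("quantitative", (6.2, 7.0), (0.8, 0.9), missing_rate=0.05),
        "Hb": FeatureSpec("quantitative", (13.0, 12.9), (1.7, 1.9), missing_rate=0.05),
        "FPG": FeatureSpec("quantitative", (102.0, 150.0), (15.0, 35.0), missing_rate=0.10),
        "CBG": FeatureSpec("quantitative", (110.0, 150.0), (25.0, 40.0), missing_rate=0.85),
        "RBC": FeatureSpec("quantitative", (431.2, 424.9), (56.8, 62.3), missing_rate=0.05),
        "UG": FeatureSpec("ordinal",
                          freqs=((0.90, 0.04, 0.03, 0.02, 0.01),
                                 (0.60, 0.10, 0.10, 0.10, 0.10)),
                          missing_rate=0.10),
        "UP": FeatureSpec("ordinal",
                          freqs=((1160 / 1293, 22 / 1293, 34 / 1293, 56 / 1293, 21 / 1293),
                                 (166 / 209, 12 / 209, 9 / 209, 11 / 209, 11 / 209)),
                          missing_rate=0.05),
        "HDL-C": FeatureSpec("quantitative", (51.1, 49.3), (10.7, 11.8), missing_rate=0.05),
        "LDL-C": FeatureSpec("quantitative", (105.6, 101.5), (22.1, 24.5), missing_rate=0.05),
        "AST": FeatureSpec("quantitative", (27.6, 28.7), (14.4, 15.0), missing_rate=0.05),
        "GGT": FeatureSpec("quantitative", (40.7, 44.2), (36.2, 35.5), missing_rate=0.05),
        "Scr": FeatureSpec("quantitative", (0.75, 0.85), (0.20, 0.35), missing_rate=0.85),
        "Hct": FeatureSpec("quantitative", (38.8, 38.4), (4.6, 5.1), missing_rate=0.05),
    }
    checkup = InstitutionProfile(
        name="checkup",
        n_samples=1399,
        feature_specs=checkup_specs,
        prevalence=43 / 1399,
        visit_model=VisitModel("fixed", 1.0),
    )
    hospital = InstitutionProfile(
        name="hospital",
        n_samples=1502,
        feature_specs=hospital_specs,
        prevalence=209 / 1502,
        visit_model=VisitModel("poisson", 3.0),
    )
    return checkup, hospital


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray,
                      sd: np.ndarray, lower: float, size: int) -> np.ndarray:
    """Normal draws constrained to [lower, inf)."""
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               size=size, random_state=rng)


def _draw_categorical(rng: np.random.Generator, freqs_by_class: tuple,
                      cls: np.ndarray, categories: tuple[str, ...]) -> np.ndarray:
    """Class-conditional categorical draw; returns category labels."""
    out = np.empty(cls.shape[0], dtype=object)
    u = rng.random(cls.shape[0])
    for c in (0, 1):
        mask = cls == c
        if not mask.any():
            continue
        cum = np.cumsum(freqs_by_class[c])
        cum[-1] = 1.0  # guard rounding
        idx = np.searchsorted(cum, u[mask], side="right")
        idx = np.minimum(idx, len(categories) - 1)
        out[mask] = np.asarray(categories, dtype=object)[idx]
    return out


def generate_institution(profile: InstitutionProfile, seed: int) -> SyntheticCohort:
    """Draw a full visit-level cohort for one institution.

    Deterministic given ``(profile, seed)``.  Raises ``ValueError`` if the
    profile's year span does not cover both the observation window
    (2014--2015) and the outcome window (2016--2018).
    """
    years = set(profile.years)
    if not (set(OBSERVATION_YEARS) <= years and set(OUTCOME_YEARS) <= years):
        raise ValueError(
            "profile years must cover the observation window 2014-2015 "
            "and the outcome window 2016-2018"
        )
    rng = np.random.default_rng(seed)
    n = profile.n_samples
    sample_ids = np.array(
        [f"{profile.name}-{i:05d}" for i in range(n)], dtype=object
    )
    cls = (rng.random(n) < profile.prevalence).astype(int)

    # Per-person constants.
    sex_spec = profile.feature_specs["Sex"]
    sex = _draw_categorical(rng, sex_spec.freqs, cls, get_feature("Sex").categories)
    age_spec = profile.feature_specs["Age"]
    first_year = min(profile.years)
    age0 = np.clip(
        rng.normal(np.take(age_spec.mean, cls), np.take(age_spec.sd, cls)), 0, None
    )

    frames = []
    for year in sorted(profile.years):
        counts = profile.visit_model.draw(rng, n) if n else np.zeros(0, dtype=int)
        s_idx = np.repeat(np.arange(n), counts)
        m = s_idx.shape[0]
        visit_index = np.concatenate(
            [np.arange(1, c + 1) for c in counts]
        ) if m else np.zeros(0, dtype=int)
        occ_cls = cls[s_idx]
        data: dict[str, np.ndarray] = {
            "sample_id": sample_ids[s_idx],
            "institution": np.full(m, profile.name, dtype=object),
            "year": np.full(m, year, dtype=int),
            "visit_index": visit_index,
        }
        for fname in FEATURE_NAMES:
            spec = profile.feature_specs[fname]
            feat = get_feature(fname)
            offset = profile.drift.get(fname, 0.0)
            if fname == "Sex":
                vals = sex[s_idx].copy()
            elif fname == "Age":
                vals = age0[s_idx] + (year - first_year) + offset
            elif feat.kind == "quantitative":
                mean = np.take(spec.mean, occ_cls) + offset
                sd = np.take(spec.sd, occ_cls)
                vals = rng.normal(mean, sd)
                if fname in ("HbA1c", "FPG") and year in OUTCOME_YEARS:
                    vals = _outcome_year_values(rng, fname, vals, mean, sd, occ_cls)
                vals = np.clip(vals, 0.0, None)
            else:
                vals = _draw_categorical(rng, spec.freqs, occ_cls, feat.categories)
            # MCAR masking.
            if spec.missing_rate > 0 and m:
                miss = rng.random(m) < spec.missing_rate
                if feat.is_qualitative:
                    vals = vals.copy()
                    vals[miss] = None
                else:
                    vals = vals.astype(float)
                    vals[miss] = np.nan
            data[fname] = vals
        frames.append(pd.DataFrame(data))

    if frames:
        visits = pd.concat(frames, ignore_index=True)
    else:
        visits = pd.DataFrame(columns=list(VISIT_COLUMNS) + list(FEATURE_NAMES))
    # Negative samples must never satisfy both diagnostic criteria on one
    # occasion; cap FPG just under threshold where HbA1c crossed.
    if len(visits):
        neg = visits["sample_id"].map(
            pd.Series(cls, index=sample_ids)
        ).to_numpy() == 0
        outcome = visits["year"].isin(OUTCOME_YEARS).to_numpy()
        hba = visits["HbA1c"].to_numpy(dtype=float)
        fpg = visits["FPG"].to_numpy(dtype=float)
        clash = neg & outcome & (hba >= HBA1C_THRESHOLD) & (fpg >= FPG_THRESHOLD)
        fpg[clash] = FPG_THRESHOLD - 1.0
        visits["FPG"] = fpg
    labels = pd.Series(cls, index=pd.Index(sample_ids, name="sample_id"),
                       name="outcome")
    return SyntheticCohort(visits=visits, true_labels=labels)


def _outcome_year_values(rng, fname, vals, mean, sd, occ_cls):
    """Glycaemia in the outcome window: positives persistently cross the
    diagnostic threshold, so the label is recoverable under any missing
    pattern of the remaining occasions."""
    threshold = HBA1C_THRESHOLD if fname == "HbA1c" else FPG_THRESHOLD
    pos = occ_cls == 1
    if pos.any():
        vals = vals.copy()
        vals[pos] = _truncated_normal(
            rng, mean[pos], sd[pos], threshold, int(pos.sum())
        )
    return vals


# ---------------------------------------------------------------------------
# CSV interchange: comma-separated, UTF-8, header row, empty field = missing.

def write_visits(visits: pd.DataFrame, path) -> None:
    visits.to_csv(path, index=False, na_rep="")


def read_visits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "institution": str})
    for fname in FEATURE_NAMES:
        if fname in df.columns and get_feature(fname).is_qualitative:
            col = df[fname].astype(object)
            col[pd.isna(col)] = None
            df[fname] = col
    return df


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("outcome").to_csv(path, header=True)


def expected_positive_rate(profile: InstitutionProfile) -> float:
    return profile.prevalence


def realized_positive_fraction(cohort: SyntheticCohort) -> float:
    if cohort.n_samples == 0:
        return math.nan
    return float(cohort.true_labels.mean())
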