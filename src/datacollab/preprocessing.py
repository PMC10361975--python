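"""Cleaning pipeline from visit-level records to a model-ready matrix.

The pipeline mirrors a two-year observation / three-year outcome design
for diabetes-onset prediction:

1. aggregate multiple visits per year (mean for quantitative features,
   mode for qualitative features);
2. keep samples observed at least once in every observation year
   (2014 and 2015);
3. label outcomes from the 2016--2018 window: a sample is retained only
   if HbA1c and fasting plasma glucose were both measured on at least
   one occasion, and labelled diabetic if both diagnostic thresholds
   (HbA1c >= 6.5 %, FPG >= 126 mg/dl) were met on one such occasion;
4. remove features missing in at least half of the observation cells;
5. remove samples with fewer than half of the surviving feature cells;
6. impute the remainder (column mean / column mode) and encode to a
   numeric matrix with one column per (feature, year), a single sex
   column and a single age column.

Sample sparsity is assessed before imputation (afterwards nothing is
missing, so the filter would be vacuous).  Mode ties break toward the
smallest ordinal code, i.e. the most benign category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    FEATURE_NAMES,
    FPG_THRESHOLD,
    HBA1C_THRESHOLD,
    get_feature,
)
from .synthetic import OBSERVATION_YEARS, OUTCOME_YEARS

__all__ = [
    "YearlyTable",
    "LabeledDataset",
    "PreparedData",
    "aggregate_by_year",
    "filter_observation_presence",
    "assign_outcome_labels",
    "drop_sparse_features",
    "drop_sparse_samples",
    "fit_impute_stats",
    "impute_missing",
    "encode_features",
    "clean_institution",
    "prepare_institution",
    "common_feature_set",
]


@dataclass
class YearlyTable:
    """One row per (sample, year); cells may be missing."""

    frame: pd.DataFrame  # MultiIndex (sample_id, year); feature columns

    @property
    def samples(self) -> pd.Index:
        return self.frame.index.get_level_values("sample_id").unique()

    @property
    def features(self) -> list[str]:
        return list(self.frame.columns)

    def restrict_samples(self, sample_ids) -> "YearlyTable":
        keep = self.frame.index.get_level_values("sample_id").isin(set(sample_ids))
        return YearlyTable(self.frame.loc[keep])

    def grid(self, years) -> pd.DataFrame:
        """Reindex to the full sample x year grid; absent rows are missing."""
        idx = pd.MultiIndex.from_product(
            [self.samples, sorted(years)], names=["sample_id", "year"]
        )
        return self.frame.reindex(idx)


@dataclass
class LabeledDataset:
    """Encoded feature matrix with binary diabetes labels (1 = diabetic)."""

    X: pd.DataFrame          # index sample_id, float columns (NaN allowed pre-imputation)
    y: pd.Series             # aligned with X.index, values in {0, 1}
    feature_kinds: dict[str, str]
    institution: str

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        if list(self.X.index) != list(self.y.index):
            raise ValueError("X and y are not aligned")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary")
        if self.X.shape[1] != len(self.feature_kinds):
            raise ValueError("feature metadata does not match matrix width")


@dataclass
class CleanResult:
    table: YearlyTable
    labels: pd.Series
    survivors: list[str]
    log: list[str] = field(default_factory=list)


@dataclass
class PreparedData:
    dataset: LabeledDataset
    survivors: list[str]
    log: list[str]


def _check_feature_columns(columns) -> list[str]:
    feats = [c for c in columns if c not in ("sample_id", "institution",
                                             "year", "visit_index")]
    unknown = [c for c in feats if c not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown}")
    return feats


def _qual_mode(values, categories) -> object:
    """Mode of category labels; ties break to the smallest ordinal code."""
    counts = np.zeros(len(categories), dtype=int)
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        counts[categories.index(v)] += 1
    if counts.sum() == 0:
        return None
    return categories[int(np.argmax(counts))]  # argmax returns first max


def aggregate_by_year(visits: pd.DataFrame) -> YearlyTable:
    """Collapse visits to one row per (sample, year).

    Quantitative cells become the mean of the observed visit values,
    qualitative cells the mode; a cell is missing only when every visit
    value was missing.
    """
    feats = _check_feature_columns(visits.columns)
    if len(visits) == 0:
        empty = pd.DataFrame(
            columns=feats,
            index=pd.MultiIndex.from_arrays([[], []], names=["sample_id", "year"]),
        )
        return YearlyTable(empty)
    grouped = visits.groupby(["sample_id", "year"], sort=True)
    parts = {}
    for fname in feats:
        feat = get_feature(fname)
        if feat.is_qualitative:
            cats = list(feat.categories)
            parts[fname] = grouped[fname].agg(
                lambda s, _c=cats: _qual_mode(s.tolist(), _c)
            )
        else:
            parts[fname] = grouped[fname].mean()
    frame = pd.DataFrame(parts)[feats]
    return YearlyTable(frame)


def filter_observation_presence(table: YearlyTable,
                                obs_years=OBSERVATION_YEARS) -> YearlyTable:
    """Keep samples with at least one observed feature in every
    observation year."""
    obs_years = set(obs_years)
    if not obs_years:
        raise ValueError("obs_years must not be empty")
    if len(table.frame) == 0:
        return table
    frame = table.frame
    years = frame.index.get_level_values("year")
    present = frame.notna().any(axis=1)
    ok_rows = frame.index[present & years.isin(obs_years)]
    seen = pd.DataFrame(
        {"sample_id": ok_rows.get_level_values("sample_id"),
         "year": ok_rows.get_level_values("year")}
    )
    counts = seen.groupby("sample_id")["year"].nunique()
    keep = counts.index[counts == len(obs_years)]
    return table.restrict_samples(keep)


def assign_outcome_labels(table: YearlyTable,
                          visits: pd.DataFrame | None = None,
                          outcome_years=OUTCOME_YEARS,
                          hba1c_thr: float = HBA1C_THRESHOLD,
                          fpg_thr: float = FPG_THRESHOLD) -> pd.Series:
    """Binary outcome per retained sample.

    A sample is retained only if HbA1c and FPG are both non-missing on
    at least one occasion in the outcome window; among those it is
    labelled 1 iff both diagnostic thresholds are met on one occasion.
    Occasions are individual visits when visit-level data are supplied,
    yearly aggregate rows otherwise.  Returns a Series indexed by the
    retained sample ids.
    """
    if hba1c_thr <= 0 or fpg_thr <= 0:
        raise ValueError("diagnostic thresholds must be positive")
    outcome_years = set(outcome_years)
    if visits is not None:
        occ = visits[visits["year"].isin(outcome_years)]
        sample_ids = occ["sample_id"].to_numpy()
        hba = occ["HbA1c"].to_numpy(dtype=float)
        fpg = occ["FPG"].to_numpy(dtype=float)
    else:
        frame = table.frame
        mask = frame.index.get_level_values("year").isin(outcome_years)
        occ = frame.loc[mask]
        sample_ids = occ.index.get_level_values("sample_id").to_numpy()
        hba = occ["HbA1c"].to_numpy(dtype=float)
        fpg = occ["FPG"].to_numpy(dtype=float)
    table_samples = set(table.samples)
    both = ~np.isnan(hba) & ~np.isnan(fpg)
    hit = both & (hba >= hba1c_thr) & (fpg >= fpg_thr)
    occ_df = pd.DataFrame({"sample_id": sample_ids, "both": both, "hit": hit})
    per_sample = occ_df.groupby("sample_id").agg(
        retained=("both", "any"), label=("hit", "any")
    )
    per_sample = per_sample[per_sample["retained"]]
    per_sample = per_sample.loc[per_sample.index.isin(table_samples)]
    return per_sample["label"].astype(int).rename("outcome").sort_index()


def drop_sparse_features(table: YearlyTable,
                         obs_years=OBSERVATION_YEARS,
                         max_missing: float = 0.5) -> tuple[YearlyTable, list[str]]:
    """Remove features missing in at least ``max_missing`` of the
    observation-window cells (a feature at exactly the threshold is
    removed)."""
    if len(table.frame) == 0:
        return table, table.features
    grid = table.grid(obs_years)
    frac = grid.isna().mean(axis=0)
    survivors = [c for c in table.features if frac[c] < max_missing]
    return YearlyTable(table.frame[survivors]), survivors


def drop_sparse_samples(table: YearlyTable,
                        obs_years=OBSERVATION_YEARS,
                        min_fraction: float = 0.5) -> YearlyTable:
    """Remove samples observing fewer than ``min_fraction`` of the
    surviving feature cells across the observation years (a sample at
    exactly the fraction is retained)."""
    if len(table.frame) == 0:
        return table
    grid = table.grid(obs_years)
    present = grid.notna().groupby(level="sample_id", sort=False).sum().sum(axis=1)
    total = len(table.features) * len(set(obs_years))
    keep = present.index[present / total >= min_fraction]
    return table.restrict_samples(keep)


# ---------------------------------------------------------------------------
# Imputation: column mean for quantitative, column mode for qualitative.

def fit_impute_stats(frame: pd.DataFrame, kinds: dict[str, str]) -> dict[str, object]:
    """Per-column fill values learned from ``frame``.

    Quantitative columns are filled with the mean of observed values,
    qualitative columns (label- or code-valued) with the mode; mode ties
    break toward the smallest ordinal code.  A fully missing column is an
    error -- there is nothing to learn from.
    """
    stats: dict[str, object] = {}
    for col in frame.columns:
        s = frame[col]
        kind = kinds[col]
        if kind == "quantitative":
            observed = s.to_numpy(dtype=float)
            observed = observed[~np.isnan(observed)]
            if observed.size == 0:
                raise ValueError(f"column {col!r} is entirely missing")
            stats[col] = float(observed.mean())
        else:
            if s.dtype == object:
                base = col.split("_")[0]
                cats = list(get_feature(base).categories)
                mode = _qual_mode(s.tolist(), cats)
                if mode is None:
                    raise ValueError(f"column {col!r} is entirely missing")
                stats[col] = mode
            else:
                codes = s.to_numpy(dtype=float)
                codes = codes[~np.isnan(codes)]
                if codes.size == 0:
                    raise ValueError(f"column {col!r} is entirely missing")
                counts = np.bincount(codes.astype(int))
                stats[col] = float(np.argmax(counts))  # first max = smallest code
    return stats


def impute_missing(frame: pd.DataFrame, kinds: dict[str, str],
                   stats: dict[str, object] | None = None
                   ) -> tuple[pd.DataFrame, dict[str, object]]:
    """Fill missing cells; observed values are never changed.

    ``stats`` may be pre-fitted (e.g. on training data only); by default
    the fill values are learned from ``frame`` itself.
    """
    if stats is None:
        stats = fit_impute_stats(frame, kinds)
    out = frame.copy()
    for col in out.columns:
        out[col] = out[col].where(out[col].notna(), stats[col])
    return out, stats


def impute_table(table: YearlyTable, obs_years=OBSERVATION_YEARS) -> YearlyTable:
    """Impute the observation-window cells of a yearly table in place of
    its missing values (outcome-window rows are left untouched; they only
    ever feed the labeller, which requires observed values)."""
    frame = table.frame.copy()
    mask = frame.index.get_level_values("year").isin(set(obs_years))
    kinds = {c: get_feature(c).kind for c in frame.columns}
    filled, _ = impute_missing(frame.loc[mask], kinds)
    frame.loc[mask] = filled
    return YearlyTable(frame)


# ---------------------------------------------------------------------------
# Encoding.

def encode_features(table: YearlyTable, labels: pd.Series,
                    features: list[str] | None = None,
                    obs_years=OBSERVATION_YEARS,
                    institution: str = "") -> LabeledDataset:
    """Numeric matrix: one column per (feature, year) for year-varying
    features, a single sex column (M=1, F=0) and a single age column
    taken from the first observation year.  Urinalysis categories map to
    ordinal codes (-)=0 ... (+++)=4.
    """
    if features is None:
        features = table.features
    years = sorted(set(obs_years))
    samples = labels.index
    grid = table.restrict_samples(samples).grid(years)
    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}

    def encode_series(s: pd.Series, feat) -> np.ndarray:
        if feat.is_qualitative:
            return np.array(
                [np.nan if v is None or (isinstance(v, float) and np.isnan(v))
                 else feat.encode(v) for v in s],
                dtype=float,
            )
        return s.to_numpy(dtype=float)

    for fname in [f for f in FEATURE_NAMES if f in features]:
        feat = get_feature(fname)
        if feat.static:
            # one column; first observation year, falling back to later ones
            vals = None
            for year in years:
                col = encode_series(grid.xs(year, level="year")[fname], feat)
                vals = col if vals is None else np.where(np.isnan(vals), col, vals)
            cols[fname] = vals
            kinds[fname] = feat.kind
        else:
            for year in years:
                name = f"{fname}_{year}"
                cols[name] = encode_series(grid.xs(year, level="year")[fname], feat)
                kinds[name] = feat.kind
    X = pd.DataFrame(cols, index=grid.index.get_level_values("sample_id").unique())
    X = X.loc[samples]
    return LabeledDataset(X=X, y=labels.astype(int), feature_kinds=kinds,
                          institution=institution)


# ---------------------------------------------------------------------------
# Orchestration.

def clean_institution(visits: pd.DataFrame,
                      obs_years=OBSERVATION_YEARS,
                      outcome_years=OUTCOME_YEARS,
                      hba1c_thr: float = HBA1C_THRESHOLD,
                      fpg_thr: float = FPG_THRESHOLD,
                      max_missing: float = 0.5,
                      min_fraction: float = 0.5) -> CleanResult:
    """Aggregation through sample filtering; encoding is left to the
    caller so a cross-institution common feature set can be applied."""
    log: list[str] = []
    table = aggregate_by_year(visits)
    n0 = len(table.samples)
    log.append(f"aggregated: {n0} samples")

    table = filter_observation_presence(table, obs_years)
    log.append(f"observation-window filter: {n0} -> {len(table.samples)} samples")

    labels = assign_outcome_labels(table, visits=visits,
                                   outcome_years=outcome_years,
                                   hba1c_thr=hba1c_thr, fpg_thr=fpg_thr)
    labels = labels.loc[labels.index.isin(set(table.samples))]
    n1 = len(table.samples)
    table = table.restrict_samples(labels.index)
    log.append(f"outcome extraction: {n1} -> {len(labels)} samples "
               f"({int(labels.sum())} positive)")

    d0 = len(table.features)
    table, survivors = drop_sparse_features(table, obs_years, max_missing)
    log.append(f"sparse-feature filter: {d0} -> {len(survivors)} features")

    n2 = len(table.samples)
    table = drop_sparse_samples(table, obs_years, min_fraction)
    labels = labels.loc[labels.index.isin(set(table.samples))].sort_index()
    log.append(f"sparse-sample filter: {n2} -> {len(table.samples)} samples")
    return CleanResult(table=table, labels=labels, survivors=survivors, log=log)


def common_feature_set(*results: CleanResult) -> list[str]:
    """Intersection of surviving features, in canonical feature order
    (the shared dimension d required for collaborative integration)."""
    common = set(results[0].survivors)
    for r in results[1:]:
        common &= set(r.survivors)
    return [f for f in FEATURE_NAMES if f in common]


def prepare_institution(visits: pd.DataFrame,
                        features: list[str] | None = None,
                        impute: bool = True,
                        institution: str = "",
                        **clean_kwargs) -> PreparedData:
    """Full pipeline for one institution.

    With ``impute=False`` the encoded matrix keeps its missing cells so
    that imputation statistics can later be fitted on training data only.
    """
    obs_years = clean_kwargs.get("obs_years", OBSERVATION_YEARS)
    res = clean_institution(visits, **clean_kwargs)
    if impute:
        res.table = impute_table(res.table, obs_years)
        res.log.append("imputation: 0 missing cells remain in the "
                       "observation window")
    use = features if features is not None else res.survivors
    ds = encode_features(res.table, res.labels, features=use,
                         obs_years=obs_years, institution=institution)
    ds.validate()
    res.log.append(f"encoded: {ds.n_samples} samples x {ds.d} columns")
    return PreparedData(dataset=ds, survivors=res.survivors, log=res.log)
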