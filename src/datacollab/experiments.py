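"""Bootstrap comparison of individual, middle and collaborative analyses.

The evaluation design: per replicate, 99 test samples are drawn at
random from the checkup institution; the remaining samples form the
training pool.  "all" uses the full pool, "half" a random half of it and
"quarter" half of that half (nested subsets, mimicking ever smaller
municipalities).  Three training representations are compared on the
same test split:

* ``individual`` — the checkup pool alone, raw features;
* ``middle``     — the checkup pool alone, through its own PCA
  intermediate map (isolates the cost of the confidentiality transform);
* ``dc``         — the checkup pool plus the full hospital cohort,
  integrated by data-collaboration analysis (anchor alignment).

Models: L1-penalised logistic regression on standardised columns, and a
LightGBM gradient-boosted tree ensemble with unrestricted depth,
learning rate 0.1 and 100 estimators.  Metrics: rank-based ROC-AUC and
recall / precision / F1 at probability threshold 0.5, summarised as
mean +- SD over 100 replicates.

Imputation and standardisation statistics are fitted on each replicate's
training subset only and applied to its test split, so no test
information leaks into training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import dc
from .features import get_feature
from .preprocessing import LabeledDataset

logger = logging.getLogger(__name__)

MODES = ("individual", "middle", "dc")
SUBSETS = ("all", "half", "quarter")
MODELS = ("lr_l1", "gbdt")
METRICS = ("auc", "recall", "precision", "f1")

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class DCParams:
    """Collaboration hyper-parameters (the method leaves them free)."""

    method: str = "pca"
    l: int | None = None        # default: min(d-1, ceil(0.75 d))
    k: int | None = None        # default: min over workers of l_i
    r: int = 1000               # anchor rows
    anchor_strategy: str = "uniform"
    scale_workers: bool = True  # private per-worker standardisation before PCA


@dataclass(frozen=True)
class ExperimentConfig:
    mode: str = "individual"
    subset: str = "all"
    model: str = "lr_l1"
    n_replicates: int = 100
    test_size: int = 99
    seed: int = 0
    lr_C: float = 1.0
    gbdt_params: dict = field(default_factory=lambda: {
        "max_depth": -1, "learning_rate": 0.1, "n_estimators": 100,
    })
    dc_params: DCParams = field(default_factory=DCParams)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class MetricsSummary:
    """Replicate-level metrics with their mean and SD."""

    replicates: pd.DataFrame  # index replicate, columns METRICS

    @property
    def mean(self) -> pd.Series:
        return self.replicates.mean()

    @property
    def sd(self) -> pd.Series:
        return self.replicates.std(ddof=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{m}={self.mean[m]:.3f}+-{self.sd[m]:.3f}" for m in METRICS]
        return f"MetricsSummary({', '.join(parts)})"


# ---------------------------------------------------------------------------
# Models and metrics.

def train_model(X: np.ndarray, y: np.ndarray, model: str = "lr_l1",
                seed: int = 0, lr_C: float = 1.0, gbdt_params: dict | None = None):
    """Fit a probabilistic classifier; returns an object with
    ``predict_proba``.  Training labels must contain both classes."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if model == "lr_l1":
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(l1_ratio=1.0, C=lr_C, solver="liblinear",
                                      max_iter=1000, random_state=seed)),
        ])
    elif model == "gbdt":
        from lightgbm import LGBMClassifier
        params = dict(max_depth=-1, learning_rate=0.1, n_estimators=100)
        params.update(gbdt_params or {})
        clf = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                             deterministic=True, force_col_wise=True, **params)
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def predict_scores(clf, X: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper warns about feature names even for
        # plain arrays; the pipeline works on positional columns only
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names")
        return clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> dict[str, float]:
    """AUC (Mann-Whitney rank statistic with tie averaging) plus
    thresholded recall, precision (0 when nothing is predicted positive)
    and F1.  Closed forms are used directly: the evaluation runs on
    thousands of small replicate splits."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined for single-class labels")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = n_pos - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return {"auc": float(auc), "recall": float(recall),
            "precision": float(precision), "f1": float(f1)}


# ---------------------------------------------------------------------------
# Replicate machinery.

def reference_bounds(columns) -> list[tuple[float, float]]:
    """Public per-column anchor bounds from clinical reference ranges
    (encoded column names carry the base feature before the year)."""
    return [get_feature(c.split("_")[0]).reference_range for c in columns]


def _impute_fit(X: np.ndarray, is_qual: np.ndarray) -> np.ndarray:
    """Column fill values: mean (quantitative) or mode with smallest-code
    tie-break (qualitative codes)."""
    fill = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"column {j} entirely missing in training subset")
        if is_qual[j]:
            fill[j] = float(np.argmax(np.bincount(obs.astype(int))))
        else:
            fill[j] = obs.mean()
    return fill


def _impute_apply(X: np.ndarray, fill: np.ndarray) -> np.ndarray:
    out = X.copy()
    nan = np.isnan(out)
    out[nan] = np.broadcast_to(fill, out.shape)[nan]
    return out


def _draw_indices(rng: np.random.Generator, y: np.ndarray,
                  test_size: int) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Test split plus nested all/half/quarter training subsets; any draw
    leaving a single class is redrawn (with a logged warning)."""
    n = len(y)
    if test_size >= n:
        raise ValueError(f"test_size {test_size} must be below the "
                         f"checkup sample count {n}")
    for _ in range(_MAX_REDRAWS):
        test_idx = rng.choice(n, size=test_size, replace=False)
        if len(np.unique(y[test_idx])) == 2:
            break
        logger.warning("single-class test split; redrawing")
    else:  # pragma: no cover - pathological prevalence
        raise RuntimeError("could not draw a two-class test split")
    pool = np.setdiff1d(np.arange(n), test_idx)
    subsets = {"all": pool}
    for name, parent in (("half", "all"), ("quarter", "half")):
        src = subsets[parent]
        size = len(src) // 2
        for _ in range(_MAX_REDRAWS):
            sub = rng.choice(src, size=size, replace=False)
            if len(np.unique(y[sub])) == 2:
                break
            logger.warning("single-class %s training subset; redrawing", name)
        else:  # pragma: no cover
            raise RuntimeError(f"could not draw a two-class {name} subset")
        subsets[name] = np.sort(sub)
    return np.sort(test_idx), subsets


def _model_seed(master_seed: int, rep: int, mode: str, subset: str,
                model: str) -> int:
    key = (rep, MODES.index(mode), SUBSETS.index(subset), MODELS.index(model))
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


class _DCContext:
    """Per-experiment state shared across replicates for the dc mode:
    the hospital worker's data and intermediate map never change."""

    def __init__(self, hospital: LabeledDataset, params: DCParams, bounds):
        Xh = hospital.X.to_numpy(dtype=float)
        is_qual = np.array([hospital.feature_kinds[c] != "quantitative"
                            for c in hospital.X.columns])
        Xh = _impute_apply(Xh, _impute_fit(Xh, is_qual))
        self.worker = dc.Worker(Xh, hospital.y.to_numpy(), name="hospital",
                                method=params.method, l=params.l,
                                scale=params.scale_workers)
        self.Xh_tilde = self.worker.intermediate()
        self.bounds = bounds


def _run_cell(checkup: LabeledDataset, hospital: LabeledDataset | None,
              modes: tuple[str, ...], subset: str, model: str,
              n_replicates: int, test_size: int, master_seed: int,
              lr_C: float, gbdt_params: dict | None,
              dc_params: DCParams) -> dict[str, pd.DataFrame]:
    """Run all requested modes for one (subset, model) cell, sharing the
    per-replicate splits and imputation so the comparison is paired."""
    Xc = checkup.X.to_numpy(dtype=float)
    yc = checkup.y.to_numpy()
    is_qual = np.array([checkup.feature_kinds[c] != "quantitative"
                        for c in checkup.X.columns])
    d = Xc.shape[1]
    dcx = None
    if "dc" in modes:
        if hospital is None:
            raise ValueError("dc mode needs the hospital dataset")
        if list(hospital.X.columns) != list(checkup.X.columns):
            raise ValueError("workers must share the encoded feature set")
        dcx = _DCContext(hospital, dc_params,
                         reference_bounds(checkup.X.columns))

    rows: dict[str, list[dict]] = {m: [] for m in modes}
    for rep in range(n_replicates):
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(rep,))
        rng = np.random.default_rng(ss)
        test_idx, subsets = _draw_indices(rng, yc, test_size)
        train_idx = subsets[subset]

        fill = _impute_fit(Xc[train_idx], is_qual)
        Xtr = _impute_apply(Xc[train_idx], fill)
        Xte = _impute_apply(Xc[test_idx], fill)
        ytr, yte = yc[train_idx], yc[test_idx]

        reps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if "individual" in modes:
            reps["individual"] = (Xtr, ytr, Xte)
        if "middle" in modes or "dc" in modes:
            w_chk = dc.Worker(Xtr, ytr, name="checkup",
                              method=dc_params.method, l=dc_params.l,
                              scale=dc_params.scale_workers)
        if "middle" in modes:
            reps["middle"] = (w_chk.intermediate(), ytr, w_chk.transform(Xte))
        if "dc" in modes:
            anchor_seed = int(
                np.random.SeedSequence(entropy=master_seed,
                                       spawn_key=(rep, 9001)
                                       ).generate_state(1)[0] % (2**31)
            )
            anchor = dc.generate_anchor(d, dc_params.r, dcx.bounds,
                                        strategy=dc_params.anchor_strategy,
                                        seed=anchor_seed)
            anc_ints = [w_chk.anchor_intermediate(anchor),
                        dcx.worker.anchor_intermediate(anchor)]
            g_maps = dc.compute_collaboration_maps(anc_ints, k=dc_params.k)
            coll = dc.build_collaborative_dataset(
                [w_chk.intermediate(), dcx.Xh_tilde],
                [ytr, dcx.worker.y], g_maps, ["checkup", "hospital"],
            )
            Xte_hat = w_chk.transform(Xte) @ g_maps[0].G
            reps["dc"] = (coll.X, coll.y, Xte_hat)

        for mode in modes:
            Xm, ym, Xt = reps[mode]
            seed = _model_seed(master_seed, rep, mode, subset, model)
            clf = train_model(Xm, ym, model=model, seed=seed, lr_C=lr_C,
                              gbdt_params=gbdt_params)
            metrics = evaluate(predict_scores(clf, Xt), yte)
            metrics["replicate"] = rep
            rows[mode].append(metrics)

    return {m: pd.DataFrame(rows[m]).set_index("replicate")[list(METRICS)]
            for m in modes}


def bootstrap_experiment(checkup: LabeledDataset,
                         hospital: LabeledDataset | None,
                         cfg: ExperimentConfig) -> MetricsSummary:
    """Run one (mode, subset, model) experiment; deterministic given the
    config seed."""
    out = _run_cell(checkup, hospital, (cfg.mode,), cfg.subset, cfg.model,
                    cfg.n_replicates, cfg.test_size, cfg.seed,
                    cfg.lr_C, cfg.gbdt_params, cfg.dc_params)
    return MetricsSummary(out[cfg.mode])


@dataclass
class GridResult:
    tidy: pd.DataFrame  # mode, subset, model, metric, replicate, value
    summaries: dict[tuple[str, str, str], MetricsSummary]


def run_grid(checkup: LabeledDataset, hospital: LabeledDataset | None,
             modes=MODES, subsets=SUBSETS, models=MODELS,
             cfg: ExperimentConfig | None = None) -> GridResult:
    """Full experiment grid.  Splits are derived from (seed, replicate)
    only, so every cell sees the same test data — the paired design the
    comparison rests on."""
    if cfg is None:
        cfg = ExperimentConfig()
    summaries: dict[tuple[str, str, str], MetricsSummary] = {}
    records = []
    for model in models:
        for subset in subsets:
            cell = _run_cell(checkup, hospital, tuple(modes), subset, model,
                             cfg.n_replicates, cfg.test_size, cfg.seed,
                             cfg.lr_C, cfg.gbdt_params, cfg.dc_params)
            for mode in modes:
                summaries[(mode, subset, model)] = MetricsSummary(cell[mode])
                df = cell[mode]
                for metric in METRICS:
                    for rep, value in df[metric].items():
                        records.append((mode, subset, model, metric,
                                        int(rep), float(value)))
    tidy = pd.DataFrame(records, columns=["mode", "subset", "model",
                                          "metric", "replicate", "value"])
    return GridResult(tidy=tidy, summaries=summaries)


def improvement_table(summaries: dict[tuple[str, str, str], MetricsSummary],
                      subsets=SUBSETS, models=MODELS) -> pd.DataFrame:
    """Mean-metric gains of collaborative analysis over each baseline,
    with the percentage relative to the baseline mean (positive values
    imply improvement)."""
    rows = []
    for model in models:
        for baseline in ("individual", "middle"):
            for metric in METRICS:
                for subset in subsets:
                    for key in ((baseline, subset, model), ("dc", subset, model)):
                        if key not in summaries:
                            raise ValueError(f"missing experiment cell {key}")
                    base = float(summaries[(baseline, subset, model)].mean[metric])
                    dc_mean = float(summaries[("dc", subset, model)].mean[metric])
                    delta = dc_mean - base
                    pct = 100.0 * delta / base if base != 0 else np.nan
                    rows.append({
                        "model": model, "baseline": baseline, "metric": metric,
                        "subset": subset, "baseline_mean": base,
                        "dc_mean": dc_mean, "delta": delta, "pct": pct,
                    })
    return pd.DataFrame(rows)


def config_for(mode: str, subset: str, model: str,
               base: ExperimentConfig | None = None, **kw) -> ExperimentConfig:
    base = base or ExperimentConfig()
    return replace(base, mode=mode, subset=subset, model=model, **kw)
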