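"""Cross-validated genomic prediction: training-set designs and quality metrics.

The study design this module reproduces: a joint cohort of two origins is
split 5-fold *within origin*; the GBLUP model is trained on four folds
assembled per scheme —

* ``joint``        - both origins' non-validation folds;
* ``pop1-only``    - only the first origin's non-validation folds;
* ``pop2-only``    - only the second origin's non-validation folds;
* ``balanced-subset`` - an equal random draw per origin per fold;

— and predicts the held-out fold of *both* origins.  Variance components are
re-estimated within every training set; the genomic relationship matrix is
built once on the full cohort (joint allele frequencies) and sub-blocked per
fold.  Quality is summarised per validation origin by the Pearson correlation
rho between observed and predicted scores, the mean squared error, and the
slope of the regression of observed on predicted (1 = unbiased; > 1 means
predictions under-disperse, < 1 over-disperse).  Replicates re-draw the fold
assignment; aggregates are the mean over folds within replicate, then mean
and min-max range over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import GRM
from .varcomp import GBLUP, build_design

__all__ = [
    "FoldAssignment",
    "CVConfig",
    "PredictionMetrics",
    "CVReport",
    "make_folds",
    "compute_metrics",
    "accuracy_of_selection",
    "run_cv",
    "pca_group_experiment",
]


@dataclass
class FoldAssignment:
    """Per-sample fold index (1..k), stratified within origin."""

    assignment: pd.Series  # index sample_id -> fold
    k: int
    seed: int

    def fold_ids(self, fold: int) -> np.ndarray:
        return self.assignment.index[self.assignment == fold].to_numpy(object)


@dataclass
class CVConfig:
    scheme: str = "joint"               # joint | pop1-only | pop2-only | balanced-subset
    replicates: int = 10
    k: int = 5
    seed: int = 0
    subset_per_origin: dict | None = None   # origin -> per-fold draw (balanced-subset)
    response: str = "score_mean"
    covariates: tuple = ("sex", "origin")

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scheme not in {"joint", "pop1-only", "pop2-only", "balanced-subset"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class PredictionMetrics:
    rho: float
    mse: float
    slope: float
    n_validation: int


def make_folds(sample_ids, origins, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Random k-fold assignment stratified within origin, larger folds first.

    Within each origin the samples are randomly permuted and cut into k
    near-equal blocks; remainders go to the lowest-numbered folds, so
    1,179 samples give folds of 236, 236, 236, 236 and 235.
    """
    sample_ids = np.asarray(sample_ids, object)
    origins = np.asarray(origins, object)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assign = pd.Series(index=pd.Index(sample_ids, name="sample_id"), dtype=float)
    for origin in pd.unique(origins):
        ids = sample_ids[origins == origin]
        n = len(ids)
        if n < k:
            raise ValueError(f"origin {origin!r} has {n} samples for {k} folds")
        perm = rng.permutation(n)
        base, rem = divmod(n, k)
        sizes = [base + (1 if f < rem else 0) for f in range(k)]
        start = 0
        for f, s in enumerate(sizes, start=1):
            assign.loc[ids[perm[start:start + s]]] = f
            start += s
    return FoldAssignment(assign.astype(int), k, seed)


def compute_metrics(observed, predicted) -> PredictionMetrics:
    """Pearson rho, MSE and the slope of observed regressed on predicted.

    Constant predictions leave rho and slope undefined (NaN); MSE is always
    reported.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    mse = float(np.mean((obs - pred) ** 2))
    if np.var(pred) <= 0 or np.var(obs) <= 0:
        return PredictionMetrics(float("nan"), mse, float("nan"), len(obs))
    rho = float(np.corrcoef(obs, pred)[0, 1])
    slope = float(np.cov(obs, pred, ddof=1)[0, 1] / np.var(pred, ddof=1))
    return PredictionMetrics(rho, mse, slope, len(obs))


def accuracy_of_selection(rho: float, h2: float) -> float:
    """Accuracy of selection: prediction correlation divided by sqrt(h2)."""
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    return float(rho / np.sqrt(h2))


@dataclass
class CVReport:
    """Per-(replicate, fold, validation origin) metrics with aggregates."""

    records: pd.DataFrame
    config: CVConfig
    n_failed_folds: int = 0

    def aggregate(self) -> pd.DataFrame:
        """Mean over folds within replicate, then mean and min-max over replicates."""
        per_rep = (
            self.records.groupby(["validation_origin", "replicate"])
            [["rho", "mse", "slope", "h2"]].mean().reset_index()
        )
        out = per_rep.groupby("validation_origin").agg(
            rho=("rho", "mean"), rho_min=("rho", "min"), rho_max=("rho", "max"),
            mse=("mse", "mean"), mse_min=("mse", "min"), mse_max=("mse", "max"),
            slope=("slope", "mean"), slope_min=("slope", "min"), slope_max=("slope", "max"),
            h2=("h2", "mean"),
        )
        return out.reset_index()


def _training_ids(folds: FoldAssignment, fold: int, scheme: str, origins: list,
                  origin_of: pd.Series, subset_per_origin, rng) -> np.ndarray:
    ids = folds.assignment.index.to_numpy(object)
    in_train = (folds.assignment != fold).to_numpy()
    org = origin_of.loc[ids].to_numpy(object)
    if scheme == "joint":
        keep = in_train
    elif scheme == "pop1-only":
        keep = in_train & (org == origins[0])
    elif scheme == "pop2-only":
        keep = in_train & (org == origins[1])
    elif scheme == "balanced-subset":
        chosen = []
        for o in origins:
            per_fold = (subset_per_origin or {}).get(o, None)
            for f in range(1, folds.k + 1):
                if f == fold:
                    continue
                pool = ids[(folds.assignment == f).to_numpy() & (org == o)]
                if per_fold is None or per_fold >= len(pool):
                    chosen.extend(pool)
                else:
                    chosen.extend(rng.choice(pool, size=per_fold, replace=False))
        return np.asarray(chosen, object)
    else:  # pragma: no cover
        raise ValueError(scheme)
    return ids[keep]


def _design_like(meta: pd.DataFrame, names: list) -> np.ndarray:
    """Design matrix for new samples with the training design's columns."""
    cols = []
    for name in names:
        if name == "intercept":
            cols.append(np.ones(len(meta)))
        else:
            cov, lev = name[:-1].split("[")
            cols.append((meta[cov].astype(str) == lev).to_numpy(float))
    return np.column_stack(cols)


def run_cv(
    pheno: pd.DataFrame,
    grm: GRM,
    config: CVConfig,
    return_predictions: bool = False,
) -> CVReport:
    """Replicated, origin-stratified k-fold cross-validation of GBLUP prediction.

    ``pheno`` needs columns sample_id, sex, origin and the response.  The GRM
    must cover all phenotyped samples; it is sub-blocked per training set.
    Folds are redrawn each replicate with seed ``config.seed + replicate``.
    Non-converged REML fits count as failed folds and are excluded from the
    aggregates (the count is surfaced on the report).
    """
    ph = pheno.reset_index(drop=True)
    origins = list(pd.unique(ph["origin"]))
    indexed = ph.set_index("sample_id")
    records, predictions = [], []
    n_failed = 0
    for rep in range(1, config.replicates + 1):
        rep_seed = config.seed + rep
        folds = make_folds(ph["sample_id"].to_numpy(object), ph["origin"].to_numpy(object),
                           k=config.k, seed=rep_seed)
        rng = np.random.default_rng(rep_seed + 7_000_000)
        for fold in range(1, config.k + 1):
            train_ids = _training_ids(folds, fold, config.scheme, origins,
                                      indexed["origin"], config.subset_per_origin, rng)
            val_ids = folds.fold_ids(fold)
            model = GBLUP.from_phenotypes(ph, grm, response=config.response,
                                          covariates=config.covariates,
                                          sample_ids=list(train_ids))
            fit = model.fit()
            if not fit.converged:
                n_failed += 1
                continue
            _, names = build_design(indexed.loc[list(train_ids)], config.covariates)
            W_val = _design_like(indexed.loc[list(val_ids)], names)
            pred = fit.predict(grm, val_ids, W_val=W_val)
            obs = indexed.loc[list(val_ids), config.response].to_numpy(float)
            vorigin = indexed.loc[list(val_ids), "origin"].to_numpy(object)
            h2 = fit.heritability().h2
            for org in origins:
                mask = vorigin == org
                if mask.sum() < 3:
                    continue
                met = compute_metrics(obs[mask], pred[mask])
                records.append(
                    {
                        "replicate": rep, "fold": fold, "scheme": config.scheme,
                        "validation_origin": org, "rho": met.rho, "mse": met.mse,
                        "slope": met.slope, "h2": h2, "n_validation": met.n_validation,
                        "n_train": len(train_ids),
                    }
                )
            if return_predictions:
                predictions.append(
                    pd.DataFrame({"replicate": rep, "fold": fold,
                                  "sample_id": val_ids, "predicted": pred, "observed": obs})
                )
    report = CVReport(pd.DataFrame(records), config, n_failed)
    if return_predictions:
        report.predictions = pd.concat(predictions, ignore_index=True)
    return report


def pca_group_experiment(
    pheno: pd.DataFrame,
    grm: GRM,
    partition: dict,
    training_groups=None,
    response: str = "score_mean",
    covariates: tuple = ("sex", "origin"),
    min_train: int = 30,
) -> pd.DataFrame:
    """Train on one group (or a union of groups), validate on every excluded group.

    ``partition`` maps group label -> sample ids; ``training_groups`` lists the
    training sets to evaluate (labels or tuples of labels; default every single
    group).  No cross-validation: one fit per training set.  Training groups
    smaller than ``min_train`` are fitted anyway but flagged — small-sample
    REML heritabilities tend to the boundary with flat likelihood profiles.
    """
    labels = list(partition)
    training_groups = training_groups or labels
    indexed = pheno.set_index("sample_id")
    rows = []
    for tg in training_groups:
        tg_labels = tuple(tg) if isinstance(tg, (tuple, list)) else (tg,)
        train_ids = np.concatenate([np.asarray(partition[l], object) for l in tg_labels])
        flagged = len(train_ids) < min_train
        model = GBLUP.from_phenotypes(pheno, grm, response=response,
                                      covariates=covariates, sample_ids=list(train_ids))
        fit = model.fit()
        _, names = build_design(indexed.loc[list(train_ids)], covariates)
        for vg in labels:
            if vg in tg_labels:
                continue
            val_ids = np.asarray(partition[vg], object)
            if set(val_ids) & set(train_ids):
                raise ValueError(f"training and validation groups overlap at {vg!r}")
            W_val = _design_like(indexed.loc[list(val_ids)], names)
            pred = fit.predict(grm, val_ids, W_val=W_val)
            obs = indexed.loc[list(val_ids), response].to_numpy(float)
            met = compute_metrics(obs, pred)
            rows.append(
                {
                    "training": "+".join(map(str, tg_labels)), "validation": vg,
                    "rho": met.rho, "mse": met.mse, "slope": met.slope,
                    "h2": fit.heritability().h2, "n_train": len(train_ids),
                    "n_validation": len(val_ids),
                    "identifiability_flag": bool(flagged or fit.boundary),
                }
            )
    return pd.DataFrame(rows)
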