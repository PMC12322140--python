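"""Outcome prediction: label construction, SMOTE rebalancing, Random-Forest
classification and the three-split ROC/AUC evaluation protocol.

Label rules (3 years = 1095 days at day resolution):

* recurrence task — positive: recurrence within 1095 days; negative: no
  recurrence, alive beyond (or death after) 1095 days with at least 1095
  days of follow-up; anything else is excluded with a reason (insufficient
  follow-up, early non-recurrence death, recurrence after 3 years).
* survival task — positive: deceased with tumor-specific or unknown cause;
  negative: alive at end of follow-up; non-tumor-specific deaths excluded.

All preprocessing (imputation statistics, z-scoring, one-hot levels, the
ICD bag-of-words vocabulary) is fitted on the training patients only and
applied unchanged to the test patients; SMOTE oversamples the training
minority class to parity before the forest is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neighbors import NearestNeighbors

from ._utils import child_rng, child_seed
from .gasplit import SplitResult
from .records import Cohort
from .vectorize import (
    DEFAULT_SCHEMA,
    EncodingSchema,
    FeaturePreprocessor,
    encode_cohort,
)

__all__ = [
    "OutcomeLabels",
    "ModelConfig",
    "EvalReport",
    "build_recurrence_labels",
    "build_survival_labels",
    "smote_resample",
    "fit_predict",
    "site_holdout_split",
    "evaluate_protocol",
]

THREE_YEARS = 1095  # days; no leap handling at day resolution


@dataclass
class OutcomeLabels:
    """Per-patient task labels: positive / negative / excluded (with reason)."""

    task: str
    states: dict[str, str]
    reasons: dict[str, str]

    def label_array(self, patient_ids: list[str]) -> np.ndarray:
        """1/0/NaN array aligned to patient_ids (NaN = excluded)."""
        out = np.full(len(patient_ids), np.nan)
        for i, pid in enumerate(patient_ids):
            s = self.states[pid]
            if s == "positive":
                out[i] = 1.0
            elif s == "negative":
                out[i] = 0.0
        return out

    def included_ids(self) -> list[str]:
        return [p for p, s in self.states.items() if s != "excluded"]


def build_recurrence_labels(cohort: Cohort) -> OutcomeLabels:
    """3-year recurrence classes; patients fitting neither class are excluded."""
    states: dict[str, str] = {}
    reasons: dict[str, str] = {}
    for rec in cohort:
        pid = rec.patient_id
        if rec.recurrence_days is not None:
            if rec.recurrence_days <= THREE_YEARS:
                states[pid] = "positive"
            else:
                states[pid] = "excluded"
                reasons[pid] = "recurrence after 3 years"
            continue
        died_early = rec.death_days is not None and rec.death_days <= THREE_YEARS
        if died_early:
            states[pid] = "excluded"
            reasons[pid] = "death within 3 years without recurrence"
        elif rec.followup_days < THREE_YEARS:
            states[pid] = "excluded"
            reasons[pid] = "insufficient follow-up"
        else:
            states[pid] = "negative"
    return OutcomeLabels("recurrence", states, reasons)


def build_survival_labels(cohort: Cohort) -> OutcomeLabels:
    """Survival-status classes; non-tumor-specific deaths are excluded,
    deaths of unknown cause are kept as positives."""
    states: dict[str, str] = {}
    reasons: dict[str, str] = {}
    for rec in cohort:
        pid = rec.patient_id
        if rec.death_days is None:
            states[pid] = "negative"
        elif rec.death_tumor_specific is False:
            states[pid] = "excluded"
            reasons[pid] = "non-tumor-specific death"
        else:
            states[pid] = "positive"
    return OutcomeLabels("survival", states, reasons)


@dataclass
class ModelConfig:
    """Random-Forest and rebalancing hyperparameters."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    smote_k: int = 5
    modalities: tuple[str, ...] | None = None  # None -> all four


def smote_resample(X: np.ndarray, y: np.ndarray, seed: int, k: int = 5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling by k-NN interpolation.

    New minority samples are drawn on the segment between a random minority
    sample and one of its k nearest minority neighbors, until the minority
    count equals the majority count.  If fewer than k+1 minority samples
    exist, k is reduced automatically (warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE requires exactly two classes in y")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X.copy(), y.copy()
    Xmin = X[y == minority]
    if Xmin.shape[0] == 1:
        synth = np.repeat(Xmin, n_needed, axis=0)
        return np.vstack([X, synth]), np.concatenate([y, [minority] * n_needed])
    k_eff = min(k, Xmin.shape[0] - 1)
    if k_eff < k:
        warnings.warn(f"SMOTE neighbors reduced from {k} to {k_eff} "
                      f"(minority size {Xmin.shape[0]})")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    _, nbrs = nn.kneighbors(Xmin)
    rng = child_rng(seed, "smote")
    base = rng.integers(Xmin.shape[0], size=n_needed)
    pick = rng.integers(1, k_eff + 1, size=n_needed)  # skip self at column 0
    lam = rng.random(n_needed)[:, None]
    partners = Xmin[nbrs[base, pick]]
    synth = Xmin[base] + lam * (partners - Xmin[base])
    return np.vstack([X, synth]), np.concatenate([y, [minority] * n_needed])


def fit_predict(train: Cohort, y_train: np.ndarray, test: Cohort,
                config: ModelConfig | None = None, seed: int = 0,
                schema: EncodingSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Train on ``train`` (labels aligned to its sorted patient order) and
    return positive-class scores for ``test`` patients.

    The ICD vocabulary, imputation statistics, one-hot levels and z-scoring
    are fitted on the training cohort only.
    """
    config = config or ModelConfig()
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    raw_tr = encode_cohort(train, schema)
    raw_te = encode_cohort(test, schema, icd_vocab=raw_tr.icd_vocab)
    if config.modalities is not None:
        raw_tr = raw_tr.modality_subset(config.modalities)
        raw_te = raw_te.modality_subset(config.modalities)
    prep = FeaturePreprocessor().fit(raw_tr)
    Xtr = prep.transform(raw_tr).X
    Xte = prep.transform(raw_te).X
    Xb, yb = smote_resample(Xtr, y_train, seed=child_seed(seed, "smote"),
                            k=config.smote_k)
    clf = RandomForestClassifier(
        n_estimators=config.n_estimators, max_features=config.max_features,
        max_depth=config.max_depth, random_state=child_seed(seed, "rf"),
        n_jobs=1)
    clf.fit(Xb, yb)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(Xte)[:, pos_col]


def site_holdout_split(cohort: Cohort, site: str) -> SplitResult:
    """Deterministic split holding out every patient of one primary site."""
    test_ids = [r.patient_id for r in cohort if r.primary_site == site]
    train_ids = [r.patient_id for r in cohort if r.primary_site != site]
    if not test_ids:
        raise ValueError(f"no patients with primary_site {site!r}")
    if not train_ids:
        raise ValueError(f"holding out {site!r} would empty the training set")
    return SplitResult(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                       best_fitness=float("nan"), fitness_trace=[],
                       mode=f"site_holdout:{site}")


@dataclass
class EvalReport:
    """Per-(split, task) evaluation: repeated AUCs and the mean ROC curve."""

    split_name: str
    task: str
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    aucs: list[float]
    seeds: list[int]
    n_train: int = 0
    n_test: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs))


_TASK_BUILDERS = {"recurrence": build_recurrence_labels,
                  "survival": build_survival_labels}


def evaluate_protocol(cohort: Cohort, splits: dict[str, SplitResult],
                      tasks: tuple[str, ...] = ("recurrence", "survival"),
                      repeats: int = 5, seed: int = 0,
                      config: ModelConfig | None = None,
                      schema: EncodingSchema = DEFAULT_SCHEMA
                      ) -> dict[tuple[str, str], EvalReport]:
    """Repeat fit/predict per split and task; average ROC on a fixed FPR grid.

    Each repeat uses a distinct derived seed; ROC curves are averaged by
    threshold-wise interpolation of the TPR on a 101-point FPR grid.
    """
    config = config or ModelConfig()
    all_ids = set(cohort.patient_ids)
    grid = np.linspace(0.0, 1.0, 101)
    out: dict[tuple[str, str], EvalReport] = {}
    for split_name, split in splits.items():
        ids = set(split.train_ids) | set(split.test_ids)
        unknown = ids - all_ids
        if unknown:
            raise ValueError(f"split {split_name!r} references unknown ids: "
                             f"{sorted(unknown)[:5]}")
        for task in tasks:
            labels = _TASK_BUILDERS[task](cohort)
            train_ids = [p for p in split.train_ids if labels.states[p] != "excluded"]
            test_ids = [p for p in split.test_ids if labels.states[p] != "excluded"]
            train = cohort.subset(train_ids)
            test = cohort.subset(test_ids)
            y_tr = labels.label_array(train.patient_ids).astype(int)
            y_te = labels.label_array(test.patient_ids).astype(int)
            aucs, tprs, seeds = [], [], []
            for r in range(repeats):
                s = child_seed(seed, split_name, task, r)
                seeds.append(s)
                scores = fit_predict(train, y_tr, test, config=config, seed=s,
                                     schema=schema)
                aucs.append(float(roc_auc_score(y_te, scores)))
                fpr, tpr, _ = roc_curve(y_te, scores)
                tprs.append(np.interp(grid, fpr, tpr))
            tprs = np.vstack(tprs)
            out[(split_name, task)] = EvalReport(
                split_name=split_name, task=task, fpr_grid=grid,
                mean_tpr=tprs.mean(axis=0), sd_tpr=tprs.std(axis=0),
                aucs=aucs, seeds=seeds, n_train=len(train_ids),
                n_test=len(test_ids))
    return out
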