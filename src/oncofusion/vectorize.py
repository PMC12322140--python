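"""Multimodal patient vectors: per-modality encoding, imputation,
one-hot expansion, z-scoring, concatenation and 2-D projection.

Encoding rules
--------------
* binary pathology flags -> {0, 1, missing}
* pT / pN stage -> consecutive ordinal integers via the decision tables
  below (configurable through :class:`EncodingSchema`)
* categorical features (sex, smoking status, primary site) -> integer
  labels, expanded to full one-hot indicators (no reference-level drop)
  at assembly time
* blood panel -> raw values of the hematology group only
* ICD-10 codes -> bag-of-words presence counts over the first four
  characters of each code ("C32.0" -> "C32."); codes carried by fewer
  than ``min_support`` patients are discarded
* CD3/CD8 densities at tumor center and invasion front -> 4 raw numerics

Missing values are imputed with the per-feature mode (binary/categorical)
or mean (numeric/ordinal); ordinal and numeric columns are z-scored.
A patient's *completeness* flag is decided before any imputation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field as dc_field

import numpy as np

from .records import (
    Cohort,
    PatientRecord,
    CohortValidationError,
    SEX_LEVELS,
    SMOKING_LEVELS,
    SITE_LEVELS,
    GRADING_LEVELS,
    FLAG_FIELDS,
    TMA_KEYS,
)
from .simulate import HEMATOLOGY_PANEL
from ._utils import child_seed

__all__ = [
    "EncodingSchema",
    "DEFAULT_SCHEMA",
    "FeatureBlock",
    "RawFeatures",
    "VectorSet",
    "FeaturePreprocessor",
    "encode_structured",
    "encode_blood",
    "encode_icd",
    "encode_tma",
    "encode_cohort",
    "assemble_vectors",
    "project_2d",
    "MODALITY_ORDER",
]

MODALITY_ORDER = ("clinical_pathological", "blood", "icd", "tma")

#: pT decision table: monotone in severity.
DEFAULT_PT_TABLE = {"pTis": 0, "pT1": 1, "pT2": 2, "pT3": 3, "pT4": 4,
                    "pT4a": 5, "pT4b": 6}
#: pN decision table: a/b/c substages collapse to their parent level.
DEFAULT_PN_TABLE = {"pN0": 0, "pN1": 1, "pN2": 2, "pN2a": 2, "pN2b": 2,
                    "pN2c": 2, "pN3": 3}
DEFAULT_GRADING_TABLE = {g: i + 1 for i, g in enumerate(GRADING_LEVELS)}


@dataclass
class EncodingSchema:
    """Configurable encoding tables and panel membership."""

    pt_table: dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_PT_TABLE))
    pn_table: dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_PN_TABLE))
    grading_table: dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_GRADING_TABLE))
    hematology_panel: tuple[str, ...] = HEMATOLOGY_PANEL
    icd_min_support: int = 3
    icd_prefix_len: int = 4


DEFAULT_SCHEMA = EncodingSchema()


@dataclass
class FeatureBlock:
    """One modality's features for one patient (NaN encodes missing)."""

    modality: str
    names: list[str]
    values: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.names) == len(self.values) == len(self.kinds)):
            raise ValueError("names, values and kinds must be aligned")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique within a block")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def encode_structured(record: PatientRecord,
                      schema: EncodingSchema = DEFAULT_SCHEMA) -> FeatureBlock:
    """Clinical/pathological block: binary flags, ordinal stages, category labels."""
    names: list[str] = []
    vals: list[float] = []
    kinds: list[str] = []

    def put(name: str, value: float | None, kind: str) -> None:
        names.append(name)
        vals.append(np.nan if value is None else float(value))
        kinds.append(kind)

    put("sex", SEX_LEVELS.index(record.sex) ^ 1, "categorical_label")  # male=1, female=0
    put("age_at_diagnosis", record.age_at_diagnosis, "numeric")
    smoking = None if record.smoking_status == "unknown" \
        else SMOKING_LEVELS.index(record.smoking_status)
    put("smoking_status", smoking, "categorical_label")
    put("primary_site", SITE_LEVELS.index(record.primary_site), "categorical_label")
    for fieldname, table in (("pt_stage", schema.pt_table),
                             ("pn_stage", schema.pn_table),
                             ("grading", schema.grading_table)):
        level = getattr(record, fieldname)
        if level is None:
            put(fieldname, None, "ordinal")
        else:
            if level not in table:
                raise CohortValidationError(
                    f"patient {record.patient_id!r}: {fieldname} level {level!r} "
                    f"absent from the decision table")
            put(fieldname, table[level], "ordinal")
    for name in FLAG_FIELDS:
        flag = getattr(record, name)
        put(name, None if flag is None else int(flag), "binary")
    return FeatureBlock("clinical_pathological", names, np.array(vals), kinds)


def encode_blood(record: PatientRecord,
                 panel: tuple[str, ...] = HEMATOLOGY_PANEL) -> FeatureBlock:
    """Raw hematology values in panel order; other blood groups are excluded."""
    vals = []
    for pname in panel:
        entry = record.blood.get(pname)
        if entry is None or entry.get("value") is None:
            vals.append(np.nan)
        else:
            vals.append(float(entry["value"]))
    return FeatureBlock("blood", [f"blood_{p}" for p in panel],
                        np.array(vals), ["numeric"] * len(panel))


def encode_icd(cohort: Cohort, min_support: int = 3, prefix_len: int = 4
               ) -> tuple[list[str], list[FeatureBlock]]:
    """Bag-of-words over truncated ICD codes with a minimum-support filter.

    Each code is truncated to its first ``prefix_len`` characters (the
    literal string including the dot).  The vocabulary keeps truncated codes
    carried by at least ``min_support`` patients, sorted lexicographically;
    per-patient vectors are presence counts over that vocabulary.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    support: Counter[str] = Counter()
    truncated: list[list[str]] = []
    for rec in cohort:
        codes = [c[:prefix_len] for c in rec.icd_codes]
        truncated.append(codes)
        support.update(set(codes))
    vocab = sorted(c for c, k in support.items() if k >= min_support)
    index = {c: j for j, c in enumerate(vocab)}
    blocks = []
    for codes in truncated:
        v = np.zeros(len(vocab))
        for c in codes:
            if c in index:
                v[index[c]] += 1.0
        blocks.append(FeatureBlock("icd", [f"icd_{c}" for c in vocab], v,
                                   ["bow"] * len(vocab)))
    return vocab, blocks


def encode_tma(record: PatientRecord) -> FeatureBlock:
    """CD3/CD8 densities (cells/mm^2) at tumor center and invasion front."""
    vals = []
    for key in TMA_KEYS:
        dens = record.tma_density.get(key)
        if dens is None:
            vals.append(np.nan)
        else:
            if dens < 0:
                raise CohortValidationError(
                    f"patient {record.patient_id!r}: tma_density[{key}] is negative")
            vals.append(float(dens))
    return FeatureBlock("tma", [f"tma_{k}" for k in TMA_KEYS],
                        np.array(vals), ["numeric"] * 4)


@dataclass
class RawFeatures:
    """Pre-expansion, pre-imputation concatenated feature matrix (NaN = missing)."""

    patient_ids: list[str]
    values: np.ndarray           # (n_patients, n_features)
    names: list[str]
    modalities: list[str]
    kinds: list[str]
    icd_vocab: list[str]
    complete: np.ndarray         # per-patient: every feature observed

    @property
    def pre_expansion_dim(self) -> int:
        return self.values.shape[1]

    def modality_subset(self, modalities: set[str] | list[str]) -> "RawFeatures":
        keep = [j for j, m in enumerate(self.modalities) if m in set(modalities)]
        vals = self.values[:, keep]
        return RawFeatures(
            patient_ids=list(self.patient_ids),
            values=vals,
            names=[self.names[j] for j in keep],
            modalities=[self.modalities[j] for j in keep],
            kinds=[self.kinds[j] for j in keep],
            icd_vocab=list(self.icd_vocab) if "icd" in set(modalities) else [],
            complete=~np.isnan(vals).any(axis=1),
        )

    def subset_rows(self, idx: np.ndarray | list[int]) -> "RawFeatures":
        idx = np.asarray(idx)
        return RawFeatures(
            patient_ids=[self.patient_ids[i] for i in idx],
            values=self.values[idx],
            names=list(self.names),
            modalities=list(self.modalities),
            kinds=list(self.kinds),
            icd_vocab=list(self.icd_vocab),
            complete=self.complete[idx],
        )


def encode_cohort(cohort: Cohort, schema: EncodingSchema = DEFAULT_SCHEMA,
                  icd_vocab: list[str] | None = None) -> RawFeatures:
    """Encode every record and concatenate blocks in fixed modality order.

    If ``icd_vocab`` is given (e.g. fitted on a training set), the
    bag-of-words block is built over it instead of refitting the
    support filter on this cohort.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if icd_vocab is None:
        vocab, icd_blocks = encode_icd(cohort, schema.icd_min_support,
                                       schema.icd_prefix_len)
    else:
        vocab = list(icd_vocab)
        index = {c: j for j, c in enumerate(vocab)}
        icd_blocks = []
        for rec in cohort:
            v = np.zeros(len(vocab))
            for c in rec.icd_codes:
                c = c[:schema.icd_prefix_len]
                if c in index:
                    v[index[c]] += 1.0
            icd_blocks.append(FeatureBlock("icd", [f"icd_{c}" for c in vocab],
                                           v, ["bow"] * len(vocab)))

    rows, names, modalities, kinds = [], None, None, None
    for rec, icd_block in zip(cohort, icd_blocks):
        blocks = [encode_structured(rec, schema),
                  encode_blood(rec, schema.hematology_panel),
                  icd_block,
                  encode_tma(rec)]
        row = np.concatenate([b.values for b in blocks]) if blocks else np.empty(0)
        if names is None:
            names = [n for b in blocks for n in b.names]
            modalities = [b.modality for b in blocks for _ in b.names]
            kinds = [k for b in blocks for k in b.kinds]
        rows.append(row)
    values = np.vstack(rows)
    # Completeness (pre-imputation): every feature observed, except grading,
    # which is structurally absent for HPV-associated (ungraded) carcinomas
    # and therefore kept out of the completeness rule.
    miss = np.isnan(values)
    if "grading" in names:
        miss = miss.copy()
        miss[:, names.index("grading")] = False
    return RawFeatures(
        patient_ids=cohort.patient_ids,
        values=values,
        names=names,
        modalities=modalities,
        kinds=kinds,
        icd_vocab=vocab,
        complete=~miss.any(axis=1),
    )


class FeaturePreprocessor:
    """Impute, one-hot expand and z-score a :class:`RawFeatures` matrix.

    Imputation is per-feature mode (binary/categorical) or mean
    (numeric/ordinal); categorical labels expand to one indicator column per
    level observed in the fitting data; ordinal and numeric columns are
    z-scored with the fitting cohort's mean and standard deviation.  A
    zero-variance column is centered and left at 0.  Fit on the whole cohort
    for visualization/splitting, or on the training rows only for
    leakage-safe model evaluation.
    """

    def fit(self, raw: RawFeatures) -> "FeaturePreprocessor":
        X = raw.values
        self.names_, self.kinds_, self.modalities_ = \
            list(raw.names), list(raw.kinds), list(raw.modalities)
        self.impute_: list[float] = []
        self.levels_: dict[int, list[float]] = {}
        for j, kind in enumerate(raw.kinds):
            col = X[:, j]
            obs = col[~np.isnan(col)]
            if kind in ("binary", "categorical_label"):
                if obs.size == 0:
                    fill = 0.0
                else:
                    vals, counts = np.unique(obs, return_counts=True)
                    fill = float(vals[np.argmax(counts)])  # ties: lowest label
                self.impute_.append(fill)
                if kind == "categorical_label":
                    self.levels_[j] = sorted(np.unique(obs).tolist()) if obs.size else [fill]
            else:
                self.impute_.append(float(obs.mean()) if obs.size else 0.0)
        # z-score stats on imputed ordinal/numeric columns
        imputed = self._impute(X)
        self.center_ = np.zeros(X.shape[1])
        self.scale_ = np.ones(X.shape[1])
        for j, kind in enumerate(raw.kinds):
            if kind in ("ordinal", "numeric"):
                col = imputed[:, j]
                self.center_[j] = col.mean()
                sd = col.std()
                self.scale_[j] = sd if sd > 0 else 1.0  # zero-variance: centered, left at 0
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        out = X.copy()
        for j, fill in enumerate(self.impute_):
            col = out[:, j]
            col[np.isnan(col)] = fill
        return out

    def transform(self, raw: RawFeatures) -> "VectorSet":
        if list(raw.names) != self.names_:
            raise ValueError("feature layout does not match the fitted preprocessor")
        X = self._impute(raw.values)
        cols, names, modalities, kinds = [], [], [], []
        for j, kind in enumerate(self.kinds_):
            if kind == "categorical_label":
                for level in self.levels_[j]:
                    cols.append((X[:, j] == level).astype(float))
                    names.append(f"{self.names_[j]}={level:g}")
                    modalities.append(self.modalities_[j])
                    kinds.append("onehot")
            elif kind in ("ordinal", "numeric"):
                cols.append((X[:, j] - self.center_[j]) / self.scale_[j])
                names.append(self.names_[j])
                modalities.append(self.modalities_[j])
                kinds.append(kind)
            else:  # binary, bow: pass through
                cols.append(X[:, j])
                names.append(self.names_[j])
                modalities.append(self.modalities_[j])
                kinds.append(kind)
        M = np.column_stack(cols) if cols else np.empty((raw.values.shape[0], 0))
        return VectorSet(
            patient_ids=list(raw.patient_ids),
            X=M,
            col_names=names,
            col_modalities=modalities,
            col_kinds=kinds,
            complete=raw.complete.copy(),
            pre_expansion_dim=raw.pre_expansion_dim,
        )


@dataclass
class VectorSet:
    """Cohort's concatenated multimodal patient vectors with column provenance."""

    patient_ids: list[str]
    X: np.ndarray
    col_names: list[str]
    col_modalities: list[str]
    col_kinds: list[str]
    complete: np.ndarray
    pre_expansion_dim: int

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.patient_ids):
            raise ValueError("one row per patient required")
        if self.X.shape[1] != len(self.col_names):
            raise ValueError("column metadata misaligned")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    def row_index(self, patient_id: str) -> int:
        return self.patient_ids.index(patient_id)


def assemble_vectors(cohort: Cohort,
                     schema: EncodingSchema = DEFAULT_SCHEMA) -> VectorSet:
    """Encode, impute, expand and normalize the whole cohort (fit on all rows)."""
    raw = encode_cohort(cohort, schema)
    return FeaturePreprocessor().fit(raw).transform(raw)


def project_2d(vectors: VectorSet, seed: int) -> np.ndarray:
    """UMAP projection to 2-D with each axis min-max rescaled to [0, 1]."""
    n = vectors.n_patients
    if n < 3:
        raise ValueError("2-D projection requires at least 3 patients")
    import umap  # deferred: heavy import

    nn = min(15, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=nn,
                            random_state=child_seed(seed, "umap"), n_jobs=1)
        coords = reducer.fit_transform(vectors.X)
    coords = np.asarray(coords, dtype=float)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (coords - lo) / span
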