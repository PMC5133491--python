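"""Reading, validation, alignment and autoscaling of multi-platform feature tables.

A study consists of one numeric sample x feature table per analytical
platform (acyl-carnitines, GC-MS fatty acids, DI-MS lipids, ...), a clinical
table of assay phenotypes (AST, albumin, glucose, relative liver weight, ...)
and a class label per sample (control, dose groups, recovery groups).  All
downstream stages assume the members of a study share one ordered sample
list; :func:`align_collection` establishes that invariant.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "ClinicalTable",
    "ClassLabels",
    "DatasetCollection",
    "read_feature_table",
    "read_clinical_table",
    "read_class_labels",
    "read_manifest",
    "autoscale",
    "align_collection",
]


class ValidationError(ValueError):
    """A table violates a structural invariant (duplicates, non-finite cells, ...)."""


def _check_unique(ids, kind: str, where: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} IDs in {where}: {dups}")


def _check_finite(df: pd.DataFrame, where: str) -> None:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValidationError(f"non-numeric columns in {where}: {list(bad)}")
    if not np.isfinite(values).all():
        rows, cols = np.nonzero(~np.isfinite(values))
        cells = [(df.index[i], df.columns[j]) for i, j in zip(rows[:5], cols[:5])]
        raise ValidationError(f"non-finite cells in {where} at (sample, feature) {cells}")


@dataclass
class FeatureTable:
    """One omics platform: samples x features numeric matrix with a dataset name."""

    dataset_name: str
    data: pd.DataFrame  # index = sample IDs, columns = feature IDs

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError(f"empty table for dataset {self.dataset_name!r}")
        _check_unique(self.data.index, "sample", self.dataset_name)
        _check_unique(self.data.columns, "feature", self.dataset_name)
        _check_finite(self.data, self.dataset_name)
        self.data.index = self.data.index.astype(str).rename(None)
        self.data.columns = self.data.columns.astype(str).rename(None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.dataset_name, self.data.loc[:, list(feature_ids)].copy())

    def prefixed(self) -> "FeatureTable":
        """Copy with feature IDs prefixed ``<dataset_name>:`` (collision-safe fusion)."""
        out = self.data.copy()
        out.columns = [f"{self.dataset_name}:{c}" for c in out.columns]
        return FeatureTable(self.dataset_name, out)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index_label="sample_id")


@dataclass
class ClinicalTable:
    """Clinical-chemistry phenotypes (assay units), samples x phenotypes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 3:
            raise ValidationError("clinical table needs >=3 samples per phenotype")
        _check_unique(self.data.index, "sample", "clinical table")
        _check_unique(self.data.columns, "phenotype", "clinical table")
        _check_finite(self.data, "clinical table")
        self.data.index = self.data.index.astype(str).rename(None)
        self.data.columns = self.data.columns.astype(str).rename(None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotype_ids(self) -> list[str]:
        return list(self.data.columns)

    def phenotype(self, phenotype_id: str) -> np.ndarray:
        return self.data[phenotype_id].to_numpy(dtype=float)


@dataclass
class ClassLabels:
    """Per-sample class labels; level order is meaningful (vote tie-breaks)."""

    labels: pd.Series  # index = sample IDs, categorical values

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample", "class labels")
        if not isinstance(self.labels.dtype, pd.CategoricalDtype):
            # preserve order of first appearance rather than sorting
            levels = pd.unique(self.labels)
            self.labels = self.labels.astype(pd.CategoricalDtype(levels))
        self.labels.index = self.labels.index.astype(str)
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValidationError("class labels must have >=2 levels")
        thin = counts[counts < 2]
        if len(thin):
            raise ValidationError(f"classes with <2 samples: {list(thin.index)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def levels(self) -> list[str]:
        return list(self.labels.cat.categories)

    def codes(self) -> np.ndarray:
        """Integer codes in level order (the encoding passed to the forests)."""
        return self.labels.cat.codes.to_numpy()


@dataclass
class DatasetCollection:
    """Aligned study: omics tables + labels (+ optional clinical), one sample order."""

    tables: list[FeatureTable]
    labels: ClassLabels
    clinical: ClinicalTable | None = None
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    @property
    def dataset_names(self) -> list[str]:
        return [t.dataset_name for t in self.tables]

    def table(self, dataset_name: str) -> FeatureTable:
        for t in self.tables:
            if t.dataset_name == dataset_name:
                return t
        raise KeyError(dataset_name)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def _read_matrix(path, sep: str | None, where: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    except FileNotFoundError:
        raise
    except Exception as exc:  # delimiter/structure problems
        raise ValidationError(f"cannot parse {where} from {path}: {exc}") from exc
    # locate the first offending cell by name rather than failing opaquely later
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = coerced.isna() & ~raw_na
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValidationError(
                f"non-numeric cell in {where} at sample {row!r}, feature {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    return df


def read_feature_table(path, dataset_name: str, sep: str | None = None) -> FeatureTable:
    """Read a delimited sample x feature table (first row features, first column samples)."""
    return FeatureTable(dataset_name, _read_matrix(path, sep, f"dataset {dataset_name!r}"))


def read_clinical_table(path, sep: str | None = None) -> ClinicalTable:
    return ClinicalTable(_read_matrix(path, sep, "clinical table"))


def read_class_labels(path, sep: str | None = None, column: str | None = None) -> ClassLabels:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"label file {path} has no label column")
    col = column if column is not None else df.columns[0]
    return ClassLabels(df[col].astype(str))


def autoscale(table: FeatureTable, drop_constant: bool = False) -> FeatureTable:
    """Standardise each feature to mean 0, sample standard deviation 1 (n-1 denominator).

    Autoscaling gives every metabolite equal weight regardless of its raw
    abundance scale.  Zero-variance features are an error by default, since
    selection must never run on constants; ``drop_constant=True`` downgrades
    that to drop-with-warning.
    """
    values = table.data
    sd = values.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        if not drop_constant:
            raise ValidationError(
                f"zero-variance features in {table.dataset_name!r}: {constant}"
            )
        warnings.warn(
            f"dropping {len(constant)} zero-variance features from "
            f"{table.dataset_name!r}: {constant}",
            stacklevel=2,
        )
        values = values.drop(columns=constant)
        sd = sd.drop(index=constant)
    scaled = (values - values.mean(axis=0)) / sd
    return FeatureTable(table.dataset_name, scaled)


def align_collection(
    tables: list[FeatureTable],
    labels: ClassLabels,
    clinical: ClinicalTable | None = None,
) -> DatasetCollection:
    """Restrict every member to the shared samples, ordered lexicographically.

    Samples missing from any member are dropped (and reported); an empty
    intersection is an error.
    """
    if not tables:
        raise ValidationError("need at least one feature table")
    shared = set(labels.sample_ids)
    for t in tables:
        shared &= set(t.sample_ids)
    if clinical is not None:
        shared &= set(clinical.sample_ids)
    if not shared:
        raise ValidationError("no samples shared across tables/labels/clinical")
    order = sorted(shared)

    dropped: dict[str, list[str]] = {}

    def _note(name: str, ids) -> None:
        extra = sorted(set(ids) - shared)
        if extra:
            dropped[name] = extra
            logger.info("alignment dropped %d samples from %s: %s", len(extra), name, extra)

    _note("labels", labels.sample_ids)
    aligned_tables = []
    for t in tables:
        _note(t.dataset_name, t.sample_ids)
        aligned_tables.append(FeatureTable(t.dataset_name, t.data.loc[order].copy()))
    aligned_clinical = None
    if clinical is not None:
        _note("clinical", clinical.sample_ids)
        aligned_clinical = ClinicalTable(clinical.data.loc[order].copy())
    aligned_labels = ClassLabels(labels.labels.loc[order])
    return DatasetCollection(aligned_tables, aligned_labels, aligned_clinical, dropped)


def read_manifest(path) -> DatasetCollection:
    """Load a study from a JSON manifest mapping names to ``{path, role}`` entries.

    Roles: ``omics`` (default), ``clinical``, ``labels``.  Paths are resolved
    relative to the manifest file.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    tables: list[FeatureTable] = []
    clinical = None
    labels = None
    for name, entry in spec.items():
        if isinstance(entry, str):
            entry = {"path": entry}
        fpath = path.parent / entry["path"]
        if not fpath.exists():
            raise ValidationError(f"manifest entry {name!r}: missing file {fpath}")
        role = entry.get("role", "omics")
        if role == "omics":
            tables.append(read_feature_table(fpath, name))
        elif role == "clinical":
            clinical = read_clinical_table(fpath)
        elif role == "labels":
            labels = read_class_labels(fpath, column=entry.get("column"))
        else:
            raise ValidationError(f"manifest entry {name!r}: unknown role {role!r}")
    if labels is None:
        raise ValidationError("manifest defines no labels table")
    return align_collection(tables, labels, clinical)
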