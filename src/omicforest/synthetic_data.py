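"""Synthetic multi-platform dose-response studies with known ground truth.

Emulates a 13-week rodent dose-range study: eight groups — control, four
dose levels (0, 30, 100, 300, 1000 mg/kg/day; 12 animals each) and three
treatment-free recovery groups (control, intermediate-2 and high dose; 6
animals each) — for 78 animals in total.  Each omics platform is a feature
table in which a known subset of features responds monotonically to dose
(mean shift δ·log1p(dose)/log1p(max dose), attenuated by γ in recovery
groups, on unit-variance noise), optional feature blocks are drawn from a
stated precision matrix (a Gaussian graphical model with known conditional
independences), and clinical phenotypes are linear combinations of chosen
driver features plus Gaussian noise.

The dose enters through log1p so the 30→1000 range does not linearly dwarf
the low doses; recovery attenuation γ=0.3 keeps recovery classes confusable
with control, the hardest aspect of the real classification task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_datasets import (
    ClassLabels,
    ClinicalTable,
    DatasetCollection,
    FeatureTable,
    align_collection,
)

__all__ = [
    "Group",
    "StudyDesign",
    "DatasetSpec",
    "PhenotypeSpec",
    "GroundTruth",
    "default_design",
    "default_dataset_specs",
    "default_phenotype_specs",
    "chain_precision",
    "simulate_ggm_block",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class Group:
    name: str
    size: int
    dose: float
    recovery: bool = False


@dataclass
class StudyDesign:
    """Ordered group labels, sizes and dose levels; recovery groups carry their
    dose with attenuation γ."""

    groups: list[Group]
    recovery_attenuation: float = 0.3

    def __post_init__(self) -> None:
        if any(g.size < 2 for g in self.groups):
            raise ValueError("every group needs size >= 2")
        if not 0 <= self.recovery_attenuation <= 1:
            raise ValueError("recovery_attenuation must be in [0,1]")

    @property
    def n_samples(self) -> int:
        return sum(g.size for g in self.groups)

    def sample_frame(self) -> pd.DataFrame:
        """Per-sample group, dose and effect multiplier (γ for recovery groups)."""
        rows = []
        counter = 0
        for g in self.groups:
            for _ in range(g.size):
                counter += 1
                rows.append(
                    {
                        "sample_id": f"s{counter:03d}",
                        "group": g.name,
                        "dose": g.dose,
                        "attenuation": self.recovery_attenuation if g.recovery else 1.0,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def labels(self) -> ClassLabels:
        frame = self.sample_frame()
        levels = [g.name for g in self.groups]
        return ClassLabels(frame["group"].astype(pd.CategoricalDtype(levels)))


def default_design() -> StudyDesign:
    """The default 8-group, 78-animal design."""
    return StudyDesign(
        groups=[
            Group("control", 12, 0.0),
            Group("low", 12, 30.0),
            Group("intermediate1", 12, 100.0),
            Group("intermediate2", 12, 300.0),
            Group("high", 12, 1000.0),
            Group("recovery_control", 6, 0.0, recovery=True),
            Group("recovery_intermediate2", 6, 300.0, recovery=True),
            Group("recovery_high", 6, 1000.0, recovery=True),
        ]
    )


@dataclass
class DatasetSpec:
    """One platform: width, number of dose-responsive features and their effect δ
    (maximum mean shift, in noise-SD units, reached at the top dose)."""

    name: str
    p: int
    n_informative: int = 0
    delta: float = 0.0
    block_precision: np.ndarray | None = None  # correlated block, leading features

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("each dataset needs p >= 2")
        if self.n_informative > self.p:
            raise ValueError("n_informative exceeds p")


@dataclass
class PhenotypeSpec:
    """Clinical phenotype y = Σ β_j · feature_j + N(0, σ); drivers are
    (dataset, feature_id) pairs."""

    name: str
    drivers: list[tuple[str, str]] = field(default_factory=list)
    beta: float = 1.0
    sigma: float = 1.0


@dataclass
class GroundTruth:
    informative: dict[str, list[str]]  # dataset -> dose-responsive feature IDs
    deltas: dict[str, float]
    recovery_attenuation: float
    phenotype_drivers: dict[str, list[tuple[str, str]]]
    phenotype_noise: dict[str, float]
    block_precisions: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "informative": self.informative,
            "deltas": self.deltas,
            "recovery_attenuation": self.recovery_attenuation,
            "phenotype_drivers": {
                k: [list(d) for d in v] for k, v in self.phenotype_drivers.items()
            },
            "phenotype_noise": self.phenotype_noise,
            "block_precisions": {
                k: v.tolist() for k, v in self.block_precisions.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_dataset_specs() -> list[DatasetSpec]:
    """Nine platforms spanning the typical width range (40-feature targeted
    panel up to a 300-feature open profile, ~1000 features total), with
    dose-responsiveness strongest in the DI-MS lipid platforms and absent
    from the open aqueous profiles."""
    return [
        DatasetSpec("acyl_carnitines", 40, 4, 1.6),
        DatasetSpec("gcms_fatty_acids", 70, 6, 1.4),
        DatasetSpec("dims_pos", 130, 10, 2.0),
        DatasetSpec("dims_neg", 120, 8, 1.6),
        DatasetSpec("lcms_lipids_pos", 150, 8, 1.2),
        DatasetSpec("lcms_lipids_neg", 140, 6, 1.0),
        DatasetSpec("aqueous_targeted", 60, 5, 1.2),
        DatasetSpec("aqueous_open_pos", 300, 0, 0.0),
        DatasetSpec("aqueous_open_neg", 90, 2, 0.5),
    ]


def default_phenotype_specs(n_noise_phenotypes: int = 29) -> list[PhenotypeSpec]:
    """35 phenotypes: relative liver weight and five enzyme/analyte panels
    driven by platform features, the rest pure assay noise."""
    named = [
        PhenotypeSpec(
            "relative_liver_weight",
            drivers=[("dims_pos", f"dims_pos_f{i:03d}") for i in range(1, 4)],
            beta=1.0,
            sigma=0.5,
        ),
        PhenotypeSpec(
            "AST",
            drivers=[("gcms_fatty_acids", f"gcms_fatty_acids_f{i:03d}") for i in range(1, 4)],
            beta=1.0,
            sigma=1.0,
        ),
        PhenotypeSpec(
            "albumin",
            drivers=[("dims_neg", f"dims_neg_f{i:03d}") for i in range(1, 3)],
            beta=0.8,
            sigma=1.0,
        ),
        PhenotypeSpec(
            "glucose",
            drivers=[("aqueous_targeted", f"aqueous_targeted_f{i:03d}") for i in range(1, 4)],
            beta=1.0,
            sigma=1.0,
        ),
        PhenotypeSpec(
            "ALP",
            drivers=[("dims_pos", f"dims_pos_f{i:03d}") for i in range(4, 6)],
            beta=0.8,
            sigma=1.2,
        ),
        PhenotypeSpec(
            "ALT",
            drivers=[("acyl_carnitines", f"acyl_carnitines_f{i:03d}") for i in range(1, 3)],
            beta=0.7,
            sigma=1.2,
        ),
    ]
    noise = [PhenotypeSpec(f"cc_{i:02d}", drivers=[], sigma=1.0) for i in range(1, n_noise_phenotypes + 1)]
    return named + noise


def chain_precision(p: int, rho: float = -0.4) -> np.ndarray:
    """Tridiagonal precision matrix of a p-node chain GGM (unit diagonal,
    ``rho`` on the chain links); nonadjacent pairs are conditionally
    independent by construction."""
    prec = np.eye(p)
    for i in range(p - 1):
        prec[i, i + 1] = prec[i + 1, i] = rho
    if np.any(np.linalg.eigvalsh(prec) <= 0):
        raise ValueError(f"chain precision with rho={rho} is not positive definite")
    return prec


def simulate_ggm_block(precision: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """n draws from the zero-mean Gaussian whose covariance is inv(precision)."""
    precision = np.asarray(precision, dtype=float)
    if precision.shape[0] != precision.shape[1] or not np.allclose(precision, precision.T):
        raise ValueError("precision must be square and symmetric")
    eigvals = np.linalg.eigvalsh(precision)
    if eigvals.min() <= 0:
        raise ValueError("precision matrix is not positive definite")
    cov = np.linalg.inv(precision)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(len(precision)), cov, size=n, method="cholesky")


def _dose_effect(frame: pd.DataFrame, delta: float, max_dose: float) -> np.ndarray:
    scale = np.log1p(max_dose) if max_dose > 0 else 1.0
    return delta * np.log1p(frame["dose"].to_numpy()) / scale * frame["attenuation"].to_numpy()


def simulate_study(
    design: StudyDesign | None = None,
    dataset_specs: list[DatasetSpec] | None = None,
    phenotype_specs: list[PhenotypeSpec] | None = None,
    seed: int = 0,
) -> tuple[DatasetCollection, GroundTruth]:
    """Generate an aligned multi-platform study plus its ground truth.

    Features are unit-variance Gaussian noise; the first ``n_informative``
    of each platform additionally shift with dose.  Feature IDs are
    ``<dataset>_fNNN`` (informative features first).  Deterministic per seed.
    """
    design = design or default_design()
    dataset_specs = dataset_specs if dataset_specs is not None else default_dataset_specs()
    phenotype_specs = (
        phenotype_specs if phenotype_specs is not None else default_phenotype_specs()
    )
    rng = np.random.default_rng(seed)
    frame = design.sample_frame()
    n = len(frame)
    max_dose = max(g.dose for g in design.groups)

    tables: list[FeatureTable] = []
    truth = GroundTruth(
        informative={},
        deltas={},
        recovery_attenuation=design.recovery_attenuation,
        phenotype_drivers={},
        phenotype_noise={},
    )
    for spec in dataset_specs:
        X = rng.standard_normal((n, spec.p))
        if spec.block_precision is not None:
            b = len(spec.block_precision)
            if b > spec.p:
                raise ValueError(f"block wider than dataset {spec.name!r}")
            X[:, :b] = simulate_ggm_block(
                spec.block_precision, n, seed=int(rng.integers(2**31))
            )
            truth.block_precisions[spec.name] = np.asarray(spec.block_precision, float)
        ids = [f"{spec.name}_f{i:03d}" for i in range(1, spec.p + 1)]
        if spec.n_informative and spec.delta:
            shift = _dose_effect(frame, spec.delta, max_dose)
            X[:, : spec.n_informative] += shift[:, None]
        truth.informative[spec.name] = ids[: spec.n_informative]
        truth.deltas[spec.name] = spec.delta
        tables.append(
            FeatureTable(spec.name, pd.DataFrame(X, index=frame.index, columns=ids))
        )

    clinical = None
    if phenotype_specs:
        table_by_name = {t.dataset_name: t for t in tables}
        columns = {}
        for pheno in phenotype_specs:
            y = np.zeros(n)
            for dname, fid in pheno.drivers:
                if dname not in table_by_name:
                    raise ValueError(f"phenotype {pheno.name!r}: unknown dataset {dname!r}")
                y = y + pheno.beta * table_by_name[dname].data[fid].to_numpy()
            y = y + rng.normal(0.0, pheno.sigma, size=n)
            columns[pheno.name] = y
            truth.phenotype_drivers[pheno.name] = list(pheno.drivers)
            truth.phenotype_noise[pheno.name] = pheno.sigma
        clinical = ClinicalTable(pd.DataFrame(columns, index=frame.index))

    collection = align_collection(tables, design.labels(), clinical)
    return collection, truth


def write_study(collection: DatasetCollection, truth: GroundTruth, outdir) -> Path:
    """Write CSV tables + a JSON manifest readable by ``io_datasets.read_manifest``;
    returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for t in collection.tables:
        fname = f"{t.dataset_name}.csv"
        t.to_csv(outdir / fname)
        manifest[t.dataset_name] = {"path": fname, "role": "omics"}
    labels = pd.DataFrame({"class": collection.labels.labels.astype(str)})
    labels.index.name = "sample_id"
    labels.to_csv(outdir / "labels.csv")
    manifest["labels"] = {"path": "labels.csv", "role": "labels"}
    if collection.clinical is not None:
        collection.clinical.data.to_csv(outdir / "clinical.csv", index_label="sample_id")
        manifest["clinical"] = {"path": "clinical.csv", "role": "clinical"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    truth.to_json(outdir / "ground_truth.json")
    return outdir / "manifest.json"
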