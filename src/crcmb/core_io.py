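"""Feature-table / metadata I/O, cohort validation, and pipeline orchestration.

Feature tables are dense non-negative integer matrices (samples x features)
read from TSV (first column = sample IDs, header = feature IDs) or BIOM-JSON
(v1.0, dense or sparse).  Metadata is a TSV keyed by ``sample_id`` with the
paired-cohort columns (``subject_id``, ``tissue``, ``survival``) plus optional
clinical covariates.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "Config",
    "CohortBundle",
    "CohortValidationError",
    "TableFormatError",
    "MetadataError",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "validate_cohort",
    "read_config",
    "run_pipeline",
    "TISSUES",
    "SURVIVAL_GROUPS",
    "COVARIATE_LEVELS",
]

TISSUES = ("normal", "tumor")
SURVIVAL_GROUPS = ("short", "long")

#: Clinical covariate columns and their admissible categories (Table-1 coding).
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age": ("<60", "60-69", "70-74", ">=75"),
    "sex": ("female", "male"),
    "asa": ("I", "II", "III-IV"),
    "location": ("colon right", "colon left", "rectum"),
    "stage": ("III", "IV"),
    "differentiation": ("low", "medium", "high"),
    "surgery_period": ("1997-2005", "2006-2010", "2011-2017"),
    "radical_surgery": ("no", "yes"),
}

REQUIRED_METADATA_COLUMNS = ("subject_id", "tissue", "survival")


class TableFormatError(ValueError):
    """A feature-table file violates the format contract."""


class MetadataError(ValueError):
    """A metadata file violates the format contract."""


class CohortValidationError(ValueError):
    """Cohort validation produced an empty or inconsistent cohort."""


@dataclass(frozen=True)
class FeatureTable:
    """Dense samples x features count matrix with unique string IDs."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    counts: np.ndarray  # int64, shape (n_samples, n_features)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise TableFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise TableFormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise TableFormatError("counts must be non-negative")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    # -- convenience ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def feature_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def feature_prevalence(self) -> np.ndarray:
        """Number of samples in which each feature has a nonzero count."""
        return (self.counts > 0).sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        rows = [index[s] for s in wanted]
        return FeatureTable(tuple(wanted), self.feature_ids, self.counts[rows])

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        wanted = list(feature_ids)
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in wanted if f not in index]
        if missing:
            raise KeyError(f"unknown feature IDs: {missing}")
        cols = [index[f] for f in wanted]
        return FeatureTable(self.sample_ids, tuple(wanted), self.counts[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata table indexed by sample ID.

    Wraps a pandas DataFrame with required columns ``subject_id``, ``tissue``
    (normal/tumor) and ``survival`` (short/long); any column named in
    :data:`COVARIATE_LEVELS` is validated against its category set.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        if frame.index.name != "sample_id":
            if "sample_id" in frame.columns:
                frame = frame.set_index("sample_id")
            else:
                raise MetadataError("metadata requires a sample_id column or index")
        frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise MetadataError(f"duplicate sample IDs in metadata: {dupes}")
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in frame.columns:
                raise MetadataError(f"metadata missing required column {col!r}")
        for col, levels in (("tissue", TISSUES), ("survival", SURVIVAL_GROUPS)):
            bad = frame.loc[~frame[col].isin(levels) | frame[col].isna()]
            if len(bad):
                raise MetadataError(
                    f"invalid {col} value(s) {sorted(set(bad[col].astype(str)))} "
                    f"in sample(s) {bad.index.tolist()}; allowed: {list(levels)}"
                )
        for col, levels in COVARIATE_LEVELS.items():
            if col in frame.columns:
                bad = frame.loc[frame[col].notna() & ~frame[col].isin(levels)]
                if len(bad):
                    raise MetadataError(
                        f"invalid {col} value(s) {sorted(set(bad[col].astype(str)))} "
                        f"in sample(s) {bad.index.tolist()}; allowed: {list(levels)}"
                    )
        per_tissue = frame.groupby(["subject_id", "tissue"], observed=True).size()
        doubled = per_tissue[per_tissue > 1]
        if len(doubled):
            raise MetadataError(
                "subjects with more than one sample per tissue: "
                f"{sorted({s for s, _ in doubled.index})}"
            )
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.frame["subject_id"]))

    def select_samples(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].reset_index())

    def sample_for(self, subject_id: str, tissue: str) -> str:
        """Sample ID of ``subject_id``'s sample of the given tissue."""
        sel = self.frame[
            (self.frame["subject_id"] == subject_id) & (self.frame["tissue"] == tissue)
        ]
        if len(sel) != 1:
            raise KeyError(f"subject {subject_id!r} has no unique {tissue} sample")
        return str(sel.index[0])

    def paired_subjects(self) -> list[str]:
        """Subject IDs having exactly one sample of each tissue."""
        pivot = self.frame.groupby("subject_id")["tissue"].agg(lambda t: frozenset(t))
        return [s for s in self.subject_ids if pivot[s] == frozenset(TISSUES)]

    def subject_survival(self) -> pd.Series:
        """Per-subject survival group (consistent across the subject's samples)."""
        groups = self.frame.groupby("subject_id")["survival"].agg(set)
        mixed = groups[groups.map(len) > 1]
        if len(mixed):
            raise MetadataError(f"inconsistent survival within subject(s): {list(mixed.index)}")
        return groups.map(lambda s: next(iter(s)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class Config:
    """Flat pipeline configuration (TOML key/value file)."""

    table: str = ""
    metadata: str = ""
    dialect: str = "tsv"
    stages: tuple[str, ...] = ()
    out_dir: str = "crcmb_out"
    seed: int = 0
    min_depth: int = 2500
    rarefaction_depth: int = 2500
    n_perm: int = 999
    ctf_min_samples: int = 20
    ctf_min_total: int = 100
    rpca_min_frac: float = 0.10
    rpca_min_total: int = 10
    dr_rel_threshold: float = 0.001
    dr_min_frac: float = 0.10
    ctf_rank: int = 3
    dr_iterations: int = 4000
    dr_method: str = "map"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("permutation count must be >= 1")
        if self.min_depth < 1 or self.rarefaction_depth < 1:
            raise ValueError("depth must be >= 1")
        self.stages = tuple(self.stages)

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortBundle:
    """Validated paired cohort: table + metadata + provenance notes."""

    table: FeatureTable
    metadata: SampleMetadata
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.table.sample_ids) != set(self.metadata.sample_ids):
            raise CohortValidationError(
                "table and metadata sample sets differ: "
                f"table-only={sorted(set(self.table.sample_ids) - set(self.metadata.sample_ids))} "
                f"metadata-only={sorted(set(self.metadata.sample_ids) - set(self.table.sample_ids))}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _check_unique(ids: Sequence, kind: str) -> None:
    seen: set = set()
    dupes = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen.add(x)
    if dupes:
        raise TableFormatError(f"duplicate {kind} ID(s): {sorted(set(map(str, dupes)))}")


def read_feature_table(path: str | Path, dialect: str = "tsv") -> FeatureTable:
    """Read a feature table from ``tsv`` or ``biom-json``.

    TSV layout: header row of feature IDs, first column sample IDs.
    Zero-count features are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_table_tsv(path)
    if dialect == "biom-json":
        return _read_table_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'biom-json'")


def _read_table_tsv(path: Path) -> FeatureTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    feature_ids = header[1:]
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise TableFormatError(
                f"{path}: row for {parts[0]!r} has {len(parts) - 1} entries, "
                f"expected {len(feature_ids)}"
            )
        sample_ids.append(parts[0])
        row = []
        for feat, val in zip(feature_ids, parts[1:]):
            try:
                fval = float(val)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric count {val!r} (sample {parts[0]!r}, feature {feat!r})"
                ) from None
            if fval < 0 or fval != int(fval):
                raise TableFormatError(
                    f"{path}: count must be a non-negative integer, got {val!r} "
                    f"(sample {parts[0]!r}, feature {feat!r})"
                )
            row.append(int(fval))
        rows.append(row)
    counts = np.array(rows, dtype=np.int64).reshape(len(sample_ids), len(feature_ids))
    return FeatureTable(tuple(sample_ids), tuple(feature_ids), counts)


def _read_table_biom_json(path: Path) -> FeatureTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        n_feat, n_samp = doc["shape"]
        matrix_type = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise TableFormatError(f"{path}: not a BIOM-JSON table ({exc})") from exc
    if (len(feature_ids), len(sample_ids)) != (n_feat, n_samp):
        raise TableFormatError(f"{path}: BIOM shape does not match row/column lists")
    mat = np.zeros((n_feat, n_samp))
    if matrix_type == "dense":
        mat = np.asarray(data, dtype=float).reshape(n_feat, n_samp)
    else:
        for i, j, v in data:
            mat[int(i), int(j)] = v
    # BIOM stores features x samples; FeatureTable is samples x features.
    return FeatureTable(tuple(sample_ids), tuple(feature_ids), mat.T)


def write_feature_table(
    table: FeatureTable, path: str | Path, dialect: str = "tsv", header: str | None = None
) -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("sample_id\t" + "\t".join(table.feature_ids) + "\n")
            for sid, row in zip(table.sample_ids, table.counts):
                fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    elif dialect == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "crcmb",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(table.feature_ids), len(table.sample_ids)],
            "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read and validate the sample metadata TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in frame.columns:
        raise MetadataError(f"{path}: missing sample_id column")
    for col in REQUIRED_METADATA_COLUMNS:
        if col in frame.columns:
            missing = frame.loc[frame[col].isna(), "sample_id"].tolist()
            if missing:
                raise MetadataError(f"{path}: missing {col} for sample(s) {missing}")
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        metadata.frame.reset_index().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort validation


def validate_cohort(
    table: FeatureTable, metadata: SampleMetadata, min_depth: int = 2500
) -> CohortBundle:
    """Depth-filter samples and keep only fully paired subjects.

    A subject whose tumor or normal sample is absent or below ``min_depth``
    loses both samples.  Exclusions are tallied by reason in the bundle's
    provenance.
    """
    shared = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    exclusions: dict[str, list[str]] = {
        "no_metadata": sorted(set(table.sample_ids) - set(shared)),
        "no_counts": sorted(set(metadata.sample_ids) - set(table.sample_ids)),
        "low_depth": [],
        "unpaired_subject": [],
    }
    sub_table = table.select_samples(shared)
    depths = dict(zip(sub_table.sample_ids, sub_table.sample_totals()))
    deep = [s for s in shared if depths[s] >= min_depth]
    exclusions["low_depth"] = sorted(set(shared) - set(deep))

    meta_deep = metadata.frame.loc[deep]
    pivot = meta_deep.groupby("subject_id")["tissue"].agg(lambda t: frozenset(t))
    paired_subjects = set(pivot[pivot == frozenset(TISSUES)].index)
    kept = [s for s in deep if meta_deep.loc[s, "subject_id"] in paired_subjects]
    exclusions["unpaired_subject"] = sorted(set(deep) - set(kept))

    if not kept:
        raise CohortValidationError(
            f"no fully paired subjects remain after validation (min_depth={min_depth}); "
            f"exclusions: { {k: len(v) for k, v in exclusions.items()} }"
        )
    bundle = CohortBundle(
        table=table.select_samples(kept),
        metadata=metadata.select_samples(kept),
        provenance={
            "min_depth": min_depth,
            "n_subjects": len(paired_subjects),
            "n_samples": len(kept),
            "exclusions": {k: v for k, v in exclusions.items()},
            "exclusion_counts": {k: len(v) for k, v in exclusions.items()},
        },
    )
    return bundle


# ---------------------------------------------------------------------------
# config + pipeline driver


def read_config(path: str | Path) -> Config:
    """Parse a flat TOML key/value file into a :class:`Config`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return Config(**raw)


PIPELINE_STAGES = ("validate", "preprocess", "betadiv", "ordinate", "dr", "index", "model")


def run_pipeline(config: Config) -> dict[str, list[str]]:
    """Run the requested stages in dependency order; returns files per stage.

    Stage outputs land under ``config.out_dir`` with deterministic content
    (seed and parameters recorded in each file header), so re-running an
    identical config reproduces byte-identical statistical outputs.
    """
    from . import pipeline  # local import: pipeline pulls in every stage module

    stages = config.stages or PIPELINE_STAGES
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {list(PIPELINE_STAGES)}")
    ordered = [s for s in PIPELINE_STAGES if s in stages]
    return pipeline.run(config, ordered)
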