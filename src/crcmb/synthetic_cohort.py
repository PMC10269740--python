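"""Synthetic paired tumor/normal cohorts with known ground truth.

The generative model mirrors the structure the downstream analysis assumes:
per-subject random intercepts on the log-abundance scale (individual microbial
identity), a tissue effect concentrated in a designated feature subset, a
survival x tissue interaction in another subset, softmax closure so depth and
composition are decoupled, and negative-binomial counts with log-normal
per-sample sequencing depth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    COVARIATE_LEVELS,
    CohortBundle,
    FeatureTable,
    SampleMetadata,
    read_feature_table,
    read_metadata,
    write_feature_table,
    write_metadata,
)

__all__ = ["SyntheticTruth", "default_truth", "generate_cohort", "write_fixtures", "read_truth"]

LN2 = np.log(2.0)

#: Approximate Table-1 cohort frequencies for each clinical covariate.
DEFAULT_COVARIATE_FREQS: dict[str, tuple[float, ...]] = {
    "age": (0.20, 0.28, 0.26, 0.26),
    "sex": (0.45, 0.55),
    "asa": (0.30, 0.45, 0.25),
    "location": (0.35, 0.30, 0.35),
    "stage": (0.60, 0.40),
    "differentiation": (0.30, 0.55, 0.15),
    "surgery_period": (0.35, 0.35, 0.30),
    "radical_surgery": (0.15, 0.85),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth generative parameters for one synthetic cohort.

    ``tissue_effect`` and ``interaction_effect`` are per-feature log2-fold
    changes (tumor vs normal; extra change in tumors of short-term survivors).
    ``nb_dispersion`` is the negative-binomial size parameter phi, so that
    Var = mu + mu^2/phi.
    """

    baseline_log_abundance: np.ndarray
    subject_sd: float
    tissue_effect: np.ndarray
    interaction_effect: np.ndarray
    nb_dispersion: float
    depth_log_mean: float
    depth_log_sd: float
    seed: int
    covariate_freqs: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_FREQS))

    def __post_init__(self) -> None:
        base = np.asarray(self.baseline_log_abundance, dtype=float)
        te = np.asarray(self.tissue_effect, dtype=float)
        ie = np.asarray(self.interaction_effect, dtype=float)
        if not (base.shape == te.shape == ie.shape) or base.ndim != 1:
            raise ValueError("effect vectors must be 1-D with one entry per feature")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be >= 0")
        object.__setattr__(self, "baseline_log_abundance", base)
        object.__setattr__(self, "tissue_effect", te)
        object.__setattr__(self, "interaction_effect", ie)

    @property
    def n_features(self) -> int:
        return self.baseline_log_abundance.size


def default_truth(
    n_features: int = 250,
    seed: int = 0,
    subject_sd: float = 1.0,
    nb_dispersion: float = 0.5,
    n_tissue_features: int = 30,
    tissue_effect_size: tuple[float, float] = (1.0, 2.0),
    n_interaction_features: int = 38,
    interaction_effect_size: float = 1.5,
    depth_median: float = 20_000.0,
    depth_log_sd: float = 0.5,
) -> SyntheticTruth:
    """Build a default truth: log-normal baselines, +/-1-2 log2 tissue effects
    on ``n_tissue_features`` features and a +/-``interaction_effect_size`` log2
    interaction on a disjoint block of ``n_interaction_features`` features."""
    if n_features < 10:
        raise ValueError("n_features must be >= 10")
    if n_tissue_features + n_interaction_features > n_features:
        raise ValueError("effect feature blocks exceed n_features")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, 1.5, n_features)
    tissue = np.zeros(n_features)
    lo, hi = tissue_effect_size
    magnitudes = rng.uniform(lo, hi, n_tissue_features)
    signs = np.where(np.arange(n_tissue_features) % 2 == 0, 1.0, -1.0)
    tissue[:n_tissue_features] = signs * magnitudes
    interaction = np.zeros(n_features)
    isigns = np.where(np.arange(n_interaction_features) % 2 == 0, 1.0, -1.0)
    interaction[n_tissue_features : n_tissue_features + n_interaction_features] = (
        isigns * interaction_effect_size
    )
    return SyntheticTruth(
        baseline_log_abundance=baseline,
        subject_sd=subject_sd,
        tissue_effect=tissue,
        interaction_effect=interaction,
        nb_dispersion=nb_dispersion,
        depth_log_mean=float(np.log(depth_median)),
        depth_log_sd=depth_log_sd,
        seed=seed,
    )


def _sample_covariates(rng: np.random.Generator, freqs: dict) -> dict[str, str]:
    row = {}
    for col, levels in COVARIATE_LEVELS.items():
        p = np.asarray(freqs.get(col, np.ones(len(levels)) / len(levels)), dtype=float)
        p = p / p.sum()
        row[col] = levels[rng.choice(len(levels), p=p)]
    return row


def generate_cohort(
    n_subjects: int,
    n_short: int,
    n_features: int | None = None,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> tuple[CohortBundle, SyntheticTruth]:
    """Generate a paired cohort: exactly two samples (normal, tumor) per subject.

    Counts for sample s of subject i are NB with mean
    ``depth_s * softmax(baseline + u_i + ln2 * (tissue_effect*[tumor]
    + interaction_effect*[tumor and short]))`` and size ``nb_dispersion``.
    The truth is returned verbatim (with the effective seed recorded).
    """
    if truth is None:
        nf = n_features or 250
        # shrink the default effect blocks proportionally for small tables
        truth = default_truth(
            nf,
            seed=seed if seed is not None else 0,
            n_tissue_features=max(1, min(30, nf * 30 // 250)),
            n_interaction_features=max(1, min(38, nf * 38 // 250)),
        )
    if n_features is not None and n_features != truth.n_features:
        raise ValueError(
            f"n_features={n_features} does not match truth ({truth.n_features} features)"
        )
    if n_short > n_subjects:
        raise ValueError("n_short must be <= n_subjects")
    if seed is not None and seed != truth.seed:
        truth = replace(truth, seed=seed)
    rng = np.random.default_rng(truth.seed)

    p = truth.n_features
    phi = truth.nb_dispersion
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    survival = np.array(["short"] * n_short + ["long"] * (n_subjects - n_short))
    rng.shuffle(survival)
    u = rng.normal(0.0, truth.subject_sd, size=(n_subjects, p)) if truth.subject_sd > 0 else np.zeros((n_subjects, p))

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_rows: list[np.ndarray] = []
    for i, subj in enumerate(subjects):
        short = survival[i] == "short"
        covs = _sample_covariates(rng, truth.covariate_freqs)
        for tissue in ("normal", "tumor"):
            eta = truth.baseline_log_abundance + u[i]
            if tissue == "tumor":
                eta = eta + LN2 * truth.tissue_effect
                if short:
                    eta = eta + LN2 * truth.interaction_effect
            comp = np.exp(eta - eta.max())
            comp /= comp.sum()
            depth = float(np.exp(rng.normal(truth.depth_log_mean, truth.depth_log_sd)))
            mu = np.maximum(depth * comp, 1e-12)
            counts = rng.negative_binomial(phi, phi / (phi + mu))
            sid = f"{subj}.{tissue[0].upper()}"
            sample_ids.append(sid)
            count_rows.append(counts.astype(np.int64))
            meta_rows.append(
                {"sample_id": sid, "subject_id": subj, "tissue": tissue,
                 "survival": survival[i], **covs}
            )

    feature_ids = tuple(f"F{j + 1:04d}" for j in range(p))
    table = FeatureTable(tuple(sample_ids), feature_ids, np.vstack(count_rows))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    bundle = CohortBundle(
        table=table,
        metadata=metadata,
        provenance={
            "generator": "synthetic_cohort.generate_cohort",
            "seed": truth.seed,
            "n_subjects": n_subjects,
            "n_short": n_short,
            "n_features": p,
        },
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# fixture serialization


def write_fixtures(bundle: CohortBundle, truth: SyntheticTruth, out_dir: str | Path) -> list[Path]:
    """Write table.tsv, metadata.tsv, truth.tsv and generation.log.

    Deterministic content: the same bundle/truth always yields byte-identical
    files.  Reading the files back reproduces the bundle exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "table.tsv"
    meta_path = out / "metadata.tsv"
    truth_path = out / "truth.tsv"
    log_path = out / "generation.log"

    header = f"crcmb synthetic cohort seed={truth.seed}"
    write_feature_table(bundle.table, table_path, header=header)
    write_metadata(bundle.metadata, meta_path, header=header)

    with open(truth_path, "w") as fh:
        fh.write(f"# {header}\n")
        for key in ("subject_sd", "nb_dispersion", "depth_log_mean", "depth_log_sd"):
            fh.write(f"#@ {key}={float(getattr(truth, key))!r}\n")
        fh.write(f"#@ seed={truth.seed}\n")
        fh.write("feature_id\tbaseline_log_abundance\ttissue_effect\tinteraction_effect\n")
        for fid, b, t, g in zip(
            bundle.table.feature_ids,
            truth.baseline_log_abundance,
            truth.tissue_effect,
            truth.interaction_effect,
        ):
            fh.write(f"{fid}\t{float(b)!r}\t{float(t)!r}\t{float(g)!r}\n")

    digest = hashlib.sha256(bundle.table.counts.tobytes()).hexdigest()[:16]
    with open(log_path, "w") as fh:
        fh.write(f"{header}\n")
        for k, v in bundle.provenance.items():
            fh.write(f"{k}={v}\n")
        fh.write(f"counts_sha256_prefix={digest}\n")
    return [table_path, meta_path, truth_path, log_path]


def read_truth(path: str | Path) -> SyntheticTruth:
    """Read a truth file written by :func:`write_fixtures`."""
    scalars: dict[str, float] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("#@ "):
                key, val = ln[3:].split("=", 1)
                scalars[key] = float(val)
            elif ln.startswith("#") or not ln:
                continue
            else:
                rows.append(ln.split("\t"))
    body = rows[1:]  # skip column header
    return SyntheticTruth(
        baseline_log_abundance=np.array([float(r[1]) for r in body]),
        subject_sd=scalars["subject_sd"],
        tissue_effect=np.array([float(r[2]) for r in body]),
        interaction_effect=np.array([float(r[3]) for r in body]),
        nb_dispersion=scalars["nb_dispersion"],
        depth_log_mean=scalars["depth_log_mean"],
        depth_log_sd=scalars["depth_log_sd"],
        seed=int(scalars["seed"]),
    )


def read_fixtures(dir_path: str | Path) -> tuple[CohortBundle, SyntheticTruth]:
    """Round-trip loader for :func:`write_fixtures` output."""
    dir_path = Path(dir_path)
    table = read_feature_table(dir_path / "table.tsv")
    metadata = read_metadata(dir_path / "metadata.tsv")
    truth = read_truth(dir_path / "truth.tsv")
    bundle = CohortBundle(table=table, metadata=metadata, provenance={"seed": truth.seed})
    return bundle, truth
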