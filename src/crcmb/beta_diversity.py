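"""Distance matrices, paired tumor/normal distances, and the intra- vs
inter-individual permutation comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import FeatureTable, SampleMetadata
from .perm_stats import TestResult
from .preprocess import TransformedMatrix, clr

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "paired_distances",
    "intra_inter_test",
]

METRICS = ("bray_curtis", "jaccard_binary", "aitchison")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix must be square and match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate IDs in distance matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", v)

    def loc(self, a: str, b: str) -> float:
        index = {s: i for i, s in enumerate(self.ids)}
        return float(self.values[index[a], index[b]])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(rows, rows)], self.metric)

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for sid, row in zip(self.ids, self.values):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def distance_matrix(
    table_or_transform: FeatureTable | TransformedMatrix,
    metric: str,
    pseudocount: float = 1.0,
) -> DistanceMatrix:
    """Pairwise distances between samples.

    ``bray_curtis`` and ``jaccard_binary`` take a (rarefied) count table;
    ``aitchison`` takes an unrarefied count table (CLR with ``pseudocount``
    applied internally) or a precomputed complete CLR matrix.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; known: {METRICS}")
    if metric == "aitchison":
        if isinstance(table_or_transform, TransformedMatrix):
            tm = table_or_transform
            if tm.transform != "clr":
                raise ValueError("aitchison requires a complete CLR matrix or a count table")
            mat = tm.values
            ids = tm.sample_ids
        else:
            tm = clr(table_or_transform, pseudocount=pseudocount)
            mat, ids = tm.values, tm.sample_ids
        condensed = pdist(mat, metric="euclidean")
    else:
        if not isinstance(table_or_transform, FeatureTable):
            raise ValueError(f"{metric} requires a count FeatureTable")
        counts = table_or_transform.counts.astype(float)
        ids = table_or_transform.sample_ids
        if metric == "bray_curtis":
            condensed = pdist(counts, metric="braycurtis")
        else:
            condensed = pdist(counts > 0, metric="jaccard")
    return DistanceMatrix(tuple(ids), squareform(condensed), metric)


def paired_distances(dm: DistanceMatrix, metadata: SampleMetadata) -> dict[str, float]:
    """Per-subject distance between the subject's tumor and normal samples."""
    out: dict[str, float] = {}
    for subj in metadata.subject_ids:
        try:
            t = metadata.sample_for(subj, "tumor")
            n = metadata.sample_for(subj, "normal")
        except KeyError as exc:
            raise ValueError(f"subject {subj!r} is not fully paired: {exc}") from exc
        out[subj] = dm.loc(t, n)
    return out


def intra_inter_test(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    n_perm: int = 999,
    seed: int = 0,
    strata: tuple[str, ...] = ("tissue", "location", "survival"),
    equal_var: bool = False,
    scheme: str = "pairing",
) -> TestResult:
    """Within-subject paired distances vs between-subject distances matched on
    the stratification columns, compared with a permutation two-sample t test
    (Welch by default).

    Group A: each subject's tumor-normal distance.  Group B: distances between
    samples of different subjects that agree on every stratum column.

    Two permutation schemes are available.  ``"pairing"`` (default) permutes
    the subject labels, i.e. which tumor sample is paired with which normal
    sample, within strata matched on the non-tissue columns; this is the
    exchangeable unit under the null of no subject effect and is calibrated.
    ``"pooled"`` permutes group membership over the pooled distance values;
    because every sample contributes to both groups, that scheme is
    conservative under the null (kept for comparability).
    """
    frame = metadata.frame
    missing = [c for c in strata if c not in frame.columns]
    if missing:
        raise ValueError(f"metadata lacks strata column(s) {missing}")

    intra = np.array(list(paired_distances(dm, metadata).values()))

    index = {s: i for i, s in enumerate(dm.ids)}
    samples = list(frame.index)
    keys = frame[list(strata)].astype(str).agg("|".join, axis=1)
    inter: list[float] = []
    seen_strata: set[str] = set()
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            if frame.loc[a, "subject_id"] == frame.loc[b, "subject_id"]:
                continue
            if keys[a] != keys[b]:
                continue
            seen_strata.add(keys[a])
            inter.append(dm.values[index[a], index[b]])
    strata_sizes = keys.value_counts()
    singletons = strata_sizes[strata_sizes < 2]
    if not inter:
        raise ValueError(
            f"no matched between-subject pairs; empty/singleton strata: {list(singletons.index)}"
        )
    if len(singletons):
        warnings.warn(
            f"strata with < 2 samples skipped: {list(singletons.index)}", stacklevel=2
        )
    inter_arr = np.array(inter)

    from .perm_stats import TestResult as TR, _p_value, _tail_exceed, _welch_t, cohens_d, perm_welch_t

    if scheme == "pooled":
        res = perm_welch_t(intra, inter_arr, n_perm=n_perm, seed=seed, equal_var=equal_var)
        return TestResult(
            res.statistic, res.p_value, n_perm, seed, "intra_inter_t",
            effect_size=res.effect_size,
            extras={"n_intra": int(intra.size), "n_inter": int(inter_arr.size)},
        )
    if scheme != "pairing":
        raise ValueError(f"unknown scheme {scheme!r}; expected 'pairing' or 'pooled'")

    # pairing scheme: permute which tumor sample is matched with which normal
    # sample within strata that agree on every non-tissue stratum column; the
    # (fixed, same-tissue) inter group is unaffected by the pairing.
    non_tissue = tuple(c for c in strata if c != "tissue")
    subjects = sorted(metadata.subject_ids)  # canonical order: order-invariant p
    tumor_ids = [metadata.sample_for(s, "tumor") for s in subjects]
    normal_ids = [metadata.sample_for(s, "normal") for s in subjects]
    subj_keys = (
        frame.loc[tumor_ids, list(non_tissue)].astype(str).agg("|".join, axis=1)
        if non_tissue
        else pd.Series("", index=tumor_ids)
    )
    index = {s: i for i, s in enumerate(dm.ids)}
    cross = dm.values[np.ix_([index[t] for t in tumor_ids], [index[n] for n in normal_ids])]
    if (subj_keys.value_counts() < 2).all():
        raise ValueError("every pairing stratum has a single subject; nothing to permute")

    rng = np.random.default_rng(seed)
    n_subj = len(subjects)
    perm_cols = np.tile(np.arange(n_subj), (n_perm, 1))
    for _, idx in pd.Series(range(n_subj), index=subj_keys.to_numpy()).groupby(level=0):
        pos = idx.to_numpy()
        if pos.size < 2:
            continue
        perm_cols[:, pos] = rng.permuted(np.tile(pos, (n_perm, 1)), axis=1)
    intra_null = cross[np.arange(n_subj)[None, :], perm_cols]  # n_perm x n_subj

    nb = inter_arr.size
    b_sum, b_sq = inter_arr.sum(), (inter_arr**2).sum()
    t_obs = float(_welch_t(intra.sum(), (intra**2).sum(), n_subj, b_sum, b_sq, nb))
    null = _welch_t(
        intra_null.sum(axis=1), (intra_null**2).sum(axis=1), n_subj, b_sum, b_sq, nb
    )
    p = _p_value(_tail_exceed(null, t_obs, "two"), n_perm)
    try:
        d = cohens_d(intra, inter_arr)
    except ValueError:
        d = float(np.sign(intra.mean() - inter_arr.mean()) * np.inf)
    return TestResult(
        t_obs, p, n_perm, seed, "intra_inter_t", effect_size=d,
        extras={"n_intra": int(n_subj), "n_inter": int(nb)},
    )
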