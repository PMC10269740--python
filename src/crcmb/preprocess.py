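"""Feature filters, rarefaction, and compositional transforms (rCLR / CLR).

All three filter rules implement the strict inequalities of their definitions:
a feature is removed when its prevalence or total falls strictly below the
threshold, so exact-boundary features are retained.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import FeatureTable

__all__ = [
    "TransformedMatrix",
    "filter_ctf",
    "filter_rpca",
    "filter_dr",
    "rarefy",
    "rclr",
    "clr",
]


class EmptyFilterError(ValueError):
    """A filter or rarefaction step removed everything."""


@dataclass(frozen=True)
class TransformedMatrix:
    """Real-valued samples x features matrix from a log-ratio transform.

    ``values`` uses NaN for missing entries; rCLR matrices are missing exactly
    where counts were zero, CLR matrices are complete.
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    transform: str  # "rclr" | "clr"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match ID lists")
        if self.transform not in ("rclr", "clr"):
            raise ValueError(f"unknown transform tag {self.transform!r}")
        if self.transform == "clr" and np.isnan(values).any():
            raise ValueError("clr matrices must be complete")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("sample_id\t" + "\t".join(self.feature_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")


def _prevalence_threshold(min_frac: float, n_samples: int) -> int:
    # ceil(min_frac * n) computed robustly against float fuzz (0.1*110 -> 11.000...2)
    return int(math.ceil(round(min_frac * n_samples, 9)))


def _apply_feature_mask(table: FeatureTable, keep: np.ndarray, what: str) -> FeatureTable:
    if not keep.any():
        raise EmptyFilterError(f"{what} removed every feature")
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.select_features(kept)


def filter_ctf(table: FeatureTable, min_samples: int = 20, min_total: int = 100) -> FeatureTable:
    """Remove features present in fewer than ``min_samples`` samples or with
    total count < ``min_total``; samples are untouched."""
    keep = (table.feature_prevalence() >= min_samples) & (table.feature_totals() >= min_total)
    return _apply_feature_mask(table, keep, "filter_ctf")


def filter_rpca(table: FeatureTable, min_frac: float = 0.10, min_total: int = 10) -> FeatureTable:
    """Remove features present in < ``min_frac`` of the samples of the table
    passed in, or with fewer than ``min_total`` total counts."""
    thr = _prevalence_threshold(min_frac, len(table.sample_ids))
    keep = (table.feature_prevalence() >= thr) & (table.feature_totals() >= min_total)
    return _apply_feature_mask(table, keep, "filter_rpca")


def filter_dr(
    table: FeatureTable, rel_threshold: float = 0.001, min_frac: float = 0.10
) -> FeatureTable:
    """Keep a feature iff its per-sample relative abundance reaches
    ``rel_threshold`` in at least ``min_frac`` of samples."""
    totals = table.sample_totals().astype(float)
    if (totals == 0).any():
        raise ValueError("filter_dr requires every sample to have nonzero total")
    rel = table.counts / totals[:, None]
    n_hit = (rel >= rel_threshold).sum(axis=0)
    keep = n_hit >= min_frac * len(table.sample_ids) - 1e-9
    return _apply_feature_mask(table, keep, "filter_dr")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # Per-sample substream keyed by (seed, sample ID) so results do not depend
    # on sample order.
    digest = hashlib.sha256(sample_id.encode()).digest()[:8]
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with total < ``depth`` are dropped.  Draws are multivariate
    hypergeometric with per-sample seed substreams derived from one global
    seed, so results are independent of sample order.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    kept_ids, rows = [], []
    for sid, row, total in zip(table.sample_ids, table.counts, totals):
        if total < depth:
            continue
        rng = _sample_rng(seed, sid)
        rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if not kept_ids:
        raise EmptyFilterError(f"rarefy: every sample is below depth {depth}")
    return FeatureTable(tuple(kept_ids), table.feature_ids, np.vstack(rows))


def rclr(table: FeatureTable) -> TransformedMatrix:
    """Robust CLR: zeros become missing; each observed entry is log(count)
    minus the mean log over that sample's observed entries."""
    counts = table.counts.astype(float)
    nonzero = counts > 0
    if (nonzero.sum(axis=1) < 2).any():
        bad = [s for s, n in zip(table.sample_ids, nonzero.sum(axis=1)) if n < 2]
        raise ValueError(f"rclr requires >= 2 nonzero features per sample; offending: {bad}")
    logc = np.full(counts.shape, np.nan)
    np.log(counts, where=nonzero, out=logc)
    row_mean = np.nanmean(logc, axis=1, keepdims=True)
    return TransformedMatrix(table.sample_ids, table.feature_ids, logc - row_mean, "rclr")


def clr(table: FeatureTable, pseudocount: float = 1.0) -> TransformedMatrix:
    """CLR with pseudocount: ln(count + pc) minus the per-sample row mean.

    ``pseudocount=0`` is allowed only on tables without zeros.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (table.counts == 0).any():
        raise ValueError("pseudocount=0 requires a zero-free table")
    logc = np.log(table.counts + float(pseudocount))
    values = logc - logc.mean(axis=1, keepdims=True)
    return TransformedMatrix(table.sample_ids, table.feature_ids, values, "clr")
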