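"""Permutation tests and effect sizes.

Every permutation p-value uses the (b+1)/(m+1) estimator, so the smallest
attainable p at 999 permutations is 0.001, and every test is exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TestResult",
    "perm_paired_t",
    "perm_welch_t",
    "permanova",
    "cohens_d",
    "write_results",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    test: str
    effect_size: float | None = None
    extras: dict | None = None

    def __post_init__(self) -> None:
        if not (1.0 / (self.n_perm + 1) - 1e-12 <= self.p_value <= 1.0):
            raise ValueError(
                f"p-value {self.p_value} outside [1/(n_perm+1), 1] for n_perm={self.n_perm}"
            )


def _p_value(exceed: int, n_perm: int) -> float:
    return (exceed + 1) / (n_perm + 1)


def _tail_exceed(null: np.ndarray, observed: float, tail: str) -> int:
    if tail == "two":
        return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if tail == "greater":
        return int(np.sum(null >= observed - 1e-12))
    if tail == "less":
        return int(np.sum(null <= observed + 1e-12))
    raise ValueError(f"unknown tail {tail!r}")


def _t_one_sample(x: np.ndarray, axis: int = -1) -> np.ndarray:
    n = x.shape[axis]
    m = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        # zero spread: +/- inf by the sign of the mean (0/0 -> nan -> 0)
        t = np.where(sd == 0, np.sign(m) * np.inf, t)
    return np.where(np.isnan(t), 0.0, t)


def perm_paired_t(
    deltas: np.ndarray, n_perm: int = 999, seed: int = 0, tail: str = "two"
) -> TestResult:
    """Sign-flip permutation paired t test on within-subject differences.

    Observed statistic is the classical paired t; the null flips the sign of
    each difference independently.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 1 or deltas.size < 2:
        raise ValueError("deltas must be a 1-D vector with n >= 2")
    if not np.isfinite(deltas).all():
        raise ValueError("deltas must be finite")
    if np.all(deltas == deltas[0]) and deltas[0] == 0:
        raise ValueError("zero variance: all deltas are 0")
    t_obs = float(_t_one_sample(deltas))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, deltas.size))
    # sorted deltas: the sign-flip null is exchangeable, and sorting makes the
    # p-value invariant to the order the deltas arrive in
    null = _t_one_sample(signs * np.sort(deltas)[None, :], axis=1)
    p = _p_value(_tail_exceed(null, t_obs, tail), n_perm)
    d = float(np.mean(deltas) / np.std(deltas, ddof=0)) if np.std(deltas) > 0 else np.inf
    return TestResult(t_obs, p, n_perm, seed, "perm_paired_t", effect_size=d)


def _welch_t(a_sum, a_sq, na, b_sum, b_sq, nb):
    ma, mb = a_sum / na, b_sum / nb
    va = (a_sq - na * ma**2) / (na - 1)
    vb = (b_sq - nb * mb**2) / (nb - 1)
    va = np.maximum(va, 0.0)
    vb = np.maximum(vb, 0.0)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        t = np.where(denom == 0, np.sign(ma - mb) * np.inf, t)
    return np.where(np.isnan(t), 0.0, t)


def perm_welch_t(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "two",
    equal_var: bool = False,
) -> TestResult:
    """Label-permutation two-sample t test (Welch by default).

    Cohen's d (pooled, ddof=0 convention) is reported as the effect size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pool = np.sort(np.concatenate([a, b]))  # order-invariant seeding
    na, nb = a.size, b.size

    def stat(x, y):
        if equal_var:
            from scipy import stats

            return float(stats.ttest_ind(x, y, equal_var=True).statistic)
        return float(
            _welch_t(x.sum(), (x**2).sum(), x.size, y.sum(), (y**2).sum(), y.size)
        )

    t_obs = stat(a, b)
    if np.isnan(t_obs):  # zero variance in both groups, equal means
        t_obs = 0.0
    rng = np.random.default_rng(seed)
    # vectorized label permutations
    order = rng.permuted(np.tile(np.arange(na + nb), (n_perm, 1)), axis=1)
    perm = pool[order]
    pa, pb = perm[:, :na], perm[:, na:]
    if equal_var:
        null = np.array([stat(row[:na], row[na:]) for row in perm])
    else:
        null = _welch_t(
            pa.sum(axis=1), (pa**2).sum(axis=1), na,
            pb.sum(axis=1), (pb**2).sum(axis=1), nb,
        )
    p = _p_value(_tail_exceed(null, t_obs, tail), n_perm)
    if np.std(pool) == 0:
        p, t_obs, d = 1.0, 0.0, 0.0
    else:
        try:
            d = cohens_d(a, b)
        except ValueError:  # degenerate groups, unequal means
            d = float(np.sign(a.mean() - b.mean()) * np.inf)
    return TestResult(float(t_obs), p, n_perm, seed, "perm_welch_t", effect_size=d)


def cohens_d(a: np.ndarray, b: np.ndarray | None = None) -> float:
    """Cohen's d.

    One-sample form: mean/SD.  Two-sample form: (mean_a - mean_b) / pooled SD,
    pooling the MLE (ddof=0) variances: sqrt((SS_a + SS_b) / (n_a + n_b)).
    """
    a = np.asarray(a, dtype=float)
    if b is None:
        sd = a.std(ddof=0)
        if sd == 0:
            raise ValueError("zero variance")
        return float(a.mean() / sd)
    b = np.asarray(b, dtype=float)
    ssa = ((a - a.mean()) ** 2).sum()
    ssb = ((b - b.mean()) ** 2).sum()
    pooled = np.sqrt((ssa + ssb) / (a.size + b.size))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero variance with unequal means")
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    """(pseudo-F, R^2) for one labelling; d2 is the squared distance matrix."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    ss_among = ss_total - ss_within
    k = groups.size
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    r2 = ss_among / ss_total
    return f, r2


def permanova(
    dm, grouping, n_perm: int = 999, seed: int = 0
) -> TestResult:
    """One-way PERMANOVA: pseudo-F with a label-permutation null and R^2.

    ``dm`` is a DistanceMatrix (or square ndarray); ``grouping`` a label per
    object in ``dm`` order.
    """
    values = np.asarray(getattr(dm, "values", dm), dtype=float)
    labels = np.asarray(list(grouping))
    n = values.shape[0]
    if labels.size != n:
        raise ValueError("grouping length must match distance matrix size")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("PERMANOVA requires >= 2 groups")
    d2 = values**2
    f_obs, r2 = _permanova_stats(d2, labels, groups)

    rng = np.random.default_rng(seed)
    # vectorized permutation null via indicator quadratic forms
    perm_idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    perm_labels = labels[perm_idx]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(n_perm)
    for g in groups:
        m = (perm_labels == g).astype(float)
        ng = m[0].sum()  # group sizes are permutation-invariant
        ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * ng)
    k = groups.size
    f_null = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    p = _p_value(int(np.sum(f_null >= f_obs - 1e-12)), n_perm)
    return TestResult(
        float(f_obs), p, n_perm, seed, "permanova", extras={"R2": float(r2)}
    )


def write_results(results: list[TestResult], path: str | Path, header: str | None = None) -> None:
    """Tidy TSV: test, statistic, effect_size, p, n_perm, seed (+R2 if any)."""
    rows = []
    for r in results:
        row = {
            "test": r.test,
            "statistic": r.statistic,
            "effect_size": "" if r.effect_size is None else r.effect_size,
            "p": r.p_value,
            "n_perm": r.n_perm,
            "seed": r.seed,
        }
        if r.extras:
            row.update(r.extras)
        rows.append(row)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
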