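"""Subject-aware ordination: robust Aitchison PCA (matrix completion over the
rCLR observed mask) and a CP-style compositional tensor factorization for
paired samples.

Both factorizations use alternating least squares restricted to observed
entries, SVD-based initialization from the zero-imputed unfolding, tolerance
1e-8 and at most 500 iterations; the observed-entry loss is checked to be
non-increasing on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beta_diversity import DistanceMatrix
from .core_io import FeatureTable, SampleMetadata, TISSUES
from .preprocess import rclr

__all__ = [
    "OrdinationResult",
    "CTFResult",
    "rpca",
    "auto_rank",
    "ctf",
    "subject_distance",
    "paired_pc_deltas",
]

_RIDGE = 1e-12


@dataclass(frozen=True)
class OrdinationResult:
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    sample_scores: np.ndarray  # samples x k
    feature_loadings: np.ndarray  # features x k
    singular_values: np.ndarray
    proportion_explained: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.sample_scores.shape[1]
        if k < 1:
            raise ValueError("at least one component required")
        pe = np.asarray(self.proportion_explained)
        if pe.min() < -1e-12 or pe.max() > 1 + 1e-12 or np.any(np.diff(pe) > 1e-12):
            raise ValueError("proportion_explained must be non-increasing within [0,1]")

    @property
    def rank(self) -> int:
        return self.sample_scores.shape[1]

    def to_txt(self, path: str | Path, header: str | None = None) -> None:
        """Plain-text ordination serialization (eigenvalue / proportion /
        score / loading blocks)."""
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("Eigvals\t" + "\t".join(repr(float(s)) for s in self.singular_values) + "\n")
            fh.write(
                "ProportionExplained\t"
                + "\t".join(repr(float(p)) for p in self.proportion_explained)
                + "\n"
            )
            fh.write(f"Site\t{len(self.sample_ids)}\t{self.rank}\n")
            for sid, row in zip(self.sample_ids, self.sample_scores):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
            fh.write(f"Species\t{len(self.feature_ids)}\t{self.rank}\n")
            for fid, row in zip(self.feature_ids, self.feature_loadings):
                fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


@dataclass(frozen=True)
class CTFResult:
    subject_ids: tuple[str, ...]
    states: tuple[str, ...]  # ("normal", "tumor")
    feature_ids: tuple[str, ...]
    subject_scores: np.ndarray  # subjects x k
    state_loadings: np.ndarray  # states x k
    feature_loadings: np.ndarray  # features x k
    sample_scores: np.ndarray  # subjects x states x k
    sample_ids: tuple[tuple[str, ...], ...]  # per (subject, state)
    extras: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return self.subject_scores.shape[1]


# ---------------------------------------------------------------------------
# masked matrix ALS


def _batched_solve(mask: np.ndarray, B: np.ndarray, Mf: np.ndarray) -> np.ndarray:
    """Per-row LS solve of  min ||m_i * (M_i - a_i B^T)||^2  for all rows."""
    k = B.shape[1]
    G = np.einsum("ij,jk,jl->ikl", mask, B, B, optimize=True)
    G += _RIDGE * np.eye(k)
    rhs = Mf @ B
    return np.linalg.solve(G, rhs[..., None])[..., 0]


def _masked_als(
    M: np.ndarray,
    mask: np.ndarray,
    rank: int,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    maskf = mask.astype(float)
    Mf = np.where(mask, M, 0.0)
    U0, s0, Vt0 = np.linalg.svd(Mf, full_matrices=False)
    A = U0[:, :rank] * s0[:rank]
    B = Vt0[:rank].T
    losses: list[float] = []
    converged = False
    for _ in range(max_iter):
        A = _batched_solve(maskf, B, Mf)
        B = _batched_solve(maskf.T, A, Mf.T)
        resid = np.where(mask, M - A @ B.T, 0.0)
        loss = float((resid**2).sum())
        if losses and loss > losses[-1] + 1e-9 * max(1.0, losses[-1]):
            raise AssertionError("ALS loss increased")  # should be impossible
        if losses and abs(losses[-1] - loss) <= tol * max(1.0, losses[-1]):
            losses.append(loss)
            converged = True
            break
        losses.append(loss)
    return A, B, losses, converged


def _orient(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip components so each one's largest-magnitude loading is positive."""
    for r in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, r])))
        if loadings[j, r] < 0:
            loadings[:, r] *= -1
            scores[:, r] *= -1
    return scores, loadings


def rpca(
    table: FeatureTable,
    rank: int | str = "auto",
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    candidate_ranks: tuple[int, ...] = (2, 3, 4, 5),
) -> OrdinationResult:
    """Robust Aitchison PCA: rCLR transform then masked low-rank factorization.

    With ``rank="auto"`` the rank is chosen by :func:`auto_rank` over
    ``candidate_ranks``.  Components are ordered by singular value and oriented
    so each component's largest-magnitude feature loading is positive.
    """
    if len(table.sample_ids) < 3:
        raise ValueError("rpca requires >= 3 samples")
    if rank == "auto":
        rank = auto_rank(table, candidate_ranks, seed=seed)
    rank = int(rank)
    if rank >= min(table.shape):
        raise ValueError(f"rank {rank} must be < min(table dims) {min(table.shape)}")
    tm = rclr(table)
    mask = ~np.isnan(tm.values)
    A, B, losses, converged = _masked_als(tm.values, mask, rank, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(
            f"rpca ALS did not converge in {max_iter} iterations; returning best iterate",
            stacklevel=2,
        )
    U, s, Vt = np.linalg.svd(A @ B.T, full_matrices=False)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    scores = U * s
    loadings = Vt.T.copy()
    scores, loadings = _orient(scores, loadings)
    total = float((s**2).sum())
    prop = s**2 / total if total > 0 else np.zeros(rank)
    return OrdinationResult(
        sample_ids=tm.sample_ids,
        feature_ids=tm.feature_ids,
        sample_scores=scores,
        feature_loadings=loadings,
        singular_values=s,
        proportion_explained=prop,
        extras={"losses": losses, "converged": converged,
                "reconstruction_residual": losses[-1]},
    )


def auto_rank(
    table: FeatureTable,
    candidate_ranks: tuple[int, ...] = (2, 3, 4, 5),
    seed: int = 0,
    n_repeats: int = 5,
    holdout: float = 0.10,
    max_iter: int = 100,
) -> int:
    """Pick the candidate rank with the lowest held-out reconstruction error.

    A fixed random 10% of observed rCLR entries is masked out per repeat
    (``n_repeats`` repeats, seed-controlled); CV fits use a reduced iteration
    cap purely for speed.
    """
    candidates = sorted(set(int(r) for r in candidate_ranks))
    if not candidates:
        raise ValueError("empty candidate rank set")
    hi = min(table.shape) - 1
    bad = [r for r in candidates if not (2 <= r <= hi)]
    if bad:
        raise ValueError(f"candidate rank(s) {bad} outside 2..{hi}")
    tm = rclr(table)
    obs = np.argwhere(~np.isnan(tm.values))
    rng = np.random.default_rng(seed)
    errors = {r: [] for r in candidates}
    for _ in range(n_repeats):
        held = obs[rng.random(len(obs)) < holdout]
        train_mask = ~np.isnan(tm.values)
        train_mask[held[:, 0], held[:, 1]] = False
        if train_mask.sum(axis=1).min() < max(candidates):
            continue  # degenerate split; skip repeat
        for r in candidates:
            A, B, _, _ = _masked_als(tm.values, train_mask, r, max_iter=max_iter)
            fit = A @ B.T
            err = tm.values[held[:, 0], held[:, 1]] - fit[held[:, 0], held[:, 1]]
            errors[r].append(float((err**2).mean()))
    means = {r: float(np.mean(v)) for r, v in errors.items() if v}
    if not means:
        raise ValueError("auto_rank: no usable held-out splits")
    return min(means, key=lambda r: (means[r], r))


# ---------------------------------------------------------------------------
# CTF


def _tensor_from_bundle(
    table: FeatureTable, metadata: SampleMetadata
) -> tuple[np.ndarray, list[str], list[list[str]]]:
    """Subject x state x feature tensor of rCLR values (NaN where zero)."""
    tm = rclr(table)
    frame = metadata.frame
    subjects = list(metadata.paired_subjects())
    if set(frame["subject_id"]) - set(subjects):
        raise ValueError(
            "ctf requires fully paired subjects; unpaired: "
            f"{sorted(set(frame['subject_id']) - set(subjects))}"
        )
    index = {s: i for i, s in enumerate(tm.sample_ids)}
    T = np.full((len(subjects), len(TISSUES), len(tm.feature_ids)), np.nan)
    sample_ids: list[list[str]] = []
    for i, subj in enumerate(subjects):
        per_state = []
        for j, tissue in enumerate(TISSUES):
            sid = metadata.sample_for(subj, tissue)
            T[i, j] = tm.values[index[sid]]
            per_state.append(sid)
        sample_ids.append(per_state)
    return T, subjects, sample_ids


def _cp_als(
    T: np.ndarray,
    mask: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Masked CP-ALS on a 3-way tensor; returns (U, W, V, losses, converged)."""
    n, s_states, p = T.shape
    maskf = mask.astype(float)
    Tf = np.where(mask, T, 0.0)
    rng = np.random.default_rng(seed)
    # SVD init on the subject-mode unfolding; feature factors likewise.
    U = np.linalg.svd(Tf.reshape(n, -1), full_matrices=False)[0][:, :k].copy()
    V = np.linalg.svd(Tf.transpose(2, 0, 1).reshape(p, -1), full_matrices=False)[0][:, :k].copy()
    W = np.ones((s_states, k)) + 0.01 * rng.standard_normal((s_states, k))

    eye = _RIDGE * np.eye(k)
    losses: list[float] = []
    converged = False
    for _ in range(max_iter):
        C = W[:, None, :] * V[None, :, :]  # states x features x k
        G = np.einsum("isf,sfk,sfl->ikl", maskf, C, C, optimize=True) + eye
        rhs = np.einsum("isf,sfk->ik", Tf, C, optimize=True)
        U = np.linalg.solve(G, rhs[..., None])[..., 0]

        D = U[:, None, :] * V[None, :, :]  # subjects x features x k
        G = np.einsum("isf,ifk,ifl->skl", maskf, D, D, optimize=True) + eye
        rhs = np.einsum("isf,ifk->sk", Tf, D, optimize=True)
        W = np.linalg.solve(G, rhs[..., None])[..., 0]

        E = U[:, None, :] * W[None, :, :]  # subjects x states x k
        G = np.einsum("isf,isk,isl->fkl", maskf, E, E, optimize=True) + eye
        rhs = np.einsum("isf,isk->fk", Tf, E, optimize=True)
        V = np.linalg.solve(G, rhs[..., None])[..., 0]

        fit = np.einsum("ik,sk,fk->isf", U, W, V, optimize=True)
        loss = float(((Tf - maskf * fit) ** 2).sum())
        if losses and loss > losses[-1] + 1e-9 * max(1.0, losses[-1]):
            raise AssertionError("CTF ALS loss increased")
        if losses and abs(losses[-1] - loss) <= tol * max(1.0, losses[-1]):
            losses.append(loss)
            converged = True
            break
        losses.append(loss)
    return U, W, V, losses, converged


def ctf(
    table: FeatureTable,
    metadata: SampleMetadata,
    k: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    center_states: bool = False,
) -> CTFResult:
    """CP-style factorization of the subject x state x feature rCLR tensor.

    Missing (zero-count) cells are excluded from the least-squares objective.
    Per-(subject, state) sample scores are the state-loading element-wise
    scaled subject scores.  Deterministic under ``seed``.
    """
    T, subjects, sample_ids = _tensor_from_bundle(table, metadata)
    if center_states:
        for j in range(T.shape[1]):
            T[:, j] -= np.nanmean(T[:, j], axis=0, keepdims=True)
    mask = ~np.isnan(T)
    n, s_states, p = T.shape
    if k >= min(n, p):
        raise ValueError(f"k={k} too large for tensor dims {(n, s_states, p)}")
    U, W, V, losses, converged = _cp_als(T, mask, k, seed=seed, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(
            f"ctf ALS did not converge in {max_iter} iterations; returning best iterate",
            stacklevel=2,
        )

    # normalize W and V columns to unit norm, absorbing magnitude into U
    for r in range(k):
        nw = np.linalg.norm(W[:, r])
        nv = np.linalg.norm(V[:, r])
        if nw > 0 and nv > 0:
            U[:, r] *= nw * nv
            W[:, r] /= nw
            V[:, r] /= nv
    order = np.argsort(-np.linalg.norm(U, axis=0))
    U, W, V = U[:, order], W[:, order], V[:, order]
    # orient: largest-|feature loading| positive; compensate in U to keep the product
    for r in range(k):
        j = int(np.argmax(np.abs(V[:, r])))
        if V[j, r] < 0:
            V[:, r] *= -1
            U[:, r] *= -1

    sample_scores = U[:, None, :] * W[None, :, :]
    return CTFResult(
        subject_ids=tuple(subjects),
        states=TISSUES,
        feature_ids=tuple(table.feature_ids),
        subject_scores=U,
        state_loadings=W,
        feature_loadings=V,
        sample_scores=sample_scores,
        sample_ids=tuple(tuple(s) for s in sample_ids),
        extras={"losses": losses, "converged": converged, "seed": seed, "k": k},
    )


def subject_distance(result: CTFResult) -> DistanceMatrix:
    """Euclidean distances between CTF subject coordinates."""
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        result.subject_ids,
        squareform(pdist(result.subject_scores, metric="euclidean")),
        "ctf_subject_euclidean",
    )


def paired_pc_deltas(result: CTFResult, metadata: SampleMetadata | None = None) -> dict[str, np.ndarray]:
    """Per-subject ΔPC = tumor sample score − normal sample score."""
    i_normal = result.states.index("normal")
    i_tumor = result.states.index("tumor")
    deltas = result.sample_scores[:, i_tumor, :] - result.sample_scores[:, i_normal, :]
    return {subj: deltas[i] for i, subj in enumerate(result.subject_ids)}
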