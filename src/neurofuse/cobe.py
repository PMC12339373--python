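"""Common Orthogonal Basis Extraction (COBE) and residual-based augmentation.

COBE is a group component-analysis method: given multiple data blocks
(here, one block per subject whose columns are that subject's ROI
connectivity profiles), it extracts an orthonormal basis of directions
that lie close to every block's column space — the group-shared
connectivity structure. Projecting each block onto the orthogonal
complement of that basis leaves the "individualized" component, which is
used as augmented training data carrying the source subject's outcome
label.

The extraction is greedy with deflation: each candidate direction is
alternately projected onto every block's column space and replaced by
the normalized mean projection until convergence; a direction is
accepted as common while its mean per-block residual (the squared norm
of its part outside a block's span) stays below a tolerance, after which
it is deflated out of every block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiBlockData",
    "CommonBasis",
    "AugmentedSample",
    "extract_common_basis",
    "remove_common",
    "augment_dataset",
    "blocks_from_matrices",
]


@dataclass
class MultiBlockData:
    """Multi-block dataset: one D×K_s matrix per subject, shared row dim D."""

    blocks: list[np.ndarray]
    subject_ids: list[str]
    modality: str = "fmri"

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("need at least 2 blocks")
        if len(self.blocks) != len(self.subject_ids):
            raise ValueError("one subject id per block required")
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        d = self.blocks[0].shape[0]
        if any(b.shape[0] != d for b in self.blocks):
            raise ValueError("all blocks must share the row dimension")

    @property
    def dim(self) -> int:
        return self.blocks[0].shape[0]


@dataclass
class CommonBasis:
    """Orthonormal common basis with per-block coefficients and fit errors."""

    basis: np.ndarray                      # D×C, orthonormal columns
    coefficients: list[np.ndarray]         # per block: C×K_s
    residual_fit: np.ndarray               # per component: mean per-block residual

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


@dataclass
class AugmentedSample:
    """An individualized (common-structure-removed) connectivity sample."""

    source_subject_id: str
    values: np.ndarray                     # N×N symmetric residual matrix
    label: float
    augmentation_tag: int                  # number of common components removed

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("augmented sample must be symmetric")
        self.values = v


def blocks_from_matrices(matrices, subject_ids, modality: str = "fmri") -> MultiBlockData:
    """Build blocks from normalized N×N connectivity matrices (columns = ROI profiles)."""
    return MultiBlockData([np.asarray(m, dtype=float) for m in matrices], list(subject_ids), modality)


def _orthonormal_block_bases(data: MultiBlockData, block_rank: int | None) -> list[np.ndarray]:
    bases = []
    for b, sid in zip(data.blocks, data.subject_ids):
        if block_rank is None:
            q, r = np.linalg.qr(b)
            diag = np.abs(np.diag(r))
            rank = int(np.sum(diag > 1e-10 * max(1.0, diag.max(initial=0.0))))
            if rank < b.shape[1]:
                raise ValueError(f"rank-deficient block for subject {sid}")
            bases.append(q[:, : b.shape[1]])
        else:
            # restrict to the block's dominant principal directions; for
            # full-rank square blocks (one N×N connectivity per subject)
            # the untruncated column space is all of R^N and "common"
            # would be vacuous
            u, s, _ = np.linalg.svd(b, full_matrices=False)
            if s[min(block_rank, len(s)) - 1] <= 1e-12 * max(1.0, s[0]):
                raise ValueError(f"rank-deficient block for subject {sid}")
            bases.append(u[:, :block_rank])
    return bases


def extract_common_basis(
    data: MultiBlockData,
    c_max: int,
    tol: float = 0.01,
    *,
    max_iter: int = 1000,
    conv_tol: float = 1e-6,
    seed: int = 0,
    block_rank: int | None = None,
) -> CommonBasis:
    """Greedy COBE extraction of up to ``c_max`` common components.

    A component is accepted while the mean per-block residual
    ``mean_s ||w - P_s w||^2`` (P_s = projector onto block s's column
    space) is at most ``tol``. Accepted components are deflated out of
    every block so the returned basis is orthonormal.
    """
    if c_max >= data.dim:
        raise ValueError("c_max must be smaller than the block row dimension")
    if tol <= 0:
        raise ValueError("tol must be positive")
    bases = _orthonormal_block_bases(data, block_rank)
    d = data.dim
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    fits: list[float] = []

    for _ in range(c_max):
        # initialize from the dominant direction of the stacked block bases
        stacked = np.hstack(bases)
        u, s, _ = np.linalg.svd(stacked, full_matrices=False)
        w = u[:, 0]
        if not np.all(np.isfinite(w)) or np.linalg.norm(w) == 0:
            w = rng.normal(size=d)
            w /= np.linalg.norm(w)
        for _ in range(max_iter):
            proj = np.zeros(d)
            for q in bases:
                proj += q @ (q.T @ w)
            proj /= len(bases)
            nrm = np.linalg.norm(proj)
            if nrm == 0:
                break
            w_new = proj / nrm
            # sign-align to avoid oscillation between w and -w
            if w_new @ w < 0:
                w_new = -w_new
            if np.linalg.norm(w_new - w) < conv_tol:
                w = w_new
                break
            w = w_new
        fit = float(np.mean([np.sum((w - q @ (q.T @ w)) ** 2) for q in bases]))
        if fit > tol:
            break
        accepted.append(w)
        fits.append(fit)
        # deflate: remove w from every block basis
        new_bases = []
        for q in bases:
            resid = q - np.outer(w, w @ q)
            qq, rr = np.linalg.qr(resid)
            keep = np.abs(np.diag(rr)) > 1e-10
            new_bases.append(qq[:, keep])
        bases = new_bases
        if any(q.shape[1] == 0 for q in bases):
            break

    basis = np.column_stack(accepted) if accepted else np.zeros((d, 0))
    coeffs = [basis.T @ b for b in data.blocks]
    return CommonBasis(basis, coeffs, np.asarray(fits))


def remove_common(data: MultiBlockData, basis: CommonBasis) -> list[np.ndarray]:
    """Residual blocks after projecting out the common basis.

    Returns ``(I - B Bᵀ)·block`` for each block. For square blocks built
    from connectivity matrices, callers re-symmetrize via
    ``(M + Mᵀ)/2`` (see :func:`augment_dataset`).
    """
    b = basis.basis
    if b.shape[0] != data.dim:
        raise ValueError("basis dimension does not match blocks")
    if b.shape[1] == 0:
        return [blk.copy() for blk in data.blocks]
    return [blk - b @ (b.T @ blk) for blk in data.blocks]


def augment_dataset(
    matrices: list[np.ndarray],
    subject_ids: list[str],
    labels: np.ndarray,
    c_schedule: list[int],
    *,
    modality: str = "fmri",
    tol: float = 10.0,
) -> list[AugmentedSample]:
    """One residual copy of every training subject per entry of ``c_schedule``.

    For each C in the schedule, the top-C common components are removed
    from every subject's connectivity and the residual (re-symmetrized)
    becomes a new training sample with the source subject's label. The
    augmentation rate is ``len(c_schedule)``: output size is
    rate × n_train new samples. Must only ever be applied to training
    folds. ``tol`` is deliberately loose here: the schedule, not the fit
    threshold, decides how many components are removed.
    """
    data = blocks_from_matrices(matrices, subject_ids, modality)
    d = data.dim
    if any(c >= d for c in c_schedule):
        raise ValueError(f"c_schedule entries must be < block dimension {d}")
    if not c_schedule:
        return []
    c_max = max(c_schedule)
    basis = extract_common_basis(data, c_max, tol=tol, block_rank=max(2, d // 4))
    out: list[AugmentedSample] = []
    for c in c_schedule:
        sub = CommonBasis(basis.basis[:, :c], [], basis.residual_fit[:c])
        residuals = remove_common(data, sub)
        for sid, label, r in zip(subject_ids, labels, residuals):
            out.append(AugmentedSample(sid, (r + r.T) / 2.0, float(label), c))
    return out
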