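"""Cross-condition and bilateral comparison of motor-module structure.

Module weight vectors are compared with Pearson's linear correlation;
module sets are put in correspondence with an optimal one-to-one assignment
maximizing total r.  Fixed-module reconstruction solves, for a reference
weight matrix W_ref and a target activation matrix E,

    min ||W_ref @ C - E||_F    subject to  C >= 0,

which decouples into an independent nonnegative least-squares problem per
gait-cycle grid point; reconstruction quality is summarized by VAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .extraction import compute_vaf


@dataclass
class ModulePairing:
    """One-to-one correspondence between two module sets.

    ``pairs`` lists (reference index, target index) in reference order for
    the min(n_ref, n_target) matched modules; ``r_values`` the Pearson r of
    each pair.  Indices of unmatched modules (when counts differ) are
    reported separately.
    """

    pairs: list[tuple[int, int]]
    r_values: np.ndarray
    unmatched_ref: list[int]
    unmatched_target: list[int]

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))


@dataclass
class ReconstructionResult:
    """Nonnegative reconstruction of a target with fixed reference modules."""

    C_reconstruct: np.ndarray
    vaf: float

    @property
    def per_module_C(self) -> np.ndarray:
        # Rows are already aligned to the reference module order because
        # W_ref's columns define them.
        return self.C_reconstruct


def pearson_similarity(w_a: np.ndarray, w_b: np.ndarray) -> float:
    """Pearson correlation between two module weight vectors.

    Scale- and offset-invariant, so no weight normalization is required.
    Raises for constant vectors (correlation undefined) rather than
    propagating NaN.
    """
    w_a = np.asarray(w_a, dtype=float).ravel()
    w_b = np.asarray(w_b, dtype=float).ravel()
    if w_a.shape != w_b.shape:
        raise ValueError(f"length mismatch: {w_a.size} vs {w_b.size}")
    if w_a.size < 3:
        raise ValueError(f"need at least 3 entries, got {w_a.size}")
    sd_a = np.std(w_a)
    sd_b = np.std(w_b)
    if sd_a == 0 or sd_b == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r = float(np.dot(w_a - w_a.mean(), w_b - w_b.mean()) / (w_a.size * sd_a * sd_b))
    return float(np.clip(r, -1.0, 1.0))


def similarity_matrix(W_ref: np.ndarray, W_target: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between columns of two weight matrices."""
    W_ref = np.asarray(W_ref, dtype=float)
    W_target = np.asarray(W_target, dtype=float)
    if W_ref.shape[0] != W_target.shape[0]:
        raise ValueError(
            f"muscle dimension mismatch: {W_ref.shape[0]} vs {W_target.shape[0]}"
        )
    R = np.empty((W_ref.shape[1], W_target.shape[1]))
    for i in range(W_ref.shape[1]):
        for j in range(W_target.shape[1]):
            R[i, j] = pearson_similarity(W_ref[:, i], W_target[:, j])
    return R


def match_modules(W_ref: np.ndarray, W_target: np.ndarray) -> ModulePairing:
    """Optimally pair target modules with reference modules.

    Uses a linear-sum assignment maximizing the total Pearson r over all
    one-to-one pairings; with unequal module counts the pairing covers
    min(n_ref, n_target) modules and the leftovers are reported unmatched.
    """
    R = similarity_matrix(W_ref, W_target)
    row_ind, col_ind = optimize.linear_sum_assignment(-R)
    pairs = sorted(zip(row_ind.tolist(), col_ind.tolist()))
    r_values = np.array([R[i, j] for i, j in pairs])
    unmatched_ref = sorted(set(range(R.shape[0])) - {i for i, _ in pairs})
    unmatched_target = sorted(set(range(R.shape[1])) - {j for _, j in pairs})
    return ModulePairing(
        pairs=pairs,
        r_values=r_values,
        unmatched_ref=unmatched_ref,
        unmatched_target=unmatched_target,
    )


def reconstruct_with_fixed_modules(
    W_ref: np.ndarray, E_target: np.ndarray
) -> ReconstructionResult:
    """Explain a target's muscle activity with fixed reference modules.

    Solves min ||W_ref @ C - E_target||_F s.t. C >= 0 exactly, one NNLS per
    time column (the columns decouple in the Frobenius objective), and
    evaluates the reconstruction with VAF.
    """
    W_ref = np.asarray(W_ref, dtype=float)
    E_target = np.asarray(E_target, dtype=float)
    if W_ref.ndim != 2 or E_target.ndim != 2:
        raise ValueError("W_ref and E_target must be 2-D")
    if W_ref.shape[0] != E_target.shape[0]:
        raise ValueError(
            f"muscle dimension mismatch: W_ref has {W_ref.shape[0]} rows, "
            f"E_target has {E_target.shape[0]}"
        )
    n, T = W_ref.shape[1], E_target.shape[1]
    C = np.empty((n, T))
    for t in range(T):
        C[:, t], _ = optimize.nnls(W_ref, E_target[:, t])
    return ReconstructionResult(
        C_reconstruct=C, vaf=compute_vaf(E_target, W_ref @ C)
    )


@dataclass
class BilateralSimilarity:
    """Summary of left-vs-right module-structure similarity."""

    mean_r: float
    min_r: float
    max_r: float
    pairing: ModulePairing


def bilateral_similarity(
    W_left: np.ndarray, W_right: np.ndarray
) -> BilateralSimilarity:
    """Match left- and right-leg modules and summarize their Pearson r.

    Both matrices must use the same (mirrored) muscle ordering.  Returns
    mean, min and max r over the matched pairs, plus the pairing itself.
    """
    pairing = match_modules(W_left, W_right)
    r = pairing.r_values
    return BilateralSimilarity(
        mean_r=float(r.mean()),
        min_r=float(r.min()),
        max_r=float(r.max()),
        pairing=pairing,
    )


__all__ = [
    "ModulePairing",
    "ReconstructionResult",
    "BilateralSimilarity",
    "pearson_similarity",
    "similarity_matrix",
    "match_modules",
    "reconstruct_with_fixed_modules",
    "bilateral_similarity",
]
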