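"""Motor-module extraction by NMF and VAF-based module-number selection.

Muscle activity E (muscles x grid points) is factorized as E ~ W @ C with
W, C >= 0: W's columns are motor modules (groups of co-active muscles) and
C's rows their activation patterns over the gait cycle.  Factorization uses
the classic multiplicative-update rules minimizing the squared Frobenius
reconstruction error, restarted from several random initializations with
the best (highest-VAF) replicate retained.

Goodness of fit is the variability accounted for,

    VAF = 1 - sum((E - W@C)**2) / sum(E**2),

and the module number for a data set is the smallest n whose
best-of-replicates VAF strictly exceeds a threshold (0.95 by default, with
0.90 as a sensitivity setting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass
class ExtractionResult:
    """Best-replicate NMF factorization of one activation matrix.

    W columns are rescaled to unit maximum with compensating row scaling of
    C, leaving the reconstruction W @ C unchanged.  ``objective_history``
    holds the squared-Frobenius objective per iteration of the winning
    replicate (nonincreasing).
    """

    W: np.ndarray
    C: np.ndarray
    vaf: float
    n_modules: int
    replicate_seeds: list[int]
    residual: np.ndarray
    n_iter: int
    objective_history: np.ndarray

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class VafCurve:
    """Best-of-replicates VAF as a function of candidate module number."""

    n: np.ndarray
    vaf_at_n: np.ndarray
    threshold_reached: bool = True

    def smallest_n_above(self, threshold: float) -> int | None:
        """Smallest n with VAF strictly above ``threshold``; None if never."""
        above = np.nonzero(self.vaf_at_n > threshold)[0]
        if above.size == 0:
            return None
        return int(self.n[above[0]])


def compute_vaf(E: np.ndarray, E_hat: np.ndarray) -> float:
    """Variability accounted for: 1 - sum((E - E_hat)^2) / sum(E^2).

    Equals 1 for a perfect reconstruction, 0 when E_hat is all zeros, and
    can be negative for reconstructions worse than predicting zero.
    """
    E = np.asarray(E, dtype=float)
    E_hat = np.asarray(E_hat, dtype=float)
    if E.shape != E_hat.shape:
        raise ValueError(f"shape mismatch: {E.shape} vs {E_hat.shape}")
    denom = float(np.sum(E**2))
    if denom == 0.0:
        raise ValueError("VAF undefined for an all-zero activation matrix")
    return 1.0 - float(np.sum((E - E_hat) ** 2)) / denom


def _mu_nmf(
    E: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """One multiplicative-update run from a random nonnegative start."""
    m, T = E.shape
    scale = np.sqrt(E.mean() / max(n, 1)) + _EPS
    W = rng.uniform(0.0, 1.0, size=(m, n)) * scale + _EPS
    C = rng.uniform(0.0, 1.0, size=(n, T)) * scale + _EPS

    history = np.empty(max_iter)
    prev = np.sum((E - W @ C) ** 2)
    n_iter = 0
    for it in range(max_iter):
        # C <- C * (W^T E) / (W^T W C)
        C *= (W.T @ E) / (W.T @ W @ C + _EPS)
        # W <- W * (E C^T) / (W C C^T)
        W *= (E @ C.T) / (W @ (C @ C.T) + _EPS)
        obj = np.sum((E - W @ C) ** 2)
        history[it] = obj
        n_iter = it + 1
        if prev - obj < tol * max(prev, _EPS):
            break
        prev = obj
    return W, C, n_iter, history[:n_iter]


def _normalize_columns(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale W columns to unit max, compensating in C; W@C unchanged."""
    colmax = W.max(axis=0)
    nz = colmax > 0
    W = W.copy()
    C = C.copy()
    W[:, nz] /= colmax[nz]
    C[nz, :] *= colmax[nz, None]
    return W, C


def nmf_decompose(
    E: np.ndarray,
    n: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    replicates: int = 20,
) -> ExtractionResult:
    """Factor E >= 0 into n motor modules, keeping the best of ``replicates``.

    Each replicate starts from seeded uniform-random nonnegative matrices
    and iterates the multiplicative updates until the relative objective
    change drops below ``tol`` or ``max_iter`` is reached.  The replicate
    with the highest VAF wins; its W is rescaled to unit-max columns.

    Muscle rows that are identically zero in E are zero in W by convention.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError(f"E must be 2-D, got shape {E.shape}")
    if np.any(E < 0):
        raise ValueError("E must be elementwise nonnegative")
    m, T = E.shape
    if not 1 <= n <= min(m, T):
        raise ValueError(f"n must be in [1, {min(m, T)}], got {n}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    best: tuple[float, np.ndarray, np.ndarray, int, np.ndarray] | None = None
    seeds = list(range(replicates))
    for rep in seeds:
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        W, C, n_iter, history = _mu_nmf(E, n, rng, max_iter, tol)
        vaf = compute_vaf(E, W @ C)
        if best is None or vaf > best[0]:
            best = (vaf, W, C, n_iter, history)
    assert best is not None
    vaf, W, C, n_iter, history = best

    zero_rows = E.sum(axis=1) == 0
    W[zero_rows, :] = 0.0
    W, C = _normalize_columns(W, C)
    residual = E - W @ C
    return ExtractionResult(
        W=W,
        C=C,
        vaf=compute_vaf(E, W @ C),
        n_modules=n,
        replicate_seeds=seeds,
        residual=residual,
        n_iter=n_iter,
        objective_history=history,
    )


def vaf_curve(
    E: np.ndarray,
    n_max: int,
    replicates: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> VafCurve:
    """Best-of-replicates VAF for every candidate module number 1..n_max."""
    ns = np.arange(1, n_max + 1)
    vafs = np.empty(len(ns))
    for i, n in enumerate(ns):
        res = nmf_decompose(
            E, int(n), seed=seed, max_iter=max_iter, tol=tol, replicates=replicates
        )
        vafs[i] = res.vaf
    return VafCurve(n=ns, vaf_at_n=vafs)


def select_module_number(
    E: np.ndarray,
    threshold: float = 0.95,
    n_max: int = 10,
    replicates: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[int, VafCurve]:
    """Smallest module number whose best-replicate VAF exceeds ``threshold``.

    Returns the selected n and the full VAF curve over 1..n_max.  If the
    threshold is never reached the curve is flagged, a warning is issued,
    and n_max is returned.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    curve = vaf_curve(
        E, n_max, replicates=replicates, seed=seed, max_iter=max_iter, tol=tol
    )
    n_sel = curve.smallest_n_above(threshold)
    if n_sel is None:
        curve.threshold_reached = False
        warnings.warn(
            f"VAF threshold {threshold:.2f} not reached by n_max={n_max} "
            f"(best VAF {curve.vaf_at_n[-1]:.4f}); returning n_max",
            RuntimeWarning,
            stacklevel=2,
        )
        return n_max, curve
    return n_sel, curve


__all__ = [
    "ExtractionResult",
    "VafCurve",
    "compute_vaf",
    "nmf_decompose",
    "vaf_curve",
    "select_module_number",
]
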