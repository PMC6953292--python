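"""Sparse outer-weight estimation.

The penalized "Mode B" outer update solves an elastic-net criterion

    min_w  w' [(X'X + lam2 I) / (1 + lam2)] w  -  2 zt' X w  +  lam1 ||w||_1

where ``zt`` is the re-estimated latent variable of the block.  In the limit
``lam2 -> inf`` the quadratic form collapses to ``w'w`` and the minimizer is
available per coordinate in closed form — Univariate Soft Thresholding (UST):

    w_j = sign(c_j) * max(|c_j| - lam1 / 2, 0),   c_j = x_j' zt.

UST is the workhorse for genuinely high-dimensional blocks where a full
elastic-net coordinate descent over a cross-validation grid is too expensive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

__all__ = [
    "PenaltySpec",
    "EmptyModelError",
    "soft_threshold",
    "ust_update",
    "enet_update",
    "enet_objective",
    "lambda_for_cardinality",
]


class EmptyModelError(ValueError):
    """Raised when a penalty shrinks every coefficient of a block to zero."""


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty settings for the Mode B (multivariate) outer updates.

    kind
        ``"ust"`` (univariate soft thresholding), ``"enet"`` (elastic net by
        coordinate descent) or ``"cardinality"`` (UST with ``lambda1`` chosen
        per block so that ``k_target`` variables survive).
    lambda1
        LASSO penalty; a scalar shared by all penalized blocks or a mapping
        ``block name -> value``.
    lambda2
        Ridge penalty (elastic net only; ignored by UST).
    k_target
        Per-block retained-variable count (cardinality only); a positive int
        shared by all penalized blocks or a mapping ``block name -> k``.
    """

    kind: str = "ust"
    lambda1: Union[float, Mapping[str, float]] = 0.0
    lambda2: float = 0.0
    k_target: Optional[Union[int, Mapping[str, int]]] = None

    def __post_init__(self):
        if self.kind not in ("ust", "enet", "cardinality"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        if self.kind == "cardinality" and self.k_target is None:
            raise ValueError("cardinality penalty requires k_target")

    def lambda1_for(self, block_name: str) -> float:
        lam = self.lambda1
        if isinstance(lam, Mapping):
            lam = lam[block_name]
        if lam < 0:
            raise ValueError("lambda1 must be nonnegative")
        return float(lam)

    def k_for(self, block_name: str) -> int:
        k = self.k_target
        if isinstance(k, Mapping):
            k = k[block_name]
        return int(k)


def soft_threshold(c: np.ndarray, t: float) -> np.ndarray:
    return np.sign(c) * np.maximum(np.abs(c) - t, 0.0)


def ust_update(X: np.ndarray, zt: np.ndarray, lambda1: float) -> np.ndarray:
    """Closed-form elastic-net weights in the ``lambda2 -> inf`` limit.

    Parameters are the standardized block matrix, the (unnormalized)
    re-estimated latent variable and the LASSO penalty.  Raises
    :class:`EmptyModelError` if every coordinate is thresholded away.
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    c = X.T @ zt
    w = soft_threshold(c, lambda1 / 2.0)
    if not np.any(w):
        raise EmptyModelError(
            f"lambda1={lambda1:.6g} too large: empty model (all weights zero)"
        )
    return w


def enet_objective(X, zt, w, lambda1, lambda2) -> float:
    """Value of the penalized criterion minimized by :func:`enet_update`."""
    A = (X.T @ X + lambda2 * np.eye(X.shape[1])) / (1.0 + lambda2)
    return float(w @ A @ w - 2.0 * (zt @ X @ w) + lambda1 * np.abs(w).sum())


def enet_update(
    X: np.ndarray,
    zt: np.ndarray,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Elastic-net outer weights by cyclic coordinate descent.

    With ``lambda1 = 0`` the criterion is a positive (semi-)definite quadratic
    and is solved exactly by the normal equations instead; in that case
    ``lambda2 = 0`` on a ``p > n`` block is refused (singular system — the
    situation penalization exists to avoid).
    """
    n, p = X.shape
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    A = (X.T @ X + lambda2 * np.eye(p)) / (1.0 + lambda2)
    c = X.T @ zt
    if lambda1 == 0:
        if lambda2 == 0 and p > n:
            raise np.linalg.LinAlgError(
                f"unpenalized multivariate update with p={p} > n={n} is singular; "
                "use lambda1 > 0 and/or lambda2 > 0"
            )
        return np.linalg.solve(A, c)
    diag = np.diag(A).copy()
    w = np.zeros(p)
    half = lambda1 / 2.0
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            resid = c[j] - A[j] @ w + diag[j] * w[j]
            new = np.sign(resid) * max(abs(resid) - half, 0.0) / diag[j]
            delta = max(delta, abs(new - w[j]))
            w[j] = new
        if delta < tol:
            break
    if not np.any(w):
        raise EmptyModelError(
            f"lambda1={lambda1:.6g} too large: empty model (all weights zero)"
        )
    return w


def lambda_for_cardinality(X: np.ndarray, zt: np.ndarray, k: int) -> float:
    """LASSO penalty that makes the UST update keep exactly ``k`` variables.

    Returns a ``lambda1`` positioned strictly between twice the k-th and
    (k+1)-th largest ``|x_j' zt|``.  When the k-th value is tied with the
    next one, all tied variables are kept — the realized cardinality may
    exceed ``k`` (deterministic, never an arbitrary drop) and a warning is
    issued.  ``k = p`` returns 0 (no selection).
    """
    c = np.abs(X.T @ zt)
    p = c.size
    if not 1 <= k <= p:
        raise ValueError(f"k_target must be in [1, {p}], got {k}")
    if k == p:
        return 0.0
    a = np.sort(c)[::-1]
    kept = a[k - 1]
    if a[k] == kept:
        warnings.warn(
            f"tie at the cardinality boundary (|c|={kept:.6g}); keeping all tied "
            "variables, realized cardinality will exceed the target",
            stacklevel=2,
        )
        smaller = a[a < kept]
        nxt = smaller[0] if smaller.size else 0.0
    else:
        nxt = a[k]
    return float(kept + nxt)  # threshold lambda1/2 = (kept + next)/2
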