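"""The iterative msPLS estimation loop.

Each block q gets a latent variable (LV) ``zeta_q = X_q w_q`` normalized to
unit sample variance.  One iteration runs:

a. compute every LV from the current outer weights;
b. estimate the inner model Theta — ordinary multiple regression of each LV
   on its column-bound explanatory LVs, then, for every block that has
   responses, overwrite the incoming coefficients with the plain correlations
   between its LV and each response LV (the symmetric-pair rule);
c. re-estimate the LVs as ``Z~ = Z Theta`` (not re-normalized);
d. update the outer weights: per-variable regression on the re-estimated LV
   ("Mode A") for blocks without responses, penalized multivariate regression
   ("Mode B", see :mod:`mspls.penalties`) for blocks with responses;
e. convergence: CRT = sum_q ||w_q_new - w_q_old||^2 on unit-norm,
   sign-aligned weights, stop when CRT < gamma.

Weights are rescaled to unit Euclidean norm and sign-aligned (largest
absolute entry positive) after every update so CRT measures genuine change
rather than scale drift or sign flips; LV signs follow their weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .data_model import ConnectivityMatrix, MultiBlockDataset
from .penalties import PenaltySpec, enet_update, lambda_for_cardinality, ust_update

__all__ = [
    "MsplsFit",
    "compute_lv",
    "estimate_inner",
    "reestimate_lvs",
    "update_weights_modeA",
    "fit",
]


@dataclass
class MsplsFit:
    """Converged (or max-iteration) state of one msPLS fit."""

    block_names: List[str]
    weights: Dict[str, np.ndarray]        # unit-norm, sign-aligned outer weights
    scores: Dict[str, np.ndarray]         # final unit-variance LVs
    theta: np.ndarray                     # Q x Q inner coefficients
    of_per_block: Dict[str, Optional[float]]
    of_branch: Dict[str, Optional[str]]   # "response" | "terminal" | None
    modes: Dict[str, str]
    n_iter: int
    converged: bool
    crt_trace: List[float]
    penalty_used: PenaltySpec

    @property
    def scores_matrix(self) -> np.ndarray:
        return np.column_stack([self.scores[name] for name in self.block_names])


def _unit_variance(z: np.ndarray) -> np.ndarray:
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:
        raise ValueError("latent variable is constant; cannot normalize")
    return z / sd


def compute_lv(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """LV of one block: ``X w`` centered and scaled to unit sample variance."""
    w = np.asarray(w, dtype=float)
    if not np.any(w):
        raise ValueError("degenerate weights: all entries zero")
    return _unit_variance(X @ w)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def estimate_inner(C: ConnectivityMatrix, Z: np.ndarray) -> np.ndarray:
    """Inner coefficients Theta from the column-bound LV matrix ``Z``.

    ``Theta[m, q]`` multiplies ``zeta_m`` in the re-estimation of ``zeta_q``.
    Regression coefficients are filled first (step b-i); correlation overwrites
    from response LVs follow (step b-ii), so mutually-dependent block pairs end
    up with correlation entries.
    """
    n, Q = Z.shape
    Theta = np.zeros((Q, Q))
    ZtZ = Z.T @ Z
    for q in range(Q):
        expl = C.explanatory_sources(q)
        if expl.size == 0:
            continue
        G = ZtZ[np.ix_(expl, expl)]
        try:
            coef = np.linalg.solve(G, ZtZ[expl, q])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"collinear latent variables among explanatory blocks {list(expl)} "
                f"of block {q}: inner regression is singular"
            ) from exc
        Theta[expl, q] = coef
    if np.any(C.C):
        means = Z.mean(axis=0)
        Zc2 = ZtZ - n * np.outer(means, means)  # centered cross products
        norms = np.sqrt(np.diag(Zc2))
        corZ = Zc2 / np.outer(norms, norms)
        for q in range(Q):
            resp = C.responses(q)
            Theta[resp, q] = corZ[resp, q]
    return Theta


def reestimate_lvs(Z: np.ndarray, Theta: np.ndarray) -> np.ndarray:
    """Step (c): ``Z~ = Z Theta``; columns are *not* re-normalized."""
    Zt = Z @ Theta
    if not Zt.any():
        raise ValueError(
            "every re-estimated LV is identically zero (inner coefficients all "
            "zero); the connectivity matrix defines no usable relations"
        )
    return Zt


def update_weights_modeA(X: np.ndarray, zt: np.ndarray) -> np.ndarray:
    """Mode A outer update: per-column regression slope of each MV on ``zt``.

    Returns the raw weights ``X' zt / (zt' zt)``; the engine normalizes
    afterwards.
    """
    denom = zt @ zt
    if denom == 0:
        raise ValueError("re-estimated LV is zero; Mode A update undefined")
    return X.T @ zt / denom


def _normalize_sign(w: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("degenerate weights: all entries zero")
    w = w / nrm
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def _block_objective(q: int, C: ConnectivityMatrix, Z: np.ndarray, Xq: np.ndarray):
    """One block's term of the sum-of-squared-correlations objective.

    Blocks with responses score ``sum_r cor(zeta_r, zeta_q)^2``; terminal
    blocks (no responses) score ``sum_i sum_m cor(zeta_m, x_qi)^2`` over their
    own MVs and explanatory LVs.  Returns ``(branch, value)``; an isolated
    block returns ``(None, None)``.
    """
    resp = C.responses(q)
    if resp.size:
        val = sum(_pearson(Z[:, q], Z[:, m]) ** 2 for m in resp)
        return "response", float(val)
    expl = C.explanatory_sources(q)
    if expl.size == 0:
        return None, None
    n = Xq.shape[0]
    Xc = Xq - Xq.mean(axis=0)
    xnorm = np.linalg.norm(Xc, axis=0)
    xnorm[xnorm == 0] = np.inf  # zero-variance column contributes 0
    total = 0.0
    for m in expl:
        z = Z[:, m] - Z[:, m].mean()
        cors = (Xc.T @ z) / (xnorm * np.linalg.norm(z))
        total += float(cors @ cors)
    return "terminal", total


def _fit_arrays(
    Xs: List[np.ndarray],
    names: List[str],
    C: ConnectivityMatrix,
    penalty: PenaltySpec,
    gamma: float = 1e-6,
    max_iter: int = 500,
) -> MsplsFit:
    """Core loop on centered numpy matrices (no container overhead)."""
    Q = len(Xs)
    if C.Q != Q:
        raise ValueError(f"connectivity is {C.Q}x{C.Q} for {Q} blocks")
    n = Xs[0].shape[0]
    modes = {names[q]: C.mode(q) for q in range(Q)}
    ws = [_normalize_sign(np.ones(X.shape[1])) for X in Xs]
    Z = np.empty((n, Q))
    crt_trace: List[float] = []
    converged = False
    n_iter = 0
    # cardinality targets translate to a per-block lambda1, refreshed each
    # iteration from the current re-estimated LV
    for n_iter in range(1, max_iter + 1):
        for q in range(Q):
            z = Xs[q] @ ws[q]
            z -= z.mean()
            sd2 = z @ z / (n - 1)
            if sd2 == 0:
                raise ValueError("latent variable is constant; cannot normalize")
            Z[:, q] = z / np.sqrt(sd2)
        Theta = estimate_inner(C, Z)
        Zt = reestimate_lvs(Z, Theta)
        new_ws = []
        for q in range(Q):
            if modes[names[q]] == "A":
                w = update_weights_modeA(Xs[q], Zt[:, q])
                new_ws.append(_normalize_sign(w))
                continue
            # Penalized updates see the re-estimated LV rescaled to unit
            # variance and divided by n-1, so |x_j' zt| is exactly the
            # correlation of variable j with the re-estimated LV.  The raw
            # Z~ column's scale grows by an order of magnitude between the
            # all-ones start and convergence (its inner coefficients start
            # near 0 and end near 1), so a fixed lambda1 on the raw scale
            # cannot be simultaneously survivable early and selective late;
            # on the correlation scale lambda1 keeps one meaning throughout
            # the iteration and across sample sizes — in particular a lambda1
            # cross-validated on training folds transfers to the full fit.
            ztq = Zt[:, q] - Zt[:, q].mean()
            ztn2 = ztq @ ztq
            if ztn2 == 0:
                raise ValueError("re-estimated LV is constant; cannot normalize")
            ztq /= np.sqrt(ztn2 * (n - 1))  # unit variance, then / (n-1)
            if penalty.kind == "ust":
                w = ust_update(Xs[q], ztq, penalty.lambda1_for(names[q]))
            elif penalty.kind == "cardinality":
                lam = lambda_for_cardinality(Xs[q], ztq, penalty.k_for(names[q]))
                w = ust_update(Xs[q], ztq, lam)
            else:  # enet
                w = enet_update(
                    Xs[q], ztq, penalty.lambda1_for(names[q]), penalty.lambda2
                )
            new_ws.append(_normalize_sign(w))
        crt = float(sum(np.sum((wn - wo) ** 2) for wn, wo in zip(new_ws, ws)))
        crt_trace.append(crt)
        ws = new_ws
        if crt < gamma:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"msPLS did not converge in {max_iter} iterations (CRT={crt_trace[-1]:.3g})",
            stacklevel=2,
        )
    for q in range(Q):
        Z[:, q] = compute_lv(Xs[q], ws[q])
    Theta = estimate_inner(C, Z)
    of_val: Dict[str, Optional[float]] = {}
    of_branch: Dict[str, Optional[str]] = {}
    for q in range(Q):
        branch, val = _block_objective(q, C, Z, Xs[q])
        of_branch[names[q]] = branch
        of_val[names[q]] = val
    return MsplsFit(
        block_names=list(names),
        weights={names[q]: ws[q] for q in range(Q)},
        scores={names[q]: Z[:, q].copy() for q in range(Q)},
        theta=Theta,
        of_per_block=of_val,
        of_branch=of_branch,
        modes=modes,
        n_iter=n_iter,
        converged=converged,
        crt_trace=crt_trace,
        penalty_used=penalty,
    )


def fit(
    dataset: MultiBlockDataset,
    C: ConnectivityMatrix,
    penalty: Optional[PenaltySpec] = None,
    gamma: float = 1e-6,
    max_iter: int = 500,
) -> MsplsFit:
    """Fit the msPLS model.

    ``dataset`` is standardized internally when its blocks are not already
    flagged as such.  ``penalty`` defaults to the unpenalized elastic net
    (``lambda1 = lambda2 = 0``), which is only valid for low-dimensional
    full-rank blocks; high-dimensional blocks need a positive penalty.
    Non-convergence after ``max_iter`` iterations is reported with a warning,
    not an exception.
    """
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    if penalty is None:
        penalty = PenaltySpec(kind="enet", lambda1=0.0, lambda2=0.0)
    ds = dataset.standardize()
    Xs = [b.values for b in ds.blocks]
    return _fit_arrays(Xs, ds.names, C, penalty, gamma=gamma, max_iter=max_iter)
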