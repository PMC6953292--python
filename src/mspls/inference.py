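"""Model selection and resampling inference for msPLS.

Implements the sum-of-squared-correlations objective, k-fold cross-validation
of the LASSO penalty, a permutation test of model significance (permuting the
rows of each block independently destroys the between-block association while
preserving each block's internal correlation structure), and bootstrap
confidence intervals for the objective (rows resampled with replacement with
the *same* index vector in every block, preserving the cross-block
correlation; the penalty from the original fit is reused).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import KFold

from .data_model import (
    ConnectivityMatrix,
    MultiBlockDataset,
    apply_standardizer,
    column_standardizer,
)
from .engine import MsplsFit, _block_objective, _fit_arrays, compute_lv, estimate_inner, reestimate_lvs
from .penalties import EmptyModelError, PenaltySpec

__all__ = [
    "ObjectiveReport",
    "CvResult",
    "PermutationResult",
    "BootstrapResult",
    "objective_function",
    "default_lambda_grid",
    "cross_validate",
    "permutation_test",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class ObjectiveReport:
    """Per-block objective values and the branch each block used.

    ``branch[name]`` is ``"response"`` (sum of squared correlations between
    the block's LV and its response LVs, bounded by R_q), ``"terminal"``
    (sum over the block's MVs and explanatory LVs of squared correlations,
    bounded by p_q * M_q) or ``None`` for an isolated block.
    """

    values: Dict[str, Optional[float]]
    branch: Dict[str, Optional[str]]

    def __getitem__(self, name: str) -> Optional[float]:
        return self.values[name]


def objective_function(
    fit: MsplsFit, C: ConnectivityMatrix, dataset: MultiBlockDataset
) -> ObjectiveReport:
    """Recompute the objective from a fit's final LVs and the (standardized) data."""
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    ds = dataset.standardize()
    Z = fit.scores_matrix
    values, branch = {}, {}
    for q, name in enumerate(fit.block_names):
        br, val = _block_objective(q, C, Z, ds[name].values)
        values[name], branch[name] = val, br
    return ObjectiveReport(values=values, branch=branch)


def _default_of_block(C: ConnectivityMatrix, names: Sequence[str]) -> str:
    """First terminal block (no responses but with explanatory sources)."""
    for q, name in enumerate(names):
        if C.n_responses(q) == 0 and C.n_explanatory(q) > 0:
            return name
    # fall back to the first block with a defined objective
    for q, name in enumerate(names):
        if C.n_responses(q) > 0:
            return name
    raise ValueError("no block has a defined objective under this connectivity")


def default_lambda_grid(
    dataset: MultiBlockDataset, C: ConnectivityMatrix, size: int = 20
) -> np.ndarray:
    """Heuristic lambda1 grid: 20 log-spaced values in [0.01*lam_max, lam_max].

    ``lam_max`` is twice the largest ``|x_j' zt|`` over penalized blocks after
    one unpenalized warm-start pass (steps a-c from the all-ones weights), the
    smallest value that already empties every penalized block at that pass.
    """
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    ds = dataset.standardize()
    Xs = [b.values for b in ds.blocks]
    Q = len(Xs)
    Z = np.column_stack(
        [compute_lv(X, np.ones(X.shape[1])) for X in Xs]
    )
    Zt = reestimate_lvs(Z, estimate_inner(C, Z))
    lam_max = 0.0
    for q in range(Q):
        if C.mode(q) == "B":
            ztq = Zt[:, q] - Zt[:, q].mean()
            # the engine penalizes on the correlation scale
            ztq = ztq / (ztq.std(ddof=1) * (len(ztq) - 1))
            lam_max = max(lam_max, 2.0 * float(np.max(np.abs(Xs[q].T @ ztq))))
    if lam_max == 0.0:
        raise ValueError("no penalized block; lambda grid is undefined")
    return np.geomspace(0.01 * lam_max, lam_max, size)


@dataclass(frozen=True)
class CvResult:
    grid: np.ndarray
    fold_objectives: np.ndarray   # len(grid) x folds held-out objective values
    mean_objectives: np.ndarray   # len(grid)
    chosen_lambda1: float
    folds: int
    seed: Optional[int]
    of_block: str


def _held_out_objective(
    C: ConnectivityMatrix,
    names: Sequence[str],
    of_idx: int,
    Z_test: np.ndarray,
    X_test_of: np.ndarray,
) -> float:
    branch, val = _block_objective(of_idx, C, Z_test, X_test_of)
    if val is None:
        raise ValueError(f"objective undefined for block {names[of_idx]!r}")
    return val


def cross_validate(
    dataset: MultiBlockDataset,
    C: ConnectivityMatrix,
    grid: Optional[Sequence[float]] = None,
    folds: int = 10,
    seed: Optional[int] = None,
    penalty_kind: str = "ust",
    lambda2: float = 0.0,
    of_block: Optional[str] = None,
    gamma: float = 1e-6,
    max_iter: int = 500,
) -> CvResult:
    """Choose lambda1 by k-fold cross-validation of the held-out objective.

    Samples are partitioned once (seeded).  For each fold the model is fitted
    on the training rows (standardized with training means/sds); held-out LVs
    are obtained by projecting the test rows — standardized with the
    *training* parameters — onto the fitted weights, and the objective branch
    of ``of_block`` is evaluated on the held-out data.  The lambda with the
    best mean held-out objective wins; ties go to the largest (sparsest)
    lambda.  A lambda that empties a block in any fold scores ``-inf``.
    """
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    n = dataset.n_samples
    if folds < 2 or n < folds:
        raise ValueError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    if grid is None:
        grid = default_lambda_grid(dataset, C)
    grid = np.sort(np.asarray(list(grid), dtype=float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    names = dataset.names
    of_name = of_block or _default_of_block(C, names)
    of_idx = names.index(of_name)
    raw = [b.values for b in dataset.blocks]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(np.arange(n)))
    # pre-standardize each fold once; reused across the lambda grid
    fold_data = []
    for train, test in splits:
        Xtr, Xte = [], []
        for X in raw:
            mean, sd = column_standardizer(X[train])
            if np.any(sd == 0):
                raise ValueError("constant column in a training fold; reduce folds")
            Xtr.append(apply_standardizer(X[train], mean, sd))
            Xte.append(apply_standardizer(X[test], mean, sd))
        fold_data.append((Xtr, Xte))

    fold_obj = np.full((grid.size, folds), -np.inf)
    for li, lam in enumerate(grid):
        pen = PenaltySpec(kind=penalty_kind, lambda1=float(lam), lambda2=lambda2)
        for fi, (Xtr, Xte) in enumerate(fold_data):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f = _fit_arrays(Xtr, names, C, pen, gamma=gamma, max_iter=max_iter)
            except (EmptyModelError, np.linalg.LinAlgError):
                fold_obj[li, :] = -np.inf
                break
            Z_test = np.column_stack(
                [Xte[q] @ f.weights[names[q]] for q in range(len(names))]
            )
            fold_obj[li, fi] = _held_out_objective(C, names, of_idx, Z_test, Xte[of_idx])
    mean_obj = fold_obj.mean(axis=1)
    best = np.max(mean_obj)
    if not np.isfinite(best):
        raise ValueError("every lambda in the grid produced an empty model")
    chosen = float(np.max(grid[mean_obj == best]))
    return CvResult(
        grid=grid,
        fold_objectives=fold_obj,
        mean_objectives=mean_obj,
        chosen_lambda1=chosen,
        folds=folds,
        seed=seed,
        of_block=of_name,
    )


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_nonconverged: int
    n_empty: int
    B: int
    seed: Optional[int]
    of_block: str


def permutation_test(
    dataset: MultiBlockDataset,
    C: ConnectivityMatrix,
    penalty: PenaltySpec,
    B: int = 1000,
    seed: Optional[int] = None,
    of_block: Optional[str] = None,
    gamma: float = 1e-6,
    max_iter: int = 500,
) -> PermutationResult:
    """Permutation test of the objective at a fixed (typically CV-chosen) penalty.

    Each replicate permutes the row order of every block independently and
    refits.  The p-value is ``(1 + #{null >= observed}) / (B + 1)`` and is
    therefore never below ``1/(B+1)``.  A permuted refit whose penalized
    blocks are emptied by the penalty captures no association and contributes
    a null objective of 0 (counted in ``n_empty``); non-converged refits
    still contribute their objective (counted in ``n_nonconverged``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    ds = dataset.standardize()
    names = ds.names
    of_name = of_block or _default_of_block(C, names)
    of_idx = names.index(of_name)
    Xs = [b.values for b in ds.blocks]
    n = ds.n_samples
    rng = np.random.default_rng(seed)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f0 = _fit_arrays(Xs, names, C, penalty, gamma=gamma, max_iter=max_iter)
        observed = f0.of_per_block[of_name]
    except EmptyModelError:
        observed = 0.0  # the penalty selects nothing: no association captured
    null = np.empty(B)
    n_nonconverged = 0
    n_empty = 0
    for b in range(B):
        Xp = [X[rng.permutation(n)] for X in Xs]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fb = _fit_arrays(Xp, names, C, penalty, gamma=gamma, max_iter=max_iter)
            null[b] = fb.of_per_block[of_name]
            n_nonconverged += not fb.converged
        except EmptyModelError:
            null[b] = 0.0
            n_empty += 1
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return PermutationResult(
        observed=float(observed),
        null=null,
        p_value=float(p),
        n_nonconverged=n_nonconverged,
        n_empty=n_empty,
        B=B,
        seed=seed,
        of_block=of_name,
    )


@dataclass(frozen=True)
class BootstrapResult:
    observed: float
    replicates: np.ndarray
    levels: Tuple[float, float]
    interval: Tuple[float, float]
    n_failed: int
    B: int
    seed: Optional[int]
    of_block: str


def bootstrap_ci(
    dataset: MultiBlockDataset,
    C: ConnectivityMatrix,
    penalty: PenaltySpec,
    B: int = 1000,
    levels: Tuple[float, float] = (0.025, 0.975),
    seed: Optional[int] = None,
    of_block: Optional[str] = None,
    gamma: float = 1e-6,
    max_iter: int = 500,
) -> BootstrapResult:
    """Bootstrap confidence interval for the objective at a fixed penalty.

    One index vector (sampled with replacement) is applied to every block per
    replicate so the cross-block correlation is preserved; each resampled
    block is re-standardized before refitting.  Quantiles are empirical
    (inverse-CDF).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    ds = dataset.standardize()
    names = ds.names
    of_name = of_block or _default_of_block(C, names)
    Xs = [b.values for b in ds.blocks]
    n = ds.n_samples
    rng = np.random.default_rng(seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f0 = _fit_arrays(Xs, names, C, penalty, gamma=gamma, max_iter=max_iter)
        observed = f0.of_per_block[of_name]
    except EmptyModelError:
        observed = 0.0
    reps = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            Xb = []
            for X in Xs:
                Xr = X[idx]
                mean, sd = column_standardizer(Xr)
                if np.any(sd == 0):
                    raise ValueError("constant column in bootstrap resample")
                Xb.append(apply_standardizer(Xr, mean, sd))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fb = _fit_arrays(Xb, names, C, penalty, gamma=gamma, max_iter=max_iter)
            reps.append(fb.of_per_block[of_name])
        except (EmptyModelError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    reps = np.asarray(reps)
    lo, hi = np.quantile(reps, levels, method="inverted_cdf")
    return BootstrapResult(
        observed=float(observed),
        replicates=reps,
        levels=tuple(levels),
        interval=(float(lo), float(hi)),
        n_failed=n_failed,
        B=B,
        seed=seed,
        of_block=of_name,
    )
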