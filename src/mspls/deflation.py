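"""Extraction of multiple latent-variable sets via residualization.

After a component is fitted, selected blocks are replaced by their residuals
from the rank-1 projection onto that component's LV; refitting on the
residuals yields a second set of LVs orthogonal (within each deflated block)
to the first.  Residuals are *not* re-standardized between components: the
correlations driving the fit are scale-free, and keeping the original column
variances makes the explained-variance bookkeeping exact — the fraction of a
column's original (unit) variance captured by component alpha is
``cor(zeta, x_res)^2 * var(x_res)``, and these fractions sum across
components to at most 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .data_model import ConnectivityMatrix, MultiBlockDataset
from .engine import MsplsFit, _fit_arrays
from .penalties import PenaltySpec

__all__ = [
    "ComponentSet",
    "deflate_block",
    "explained_variance",
    "extract_components",
]


def deflate_block(X: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    """Residual of ``X`` after projecting out ``zeta``:  X - z (z'z)^-1 z' X."""
    denom = zeta @ zeta
    if denom == 0:
        raise ValueError("latent variable is constant; cannot deflate")
    return X - np.outer(zeta, (zeta @ X) / denom)


def explained_variance(X: np.ndarray, zeta: np.ndarray) -> float:
    """Average squared correlation between ``zeta`` and the columns of ``X``.

    This is the mean communality of the block under its LV — the per-block
    R^2 analogue used for explained-variance reporting.  Zero-variance
    columns (fully deflated) contribute 0 with a warning.
    """
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    dead = norms == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance column(s) contribute 0 to "
            "explained variance",
            stacklevel=2,
        )
        norms = np.where(dead, np.inf, norms)
    z = zeta - zeta.mean()
    zn = np.linalg.norm(z)
    if zn == 0:
        raise ValueError("latent variable is constant")
    cors = (Xc.T @ z) / (norms * zn)
    return float(np.mean(cors**2))


@dataclass
class ComponentSet:
    """Ordered msPLS components with per-block explained-variance accounting.

    ``explained`` and ``cumulative`` are ``block name -> list over
    components`` of original-scale variance fractions (for deflated blocks
    each column's contribution is rescaled by its residual variance, so
    cumulative fractions are non-decreasing and bounded by 1).
    """

    components: List[MsplsFit]
    explained: Dict[str, List[float]]
    cumulative: Dict[str, List[float]]
    deflate_mask: Dict[str, bool]

    @property
    def n_components(self) -> int:
        return len(self.components)


def extract_components(
    dataset: MultiBlockDataset,
    C: ConnectivityMatrix,
    penalty: Optional[PenaltySpec] = None,
    n_components: int = 2,
    deflate_mask: Optional[Sequence[bool]] = None,
    gamma: float = 1e-6,
    max_iter: int = 500,
) -> ComponentSet:
    """Fit ``n_components`` successive msPLS models with chained deflation.

    Component 1 is fitted on the original (standardized) data; component
    alpha+1 on data where masked blocks are replaced by their residuals from
    component alpha.  The default mask deflates blocks *with* responses and
    keeps terminal (response-free) blocks original, so successive explanatory
    LV sets explain disjoint portions of variance while always targeting the
    same responses.  If a residual block loses essentially all variance the
    extraction stops early with a warning.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    if penalty is None:
        penalty = PenaltySpec(kind="enet", lambda1=0.0, lambda2=0.0)
    ds = dataset.standardize()
    names = ds.names
    if deflate_mask is None:
        mask = [C.mode(q) == "B" for q in range(ds.Q)]
    else:
        mask = list(deflate_mask)
        if len(mask) != ds.Q:
            raise ValueError("deflate_mask length must equal the number of blocks")
    X_cur = [b.values.copy() for b in ds.blocks]

    components: List[MsplsFit] = []
    explained = {name: [] for name in names}
    cumulative = {name: [] for name in names}
    for _alpha in range(n_components):
        f = _fit_arrays(X_cur, names, C, penalty, gamma=gamma, max_iter=max_iter)
        components.append(f)
        for q, name in enumerate(names):
            X = X_cur[q]
            zeta = f.scores[name]
            # fraction of ORIGINAL (unit) column variance captured now
            Xc = X - X.mean(axis=0)
            var_res = (Xc**2).sum(axis=0) / (X.shape[0] - 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norms = np.linalg.norm(Xc, axis=0)
                norms = np.where(norms == 0, np.inf, norms)
                z = zeta - zeta.mean()
                cors = (Xc.T @ z) / (norms * np.linalg.norm(z))
            frac = float(np.mean(cors**2 * var_res))
            explained[name].append(frac)
            prev = cumulative[name][-1] if cumulative[name] else 0.0
            cumulative[name].append(prev + frac)
        if _alpha == n_components - 1:
            break
        exhausted = False
        for q, name in enumerate(names):
            if not mask[q]:
                continue
            X_cur[q] = deflate_block(X_cur[q], f.scores[name])
            if np.max(X_cur[q].var(axis=0, ddof=1)) < 1e-12:
                warnings.warn(
                    f"block {name!r} has no variance left after deflation; "
                    f"stopping at {len(components)} component(s)",
                    stacklevel=2,
                )
                exhausted = True
        if exhausted:
            break
    return ComponentSet(
        components=components,
        explained=explained,
        cumulative=cumulative,
        deflate_mask={name: bool(m) for name, m in zip(names, mask)},
    )
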