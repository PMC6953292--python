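"""Core containers for multi-block data and the block-relationship structure.

A *block* is one data source (e.g. one omics platform): an ``n x p`` numeric
matrix whose rows are shared samples and whose columns are manifest variables
(MVs).  A :class:`MultiBlockDataset` holds Q blocks measured on the same
samples in the same order.  The hypothesised explanatory/response structure
between blocks is a binary Q x Q :class:`ConnectivityMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "OmicsBlock",
    "MultiBlockDataset",
    "ConnectivityMatrix",
    "BlockRelations",
    "center_scale",
    "validate_connectivity",
]

MODE_UNIVARIATE = "A"
MODE_PENALIZED_MULTIVARIATE = "B"


@dataclass(frozen=True)
class OmicsBlock:
    """One data source: an ``n_samples x p`` matrix with row/column labels.

    ``standardized`` flags that every column has mean 0 and unit sample
    standard deviation (denominator ``n - 1``); the estimation engine
    requires standardized blocks.
    """

    name: str
    values: np.ndarray
    variable_ids: Sequence[str] = None
    sample_ids: Sequence[str] = None
    standardized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"block {self.name!r}: values must be a 2-d matrix")
        n, p = values.shape
        if n < 3:
            raise ValueError(f"block {self.name!r}: need at least 3 samples, got {n}")
        if p < 1:
            raise ValueError(f"block {self.name!r}: need at least 1 variable")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"block {self.name!r} contains missing or non-finite entries; "
                "impute or drop them before constructing the block"
            )
        object.__setattr__(self, "values", values)
        vids = self.variable_ids
        sids = self.sample_ids
        vids = [f"{self.name}_v{j + 1}" for j in range(p)] if vids is None else list(vids)
        sids = [f"s{i + 1}" for i in range(n)] if sids is None else list(sids)
        if len(vids) != p:
            raise ValueError(f"block {self.name!r}: {len(vids)} variable ids for {p} columns")
        if len(sids) != n:
            raise ValueError(f"block {self.name!r}: {len(sids)} sample ids for {n} rows")
        object.__setattr__(self, "variable_ids", vids)
        object.__setattr__(self, "sample_ids", sids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def column_standardizer(values: np.ndarray):
    """Column means and sample standard deviations (``ddof=1``)."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return mean, sd


def apply_standardizer(values: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Standardize ``values`` with externally supplied column parameters.

    Used in cross-validation, where held-out rows must be scaled with the
    training means/sds to avoid information leakage.
    """
    return (values - mean) / sd


def center_scale(block: OmicsBlock) -> OmicsBlock:
    """Return a standardized copy of ``block`` (mean 0, sample sd 1 columns).

    The transformation is idempotent; re-applying it to an already
    standardized block returns it unchanged up to floating point.  Constant
    columns are a hard error (silently dropping them would shift variable
    indices and corrupt any selection bookkeeping downstream).
    """
    mean, sd = column_standardizer(block.values)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(block.variable_ids[j] for j in bad[:5])
        raise ValueError(
            f"block {block.name!r}: constant column(s) cannot be scaled: {names}"
        )
    values = apply_standardizer(block.values, mean, sd)
    return replace(block, values=values, standardized=True)


@dataclass(frozen=True)
class MultiBlockDataset:
    """An ordered collection of Q >= 2 blocks sharing the same samples."""

    blocks: Sequence[OmicsBlock]

    def __post_init__(self):
        blocks = list(self.blocks)
        if len(blocks) < 2:
            raise ValueError("a multi-block dataset needs at least two blocks")
        ref = blocks[0].sample_ids
        for b in blocks[1:]:
            if b.sample_ids != ref:
                first = next(
                    (i, a, c) for i, (a, c) in enumerate(zip(ref, b.sample_ids)) if a != c
                ) if len(ref) == len(b.sample_ids) else (None, None, None)
                raise ValueError(
                    f"sample ids of block {b.name!r} do not match block "
                    f"{blocks[0].name!r} (first discrepancy: {first}); blocks must "
                    "share samples in identical order"
                )
        names = [b.name for b in blocks]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        object.__setattr__(self, "blocks", blocks)

    @property
    def Q(self) -> int:
        return len(self.blocks)

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    @property
    def names(self) -> list:
        return [b.name for b in self.blocks]

    @property
    def standardized(self) -> bool:
        return all(b.standardized for b in self.blocks)

    def __getitem__(self, key) -> OmicsBlock:
        if isinstance(key, str):
            for b in self.blocks:
                if b.name == key:
                    return b
            raise KeyError(key)
        return self.blocks[key]

    def standardize(self) -> "MultiBlockDataset":
        """Center-and-scale every block that is not already standardized."""
        return MultiBlockDataset(
            [b if b.standardized else center_scale(b) for b in self.blocks]
        )


@dataclass(frozen=True)
class BlockRelations:
    """Relation summary for one block derived from the connectivity matrix."""

    name: str
    explanatory: np.ndarray  # indices of blocks explanatory for this block
    responses: np.ndarray    # indices of blocks that are responses of this block
    mode: str                # "A" (univariate) or "B" (penalized multivariate)


class ConnectivityMatrix:
    """Binary Q x Q relation ``c[q, q'] = 1`` iff block q is response for q'.

    Row ``q`` therefore marks the explanatory sources of block ``q`` and
    column ``q'`` the responses of block ``q'``.  Blocks with no responses
    (empty column) use the univariate "Mode A" outer update; blocks with
    responses use the penalized multivariate "Mode B" update.
    """

    def __init__(self, C):
        C = np.asarray(C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isin(C, (0.0, 1.0)).all():
            raise ValueError("connectivity entries must be 0 or 1")
        if np.any(np.diag(C) != 0):
            raise ValueError("connectivity diagonal must be zero (no self-relations)")
        self.C = C.astype(int)

    @property
    def Q(self) -> int:
        return self.C.shape[0]

    def explanatory_sources(self, q: int) -> np.ndarray:
        """Indices of blocks explanatory for block ``q`` (row support)."""
        return np.flatnonzero(self.C[q, :])

    def responses(self, q: int) -> np.ndarray:
        """Indices of blocks that are responses of block ``q`` (column support)."""
        return np.flatnonzero(self.C[:, q])

    def n_explanatory(self, q: int) -> int:
        """M_q: number of explanatory latent variables feeding block q."""
        return int(self.C[q, :].sum())

    def n_responses(self, q: int) -> int:
        """R_q: number of response latent variables of block q."""
        return int(self.C[:, q].sum())

    def mode(self, q: int) -> str:
        return MODE_UNIVARIATE if self.n_responses(q) == 0 else MODE_PENALIZED_MULTIVARIATE


def validate_connectivity(C: ConnectivityMatrix, dataset: MultiBlockDataset):
    """Check ``C`` against ``dataset`` and derive per-block relation labels.

    Returns one :class:`BlockRelations` per block.  A block with neither
    explanatory sources nor responses is isolated (it would contribute
    nothing to the inner model) and triggers a warning.
    """
    if not isinstance(C, ConnectivityMatrix):
        C = ConnectivityMatrix(C)
    if C.Q != dataset.Q:
        raise ValueError(
            f"connectivity matrix is {C.Q}x{C.Q} but the dataset has {dataset.Q} blocks"
        )
    out = []
    for q, block in enumerate(dataset.blocks):
        expl = C.explanatory_sources(q)
        resp = C.responses(q)
        if expl.size == 0 and resp.size == 0:
            warnings.warn(
                f"block {block.name!r} is isolated: it has no explanatory sources "
                "and no responses",
                stacklevel=2,
            )
        out.append(
            BlockRelations(name=block.name, explanatory=expl, responses=resp, mode=C.mode(q))
        )
    return out
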