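"""Delimited-text input/output and run configuration.

Matrices travel as CSV/TSV with one header row of variable IDs and one
leading column of sample IDs.  Results are written as small delimited tables
keyed by variable ID (the interchange surface downstream enrichment tooling
consumes) plus a JSON sidecar with the exact configuration and seeds, so any
run is reproducible from its own output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import ConnectivityMatrix, MultiBlockDataset, OmicsBlock
from .engine import MsplsFit

__all__ = [
    "RunConfig",
    "load_config",
    "load_block",
    "load_dataset",
    "save_block",
    "save_fit",
    "save_study",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def load_block(path, name: Optional[str] = None) -> OmicsBlock:
    """Read one block; first row variable IDs, first column sample IDs."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = df.to_numpy(dtype=object)
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = np.flatnonzero(numeric != numeric)  # NaN marks unparsable or missing
    # distinguish true NaN input (missing) from unparsable text: both rejected
    if bad.size:
        i, j = divmod(int(bad[0]), df.shape[1])
        raise ValueError(
            f"{path}: non-numeric or missing value {values[i, j]!r} at "
            f"sample {df.index[i]!r}, variable {df.columns[j]!r}"
        )
    return OmicsBlock(
        name=name or path.stem,
        values=numeric.reshape(df.shape).astype(float),
        variable_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def load_dataset(paths: Sequence, names: Optional[Sequence[str]] = None) -> MultiBlockDataset:
    """Read Q block files sharing the same samples in the same order.

    A sample-ID mismatch is an error (no silent reordering or joining).
    """
    names = list(names) if names is not None else [None] * len(paths)
    blocks = [load_block(p, n) for p, n in zip(paths, names)]
    return MultiBlockDataset(blocks)


def save_block(block: OmicsBlock, path) -> None:
    path = Path(path)
    df = pd.DataFrame(block.values, index=block.sample_ids, columns=block.variable_ids)
    df.to_csv(path, sep=_sep_for(path))


@dataclass
class RunConfig:
    """Declarative description of one analysis run (YAML or JSON)."""

    block_paths: List[str]
    block_names: List[str]
    connectivity: List[List[int]]
    penalty_kind: str = "ust"
    lambda1: float = 0.0
    lambda2: float = 0.0
    k_target: Optional[Dict[str, int]] = None
    cv_folds: int = 10
    cv_grid: Optional[List[float]] = None
    cv_seed: Optional[int] = None
    B_permutation: int = 1000
    B_bootstrap: int = 1000
    bootstrap_levels: List[float] = field(default_factory=lambda: [0.025, 0.975])
    inference_seed: Optional[int] = None
    n_components: int = 1
    deflate_mask: Optional[List[bool]] = None
    output_dir: str = "."

    def __post_init__(self):
        if len(self.block_paths) != len(self.block_names):
            raise ValueError("block_paths and block_names must align")
        Q = len(self.block_paths)
        C = np.asarray(self.connectivity)
        if C.shape != (Q, Q):
            raise ValueError(
                f"connectivity is {C.shape} but there are {Q} blocks"
            )
        ConnectivityMatrix(C)  # validates binary / zero diagonal
        for p in self.block_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return RunConfig(**data)


def save_fit(fit: MsplsFit, outdir, dataset: Optional[MultiBlockDataset] = None) -> None:
    """Write a machine-readable results bundle for one fit.

    Per block: a two-column ``variable_id, weight`` table; plus LV scores per
    sample, the inner-coefficient matrix, the per-block objective values and
    a JSON summary (convergence, penalty, iteration trace).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = (
        dataset.blocks[0].sample_ids
        if dataset is not None
        else [f"s{i + 1}" for i in range(len(next(iter(fit.scores.values()))))]
    )
    for name in fit.block_names:
        vids = (
            dataset[name].variable_ids
            if dataset is not None
            else [f"{name}_v{j + 1}" for j in range(len(fit.weights[name]))]
        )
        pd.DataFrame({"variable_id": vids, "weight": fit.weights[name]}).to_csv(
            outdir / f"weights_{name}.csv", index=False
        )
    pd.DataFrame(fit.scores, index=sample_ids).to_csv(outdir / "scores.csv")
    pd.DataFrame(fit.theta, index=fit.block_names, columns=fit.block_names).to_csv(
        outdir / "theta.csv"
    )
    pd.DataFrame(
        {
            "block": fit.block_names,
            "branch": [fit.of_branch[n] for n in fit.block_names],
            "objective": [fit.of_per_block[n] for n in fit.block_names],
            "mode": [fit.modes[n] for n in fit.block_names],
        }
    ).to_csv(outdir / "objective.csv", index=False)
    summary = {
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "crt_trace": [float(c) for c in fit.crt_trace],
        "penalty": {
            "kind": fit.penalty_used.kind,
            "lambda1": fit.penalty_used.lambda1
            if not isinstance(fit.penalty_used.lambda1, dict)
            else dict(fit.penalty_used.lambda1),
            "lambda2": fit.penalty_used.lambda2,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def save_study(study, path) -> None:
    """Write a recovery study as a delimited table: one row per replicate
    plus a trailing aggregate (mean) row."""
    path = Path(path)
    records = study.records.copy()
    agg = {
        c: records[c].mean() for c in records.columns if c not in ("seed", "converged")
    }
    agg["replicate"] = "mean"
    out = pd.concat([records, pd.DataFrame([agg])], ignore_index=True)
    out.to_csv(path, sep=_sep_for(path), index=False)
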