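"""Replicate averaging and ternary discretization.

The inference stage consumes a matrix over {-1, 0, +1}: per gene, values are
centered (gene mean by default) and thresholded symmetrically at k times the
standard deviation of the full centered matrix.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = ["DiscreteMatrix", "average_replicates", "discretize"]


class DiscreteMatrix:
    """Genes x samples matrix over the three states {-1, 0, +1}."""

    def __init__(self, states: pd.DataFrame):
        arr = states.to_numpy()
        if not np.isin(arr, (-1, 0, 1)).all():
            raise ValueError("discrete matrix may only contain -1, 0, +1")
        self.states = states.astype(np.int8)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.columns)

    def row(self, gene: str) -> np.ndarray:
        return self.states.loc[gene].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.states.shape
        nz = float((self.states.to_numpy() != 0).mean())
        return f"DiscreteMatrix({g} genes x {s} samples, {nz:.1%} nonzero)"


def average_replicates(
    expr: ExpressionMatrix, grouping: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Collapse replicate columns to their arithmetic group means.

    ``grouping`` maps every sample id to a group label; output has one column
    per group, in order of first occurrence among the samples. Numeric
    metadata columns are averaged within groups, non-numeric ones take the
    first member's value.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    missing = [s for s in expr.sample_ids if s not in grouping]
    if missing:
        raise ValueError(f"sample(s) without a replicate group: {missing}")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        g = str(grouping[s])
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(s)
    for g, mem in members.items():
        if not mem:  # pragma: no cover - unreachable by construction
            raise ValueError(f"replicate group with zero members: {g!r}")
    out = pd.DataFrame(
        {g: expr.values[members[g]].mean(axis=1) for g in order},
        index=expr.values.index,
    )
    meta = None
    if expr.sample_meta is not None:
        rows = {}
        for g in order:
            sub = expr.sample_meta.loc[members[g]]
            rec = {}
            for col in sub.columns:
                if pd.api.types.is_numeric_dtype(sub[col]):
                    rec[col] = sub[col].mean()
                else:
                    rec[col] = sub[col].iloc[0]
            rows[g] = rec
        meta = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    return ExpressionMatrix(out, sample_meta=meta)


def discretize(
    expr: ExpressionMatrix,
    k: float = 1.0,
    center: str = "gene_mean",
    reference_samples: Sequence[str] | None = None,
) -> DiscreteMatrix:
    """Ternarize expression: +1 above +k*sigma, -1 below -k*sigma, else 0.

    Each gene is centered on its mean across samples (``center='gene_mean'``,
    the default) or on its mean over ``reference_samples``
    (``center='reference'``); sigma is the standard deviation of the full
    centered matrix, so one global scale applies to every gene. The
    thresholds are closed (>= / <=). An all-constant matrix (sigma = 0)
    yields all-zero states with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    vals = expr.values.to_numpy(dtype=float)
    if center == "gene_mean":
        centered = vals - vals.mean(axis=1, keepdims=True)
    elif center == "reference":
        if not reference_samples:
            raise ValueError("center='reference' requires reference_samples")
        idx = [expr.sample_ids.index(s) for s in reference_samples]
        centered = vals - vals[:, idx].mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown centering mode: {center!r}")
    sigma = float(centered.std())
    states = np.zeros_like(centered, dtype=np.int8)
    if sigma == 0.0:
        warnings.warn("all-constant expression matrix: every state set to 0")
    else:
        states[centered >= k * sigma] = 1
        states[centered <= -k * sigma] = -1
    return DiscreteMatrix(
        pd.DataFrame(states, index=expr.values.index, columns=expr.values.columns)
    )
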