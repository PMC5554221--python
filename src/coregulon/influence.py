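"""Sample-specific TF influence: a Welch-t statistic on regulon expression.

For a regulator r with activated targets A^r and repressed targets I^r, the
influence in one sample compares the expression of the two target sets:

    influence = (mean E(A^r) - mean E(I^r)) /
                sqrt(s2_A / |A^r| + s2_I / |I^r|)

with s2 the per-set sample variance (ddof = 1; a singleton contributes
variance 0). A positive value means the activated targets sit above the
repressed ones -- the regulator is acting; a negative value means the
opposite pattern. Influence is only reported for TFs with at least
``min_target`` targets in total (10 in the default configuration).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .licorn import GRN

__all__ = ["InfluenceMatrix", "compute_influence", "influence_matrix",
           "influence_heatmap"]


class InfluenceMatrix:
    """TF x sample matrix of influence values; NaN marks undefined entries."""

    def __init__(self, values: pd.DataFrame, min_target: int):
        self.values = values
        self.min_target = min_target

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self) -> str:  # pragma: no cover
        t, s = self.values.shape
        return f"InfluenceMatrix({t} TFs x {s} samples, min_target={self.min_target})"


def _side_stats(vals: np.ndarray) -> tuple[float, float]:
    """(mean, variance/n) of one target side; an empty side contributes
    mean 0 and no variance term, a singleton contributes variance 0."""
    n = vals.size
    if n == 0:
        return 0.0, 0.0
    m = float(vals.mean())
    if n < 2:
        return m, 0.0
    return m, float(vals.var(ddof=1)) / n


def compute_influence(
    expr_sample: Mapping[str, float] | pd.Series,
    Ar: Sequence[str],
    Ir: Sequence[str],
) -> float:
    """Influence of one regulator in one sample; NaN when undefined.

    ``expr_sample`` maps gene id to expression in that sample. Undefined
    when both target sets are empty, or when the denominator vanishes with
    unequal means; equal means with zero denominator give 0 by convention.
    """
    Ar, Ir = list(Ar), list(Ir)
    if set(Ar) & set(Ir):
        raise ValueError("activated and repressed target sets must be disjoint")
    if not Ar and not Ir:
        return float("nan")
    if isinstance(expr_sample, pd.Series):
        a = expr_sample.loc[Ar].to_numpy(dtype=float) if Ar else np.empty(0)
        i = expr_sample.loc[Ir].to_numpy(dtype=float) if Ir else np.empty(0)
    else:
        a = np.array([expr_sample[g] for g in Ar], dtype=float)
        i = np.array([expr_sample[g] for g in Ir], dtype=float)
    ma, va = _side_stats(a)
    mi, vi = _side_stats(i)
    num = ma - mi
    den = np.sqrt(va + vi)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("nan")
    return float(num / den)


def influence_matrix(
    expr: ExpressionMatrix, grn: GRN, min_target: int = 10
) -> InfluenceMatrix:
    """Influence of every sufficiently-connected TF in every sample.

    ``expr`` should already be replicate-averaged. Rows appear only for TFs
    with |A^r| + |I^r| >= ``min_target``, in sorted TF order.
    """
    regulons = grn.regulons
    kept = [tf for tf in sorted(regulons)
            if len(regulons[tf][0]) + len(regulons[tf][1]) >= min_target]
    if not kept:
        warnings.warn(f"no TF reaches min_target={min_target}: empty influence matrix")
        return InfluenceMatrix(
            pd.DataFrame(index=pd.Index([], name="tf"), columns=expr.sample_ids, dtype=float),
            min_target,
        )
    vals = expr.values
    out = np.empty((len(kept), len(expr.sample_ids)))
    for r, tf in enumerate(kept):
        Ar, Ir = regulons[tf]
        a = vals.loc[list(Ar)].to_numpy(dtype=float) if Ar else np.empty((0, vals.shape[1]))
        i = vals.loc[list(Ir)].to_numpy(dtype=float) if Ir else np.empty((0, vals.shape[1]))
        ma = a.mean(axis=0) if a.shape[0] else np.zeros(vals.shape[1])
        mi = i.mean(axis=0) if i.shape[0] else np.zeros(vals.shape[1])
        va = a.var(axis=0, ddof=1) / a.shape[0] if a.shape[0] >= 2 else np.zeros(vals.shape[1])
        vi = i.var(axis=0, ddof=1) / i.shape[0] if i.shape[0] >= 2 else np.zeros(vals.shape[1])
        num = ma - mi
        den = np.sqrt(va + vi)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = num / den
        row[(den == 0.0) & (num == 0.0)] = 0.0
        row[(den == 0.0) & (num != 0.0)] = np.nan
        out[r] = row
    return InfluenceMatrix(
        pd.DataFrame(out, index=pd.Index(kept, name="tf"), columns=expr.sample_ids),
        min_target,
    )


def influence_heatmap(infl: InfluenceMatrix, path, sample_times=None) -> None:
    """Write a PNG heatmap of the influence matrix (red = positive, blue =
    negative), columns in the given time order. Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = infl.values
    if sample_times is not None:
        order = sorted(vals.columns, key=lambda s: sample_times[s])
        vals = vals[order]
    lim = float(np.nanmax(np.abs(vals.to_numpy()))) or 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * vals.shape[1]),
                                    max(3, 0.25 * vals.shape[0])))
    im = ax.imshow(vals.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim,
                   aspect="auto", interpolation="nearest")
    ax.set_yticks(range(vals.shape[0]), vals.index, fontsize=6)
    ax.set_xticks(range(vals.shape[1]), vals.columns, fontsize=6, rotation=90)
    ax.set_xlabel("sample")
    fig.colorbar(im, ax=ax, label="influence (Welch t)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
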