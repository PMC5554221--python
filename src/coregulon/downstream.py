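"""Phase segmentation, robust rank aggregation and master-regulator tests.

Three downstream reads of the influence matrix:

* :func:`segment_phases` cuts the time course into contiguous phases by an
  exact multivariate least-squares change-point dynamic program, with a
  penalized model choice for the number of phases.
* :func:`aggregate_ranks` ranks TFs per sample (signed influence within a
  phase; absolute influence over the whole course) and aggregates the rank
  lists with the robust rank aggregation rho score -- the minimum Beta
  order-statistic tail probability of the TF's normalized ranks under a
  uniform null.
* :func:`master_regulators` tests each TF's regulon for one-sided
  hypergeometric enrichment in a gene list of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, hypergeom
from statsmodels.stats.multitest import multipletests

from .influence import InfluenceMatrix
from .licorn import GRN

__all__ = [
    "PhaseSegmentation",
    "segment_phases",
    "rho_score",
    "aggregate_ranks",
    "EnrichmentResult",
    "master_regulators",
]


@dataclass
class PhaseSegmentation:
    """Contiguous segmentation of time-ordered samples into phases.

    ``boundaries`` lists the 0-based sample indices at which phases 2..K
    start (the first sample always starts phase 1); ``labels`` gives the
    phase number (1-based) of every sample.
    """

    boundaries: list[int]
    labels: list[int]
    n_phases: int
    cost: float

    def __post_init__(self):
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("phase boundaries must be strictly increasing")
        if self.labels and self.labels[0] != 1:
            raise ValueError("first sample must start phase 1")


def _segment_cost_table(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment sum of squared deviation of samples i..j-1
    (summed over dimensions), from cumulative sums."""
    n, d = x.shape
    c1 = np.vstack([np.zeros(d), np.cumsum(x, axis=0)])
    c2 = np.vstack([np.zeros(d), np.cumsum(x * x, axis=0)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + 1, n + 1):
            m = j - i
            s = c1[j] - c1[i]
            ss = c2[j] - c2[i]
            cost[i, j] = float((ss - s * s / m).sum())
    return cost


def segment_phases(
    infl: InfluenceMatrix | pd.DataFrame,
    max_phases: int = 8,
    penalty: float | None = None,
    n_phases: int | None = None,
) -> PhaseSegmentation:
    """Optimal least-squares change-point segmentation of the influence matrix.

    Samples must be in time order. Rows containing undefined entries are
    dropped. For each candidate number of segments k the dynamic program is
    exact; when ``n_phases`` is not fixed, k is chosen to minimize
    cost + penalty * (k - 1) over 1..``max_phases``. The default penalty is
    2 * d * log(n) * s2 (d = number of TF rows, n = number of samples),
    where s2 -- half the median across TFs of the variance of the
    first differences -- estimates the fast within-phase fluctuation scale,
    making the criterion invariant to the units of the influence values.
    """
    vals = infl.values if isinstance(infl, InfluenceMatrix) else infl
    vals = vals.dropna(axis=0)
    x = vals.to_numpy(dtype=float).T  # samples x dims
    n, d = x.shape
    if n < 2:
        raise ValueError("segmentation requires at least 2 samples")
    if max_phases > n:
        raise ValueError(f"max_phases={max_phases} exceeds n_samples={n}")
    if n_phases is not None and n_phases > n:
        raise ValueError(f"n_phases={n_phases} exceeds n_samples={n}")
    kmax = n_phases if n_phases is not None else max_phases
    cost = _segment_cost_table(x)

    # D[k, j] = min cost of splitting the first j samples into k segments
    D = np.full((kmax + 1, n + 1), np.inf)
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for j in range(k, n + 1):
            prev = D[k - 1, k - 1:j] + cost[k - 1:j, j]
            b = int(np.argmin(prev))
            D[k, j] = float(prev[b])
            back[k, j] = b + k - 1
    if n_phases is not None:
        k_best = n_phases
    else:
        if penalty is None:
            s2 = 0.5 * float(np.median(np.var(np.diff(x, axis=0), axis=0)))
            pen = 2.0 * d * np.log(n) * s2
        else:
            pen = penalty
        scores = [D[k, n] + pen * (k - 1) for k in range(1, kmax + 1)]
        k_best = 1 + int(np.argmin(scores))
    # backtrack
    cuts = []
    j = n
    for k in range(k_best, 0, -1):
        i = back[k, j]
        cuts.append(i)
        j = i
    cuts = sorted(cuts)  # first element is 0
    boundaries = [int(c) for c in cuts if c != 0]
    labels = np.zeros(n, dtype=int)
    for b in boundaries:
        labels[b:] += 1
    return PhaseSegmentation(
        boundaries=boundaries,
        labels=(labels + 1).tolist(),
        n_phases=k_best,
        cost=float(D[k_best, n]),
    )


# ---------------------------------------------------------------------------
# robust rank aggregation
# ---------------------------------------------------------------------------

def rho_score(norm_ranks: np.ndarray) -> float:
    """Rho of one item: min over k of P(U_(k) <= r_(k)) for the sorted
    normalized ranks r under the uniform order-statistic null, i.e. the
    Beta(k, n - k + 1) lower tail."""
    r = np.sort(np.asarray(norm_ranks, dtype=float))
    n = r.size
    if n == 0:
        return 1.0
    k = np.arange(1, n + 1)
    return float(beta.cdf(r, k, n - k + 1).min())


def aggregate_ranks(
    infl: InfluenceMatrix | pd.DataFrame,
    samples: list[str] | None = None,
    mode: str = "signed",
    provenance: str = "overall",
) -> pd.DataFrame:
    """Robust rank aggregation of per-sample TF rankings.

    In each selected sample, TFs are ranked descending by signed influence
    (``mode='signed'``: strong activators first) or by absolute influence
    (``mode='absolute'``: strong actors of either sign first); normalized
    rank = rank / list length. A TF with undefined influence in a sample is
    excluded from that sample's list and its list count adjusted. Returns a
    frame sorted by rho ascending (ties: mean normalized rank, then id) with
    columns rho_score, corrected_score (min(1, rho x number of TFs)),
    aggregate_rank and provenance.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    vals = infl.values if isinstance(infl, InfluenceMatrix) else infl
    if samples is not None:
        if not samples:
            raise ValueError("empty sample subset")
        vals = vals[list(samples)]
    tf_ids = sorted(vals.index)
    norm_ranks: dict[str, list[float]] = {t: [] for t in tf_ids}
    for col in vals.columns:
        s = vals[col].dropna()
        if s.empty:
            continue
        key = -s if mode == "signed" else -s.abs()
        # deterministic: value, then id
        ordered = sorted(s.index, key=lambda t: (key[t], t))
        m = len(ordered)
        for rank, t in enumerate(ordered, start=1):
            norm_ranks[t].append(rank / m)
    m_total = len(tf_ids)
    rows = []
    for t in tf_ids:
        r = np.array(norm_ranks[t])
        rho = rho_score(r)
        rows.append(
            {
                "tf": t,
                "rho_score": rho,
                "corrected_score": min(1.0, rho * m_total),
                "n_lists": r.size,
                "mean_norm_rank": float(r.mean()) if r.size else 1.0,
                "provenance": provenance,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["rho_score", "mean_norm_rank", "tf"], kind="mergesort"
    ).reset_index(drop=True)
    out["aggregate_rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# master regulators
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    tf: str
    overlap: int
    target_count: int
    geneset_count: int
    universe_count: int
    p_value: float
    p_bh: float | None = None


def master_regulators(
    grn: GRN,
    gene_set: set[str],
    universe: set[str] | None = None,
    side: str = "all",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of every TF's regulon in a gene set.

    The universe defaults to the genes carrying a selected model. ``side``
    restricts the regulon to activated or repressed targets. Results are
    sorted by p ascending (ties by id) and carry a Benjamini-Hochberg
    column, which is reported but not used for selection.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if side not in ("all", "activated", "repressed"):
        raise ValueError(f"side must be all|activated|repressed, got {side!r}")
    uni = set(universe) if universe is not None else set(grn.models)
    gs = set(gene_set) & uni
    if not gs:
        raise ValueError("gene set has no member inside the universe")
    results = []
    for tf in sorted(grn.regulons):
        Ar, Ir = grn.regulons[tf]
        if side == "activated":
            reg = set(Ar)
        elif side == "repressed":
            reg = set(Ir)
        else:
            reg = set(Ar) | set(Ir)
        reg &= uni
        ov = len(reg & gs)
        p = float(hypergeom.sf(ov - 1, len(uni), len(gs), len(reg))) if reg else 1.0
        results.append(
            EnrichmentResult(
                tf=tf,
                overlap=ov,
                target_count=len(reg),
                geneset_count=len(gs),
                universe_count=len(uni),
                p_value=min(1.0, p),
            )
        )
    if results:
        bh = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, bh):
            r.p_bh = float(q)
    results.sort(key=lambda r: (r.p_value, r.tf))
    return results
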