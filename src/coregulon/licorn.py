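"""Cooperative per-gene regulatory-program inference (h-LICORN style).

The algorithm works in two passes. First, sets of co-regulators are mined
from the discretized TF matrix by an Apriori-style levelwise search: the
*collective state* of a TF set in a sample is the shared state if every
member agrees on one nonzero state, and 0 otherwise, and a set's support is
the fraction of samples with nonzero collective state. Unanimity makes
support anti-monotone in set size, so the search enjoys downward closure.

Second, for each target gene, candidate (activator-set, inhibitor-set)
pairs are ranked by discrete agreement -- the predicted gene state is
sign(a - i) for collective states a, i -- and the surviving candidates are
scored by a sign-constrained least-squares fit of the gene's expression on
the mean expression of each set (activator coefficient >= 0, inhibitor
coefficient <= 0, violating terms refit at zero). The fit score is the
adjusted R-squared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import EvidenceSet, ExpressionMatrix, PipelineConfig, RegulatorList
from .preprocess import DiscreteMatrix

__all__ = [
    "CoregSet",
    "LocalModel",
    "GRN",
    "collective_state",
    "mine_coreg_sets",
    "score_candidate_discrete",
    "select_candidates",
    "fit_local_model",
    "infer_grn",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoregSet:
    """A mined co-regulator set with its collective-state support."""

    members: tuple[str, ...]
    support: float

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class LocalModel:
    """One gene's candidate regulatory program.

    ``discrete_score`` is the normalized mean absolute error of the ternary
    prediction (0 best, 1 worst); ``fit_score`` is the adjusted R-squared of
    the sign-constrained regression; ``evidence_score`` is the fraction of
    within-side cooperative TF pairs backed by PPI evidence; ``merged_score``
    averages the available component scores on [0, 1].
    """

    gene: str
    activators: tuple[str, ...]
    inhibitors: tuple[str, ...]
    discrete_score: float = float("nan")
    fit_score: float | None = None
    evidence_score: float | None = None
    merged_score: float | None = None

    def __post_init__(self):
        self.activators = tuple(sorted(self.activators))
        self.inhibitors = tuple(sorted(self.inhibitors))
        overlap = set(self.activators) & set(self.inhibitors)
        if overlap:
            raise ValueError(f"activators and inhibitors overlap: {sorted(overlap)}")
        if self.gene in self.activators or self.gene in self.inhibitors:
            raise ValueError(f"gene {self.gene!r} cannot regulate itself")

    @property
    def n_regulators(self) -> int:
        return len(self.activators) + len(self.inhibitors)

    def sort_key(self) -> tuple:
        return (self.n_regulators, self.activators, self.inhibitors)


@dataclass
class GRN:
    """Selected local model per gene, with the inverse regulon view per TF."""

    models: dict[str, LocalModel] = field(default_factory=dict)

    @property
    def regulons(self) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
        """TF -> (activated targets A^r, repressed targets I^r), sorted."""
        act: dict[str, list[str]] = {}
        rep: dict[str, list[str]] = {}
        for gene in sorted(self.models):
            m = self.models[gene]
            for tf in m.activators:
                act.setdefault(tf, []).append(gene)
            for tf in m.inhibitors:
                rep.setdefault(tf, []).append(gene)
        out = {}
        for tf in sorted(set(act) | set(rep)):
            out[tf] = (tuple(sorted(act.get(tf, ()))), tuple(sorted(rep.get(tf, ()))))
        return out

    @property
    def n_interactions(self) -> int:
        return sum(m.n_regulators for m in self.models.values())

    def edges(self) -> set[tuple[str, str, str]]:
        """Signed TF->gene edges as (tf, gene, 'activator'|'inhibitor')."""
        out = set()
        for gene, m in self.models.items():
            out.update((tf, gene, "activator") for tf in m.activators)
            out.update((tf, gene, "inhibitor") for tf in m.inhibitors)
        return out

    def summary(self) -> dict[str, int]:
        return {
            "n_genes": len(self.models),
            "n_tfs": len(self.regulons),
            "n_interactions": self.n_interactions,
        }


# ---------------------------------------------------------------------------
# frequent co-regulator mining
# ---------------------------------------------------------------------------

def collective_state(members: tuple[str, ...], disc: DiscreteMatrix) -> np.ndarray:
    """Per-sample collective state of a TF set: the unanimous nonzero state,
    else 0. The empty set is all zeros."""
    n = len(disc.sample_ids)
    if not members:
        return np.zeros(n, dtype=np.int8)
    sub = disc.states.loc[list(members)].to_numpy()
    first = sub[0]
    agree = (sub == first).all(axis=0) & (first != 0)
    return np.where(agree, first, 0).astype(np.int8)


def mine_coreg_sets(
    disc: DiscreteMatrix, min_coreg_support: float, max_coreg: int
) -> list[CoregSet]:
    """Levelwise mining of all TF sets with collective-state support >=
    ``min_coreg_support`` and size <= ``max_coreg``.

    The result is downward-closed and ordered by (size, members).
    ``disc`` must be restricted to TF rows.
    """
    tfs = sorted(disc.gene_ids)
    n = len(disc.sample_ids)
    if not tfs or n == 0:
        return []
    states = {t: disc.states.loc[t].to_numpy().astype(np.int8) for t in tfs}

    out: list[CoregSet] = []
    # level 1
    level: dict[tuple[str, ...], np.ndarray] = {}
    for t in tfs:
        v = states[t]
        sup = float((v != 0).mean())
        if sup >= min_coreg_support:
            level[(t,)] = v
            out.append(CoregSet((t,), sup))
    k = 1
    while level and k < max_coreg:
        nxt: dict[tuple[str, ...], np.ndarray] = {}
        keys = sorted(level)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if a[:-1] != b[:-1]:
                    break  # sorted prefix join: later keys share no prefix
                cand = a + (b[-1],)
                # downward closure: every k-subset must be frequent
                if any(cand[:j] + cand[j + 1:] not in level for j in range(len(cand))):
                    continue
                v = np.where(level[a] == states[cand[-1]], level[a], 0).astype(np.int8)
                sup = float((v != 0).mean())
                if sup >= min_coreg_support:
                    nxt[cand] = v
                    out.append(CoregSet(cand, sup))
        level = nxt
        k += 1
    out.sort(key=lambda s: (len(s.members), s.members))
    return out


# ---------------------------------------------------------------------------
# discrete candidate selection
# ---------------------------------------------------------------------------

def score_candidate_discrete(
    gene_states: np.ndarray,
    A: tuple[str, ...] | CoregSet,
    I: tuple[str, ...] | CoregSet,
    disc: DiscreteMatrix,
) -> float:
    """Normalized discrete disagreement of the program (A, I) with the gene.

    Predicted state per sample is sign(a - i) for the collective states a of
    A and i of I (empty set contributes 0); the score is
    mean(|gene_state - prediction|) / 2, in [0, 1], lower is better.
    """
    mem_a = A.members if isinstance(A, CoregSet) else tuple(A)
    mem_i = I.members if isinstance(I, CoregSet) else tuple(I)
    if set(mem_a) & set(mem_i):
        raise ValueError("activator and inhibitor sets must be disjoint")
    a = collective_state(mem_a, disc)
    i = collective_state(mem_i, disc)
    pred = np.sign(a - i)
    return float(np.abs(np.asarray(gene_states) - pred).mean() / 2.0)


class _CandidateContext:
    """Precomputed collective states, disjointness bitmasks and ordering
    ranks for a fixed list of mined sets (shared across genes)."""

    def __init__(self, sets: list[CoregSet], disc: DiscreteMatrix):
        self.members: list[tuple[str, ...]] = [()] + [s.members for s in sets]
        n_samp = len(disc.sample_ids)
        self.coll = np.zeros((len(self.members), n_samp), dtype=np.int8)
        tf_index = {t: j for j, t in
                    enumerate(sorted({t for m in self.members for t in m}))}
        self.masks = np.zeros(len(self.members), dtype=np.int64)
        self.member_bits: dict[str, int] = tf_index
        for r, mem in enumerate(self.members):
            if mem:
                self.coll[r] = collective_state(mem, disc)
                mk = 0
                for t in mem:
                    mk |= 1 << tf_index[t]
                self.masks[r] = mk
        self.sizes = np.array([len(m) for m in self.members])
        # rank of each member tuple in pure lexicographic order (() first);
        # numeric stand-in for lexicographic tie-breaking
        order = sorted(range(len(self.members)), key=lambda r: self.members[r])
        self.lexrank = np.empty(len(self.members), dtype=np.int64)
        for pos, r in enumerate(order):
            self.lexrank[r] = pos


def select_candidates(
    gene: str,
    sets: list[CoregSet],
    disc: DiscreteMatrix,
    search_thresh: float = 0.5,
    max_candidates: int = 100,
    min_gene_support: float = 0.1,
    _ctx: _CandidateContext | None = None,
) -> list[LocalModel]:
    """Enumerate (activator-set, inhibitor-set) candidates for one gene.

    Pairs are drawn from the mined sets plus the empty set on either side
    (not both); sets containing the gene itself are excluded; members must
    be disjoint. Pairs with discrete score <= ``search_thresh`` are kept and
    truncated to the ``max_candidates`` best, ties broken by fewer
    regulators then lexicographic member lists. Genes whose states are
    nonzero in fewer than ``min_gene_support`` of samples return an empty
    list (the gene is skipped).
    """
    g = disc.row(gene).astype(np.int8)
    if float((g != 0).mean()) < min_gene_support:
        return []
    if _ctx is None or any(gene in m for m in _ctx.members):
        usable = [s for s in sets if gene not in s.members]
        ctx = _CandidateContext(usable, disc)
    else:
        ctx = _ctx
    members, coll, masks = ctx.members, ctx.coll, ctx.masks

    # score all pairs at once: pred[ia, ii, s] = sign(a - i)
    pred = np.sign(coll[:, None, :].astype(np.int16) - coll[None, :, :])
    err = np.abs(g[None, None, :] - pred).mean(axis=2) / 2.0
    disjoint = (masks[:, None] & masks[None, :]) == 0
    disjoint[0, 0] = False  # not both empty
    ok = disjoint & (err <= search_thresh)

    ia_idx, ii_idx = np.nonzero(ok)
    if ia_idx.size == 0:
        return []
    e = err[ia_idx, ii_idx]
    size = ctx.sizes[ia_idx] + ctx.sizes[ii_idx]
    # lexsort: last key is primary -> (err, |A|+|I|, lex(A), lex(I))
    order = np.lexsort((ctx.lexrank[ii_idx], ctx.lexrank[ia_idx], size, e))
    out = []
    for q in order[:max_candidates]:
        out.append(
            LocalModel(
                gene=gene,
                activators=members[ia_idx[q]],
                inhibitors=members[ii_idx[q]],
                discrete_score=float(e[q]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# sign-constrained regression
# ---------------------------------------------------------------------------

def _set_mean(expr: ExpressionMatrix, members: tuple[str, ...]) -> np.ndarray:
    return expr.values.loc[list(members)].to_numpy().mean(axis=0)


def fit_local_model(
    expr: ExpressionMatrix,
    gene: str,
    A: tuple[str, ...],
    I: tuple[str, ...],
) -> float:
    """Adjusted R-squared of the sign-constrained local regression.

    The gene's expression is regressed on an intercept, the mean expression
    of the activator set (coefficient constrained >= 0) and the mean
    expression of the inhibitor set (coefficient <= 0). A violating term is
    refit at zero (dropped); with at most two regressors this active-set
    step is exact. The score is 1 - (1 - R^2)(n - 1)/(n - p - 1) with p the
    number of retained non-intercept terms.
    """
    y = expr.values.loc[gene].to_numpy(dtype=float)
    if y.size < 4:
        raise ValueError("fit_local_model requires at least 4 samples")
    vA = _set_mean(expr, tuple(A)) if A else None
    vI = _set_mean(expr, tuple(I)) if I else None
    return _fit_from_vectors(y, vA, vI, gene=gene)


def _fit_from_vectors(
    y: np.ndarray, vA: np.ndarray | None, vI: np.ndarray | None, gene: str = "?"
) -> float:
    n = y.size
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn(f"zero-variance gene {gene!r}: fit score 0")
        return 0.0

    terms: list[tuple[str, np.ndarray]] = []
    if vA is not None:
        terms.append(("A", vA))
    if vI is not None:
        terms.append(("I", vI))

    while True:
        X = np.column_stack([np.ones(n)] + [v for _, v in terms])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        bad = [
            j for j, (side, _) in enumerate(terms)
            if (side == "A" and beta[j + 1] < 0) or (side == "I" and beta[j + 1] > 0)
        ]
        if not bad:
            break
        # drop the worst violator and refit
        worst = max(bad, key=lambda j: abs(beta[j + 1]))
        terms.pop(worst)
    resid = y - X @ beta
    r2 = 1.0 - float((resid ** 2).sum()) / sst
    p = len(terms)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


# ---------------------------------------------------------------------------
# full inference
# ---------------------------------------------------------------------------

def _constrained_fit_batch(
    iA: np.ndarray,
    iI: np.ndarray,
    n: int,
    sst: float,
    yy: float,
    ys: float,
    My: np.ndarray,
    s: np.ndarray,
    G: np.ndarray,
) -> np.ndarray:
    """Adjusted R-squared of the sign-constrained fit for many candidate
    pairs at once, from sufficient statistics.

    ``My[k]``, ``s[k]`` and ``G[j, k]`` are the per-set statistics
    sum(m_k * y), sum(m_k) and sum(m_j * m_k); index 0 is the empty set.
    Semantics match :func:`fit_local_model` (clip-and-refit active set).
    """
    m = iA.size
    if sst == 0.0:
        return np.zeros(m)

    # single-term fits per set: y ~ 1 + m_k
    nk = G.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_k = G.diagonal() - s * s / n
        cov_k = My - s * ys / n
        c1 = np.where(var_k > 0, cov_k / np.where(var_k > 0, var_k, 1.0), 0.0)
    sse1 = yy - ys * ys / n - c1 * cov_k
    adj1 = 1.0 - (sse1 / sst) * (n - 1) / (n - 2)

    adj_a_only = np.where(c1 >= 0, adj1, 0.0)   # kept as activator or dropped
    adj_i_only = np.where(c1 <= 0, adj1, 0.0)   # kept as inhibitor or dropped

    both = (iA > 0) & (iI > 0)
    out = np.empty(m)
    # one empty side -> single-term path directly
    only_a = (iI == 0) & ~both
    only_i = (iA == 0) & ~both
    out[only_a] = adj_a_only[iA[only_a]]
    out[only_i] = adj_i_only[iI[only_i]]

    if both.any():
        a, i = iA[both], iI[both]
        nb = a.size
        XtX = np.empty((nb, 3, 3))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = s[a]
        XtX[:, 0, 2] = XtX[:, 2, 0] = s[i]
        XtX[:, 1, 1] = G[a, a]
        XtX[:, 1, 2] = XtX[:, 2, 1] = G[a, i]
        XtX[:, 2, 2] = G[i, i]
        Xty = np.stack([np.full(nb, ys), My[a], My[i]], axis=1)
        try:
            beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        except np.linalg.LinAlgError:  # exactly collinear regressors
            beta = (np.linalg.pinv(XtX) @ Xty[..., None])[..., 0]
        sse3 = yy - (beta * Xty).sum(axis=1)
        adj3 = 1.0 - (sse3 / sst) * (n - 1) / (n - 3)
        ba, bi = beta[:, 1], beta[:, 2]
        viol_a, viol_i = ba < 0, bi > 0
        res = adj3.copy()
        # exactly one violation: drop it, fall back to the other single term
        drop_a = (viol_a & ~viol_i) | (viol_a & viol_i & (np.abs(ba) >= np.abs(bi)))
        drop_i = (viol_i & ~viol_a) | (viol_a & viol_i & (np.abs(bi) > np.abs(ba)))
        res[drop_a] = adj_i_only[i[drop_a]]
        res[drop_i] = adj_a_only[a[drop_i]]
        out[both] = res
    return out


def infer_grn(
    expr: ExpressionMatrix,
    disc: DiscreteMatrix,
    tfs: RegulatorList,
    config: PipelineConfig | None = None,
    evidence: EvidenceSet | None = None,
) -> GRN:
    """Infer one selected local model per eligible gene.

    TFs failing the ``min_gene_support`` row filter are excluded as
    regulators; a TF is never a candidate regulator of itself. By default
    only non-TF rows are modeled as targets (``config.include_tf_targets``
    switches TF targets on). Candidate programs are scored by the
    sign-constrained regression, optionally combined with PPI evidence, and
    the merged-score argmax is selected per gene (see
    :mod:`coregulon.evidence`).
    """
    from .evidence import evidence_score, merge_and_select

    config = config or PipelineConfig()
    missing = tfs.missing_from(expr)
    if missing:
        warnings.warn(f"regulator id(s) absent from expression matrix: {missing}")
    present_tfs = sorted(set(tfs.tf_ids) & set(disc.gene_ids))
    nz = (disc.states.loc[present_tfs].to_numpy() != 0).mean(axis=1)
    eligible_tfs = [t for t, f in zip(present_tfs, nz) if f >= config.min_gene_support]

    disc_tf = DiscreteMatrix(disc.states.loc[eligible_tfs])
    mined = mine_coreg_sets(disc_tf, config.min_coreg_support, config.max_coreg)
    log.info("mined %d co-regulator sets from %d eligible TFs", len(mined), len(eligible_tfs))

    if config.include_tf_targets:
        targets = list(disc.gene_ids)
    else:
        targets = [g for g in disc.gene_ids if g not in tfs]

    if list(expr.sample_ids) != list(disc.sample_ids):
        raise ValueError("expression and discrete matrices must share sample order")

    use_ev = evidence is not None and config.use_evidence
    ctx = _CandidateContext(mined, disc)
    members, coll, masks = ctx.members, ctx.coll, ctx.masks
    sizes, lexrank = ctx.sizes, ctx.lexrank
    n = len(expr.sample_ids)

    # sufficient statistics per mined set over the expression samples
    M = np.zeros((len(members), n))
    for r, mem in enumerate(members):
        if mem:
            M[r] = expr.values.loc[list(mem)].to_numpy(dtype=float).mean(axis=0)
    G = M @ M.T
    s_sum = M.sum(axis=1)

    if use_ev:
        n_pairs = np.array([len(m) * (len(m) - 1) // 2 for m in members])
        n_valid = np.zeros(len(members))
        for r, mem in enumerate(members):
            if len(mem) >= 2:
                n_valid[r] = sum(1 for p in combinations(mem, 2) if p in evidence)

    # gene-independent pair structure: discrete predictions and disjointness
    pred = np.sign(coll[:, None, :].astype(np.int16) - coll[None, :, :])
    disjoint = (masks[:, None] & masks[None, :]) == 0
    disjoint[0, 0] = False  # not both empty
    sets_with: dict[str, list[int]] = {}
    for r, mem in enumerate(members):
        for t in mem:
            sets_with.setdefault(t, []).append(r)

    models: dict[str, LocalModel] = {}
    for gene in sorted(targets):
        g = disc.row(gene).astype(np.int8)
        if float((g != 0).mean()) < config.min_gene_support:
            continue
        err = np.abs(g[None, None, :] - pred).mean(axis=2) / 2.0
        ok = disjoint & (err <= config.search_thresh)
        if gene in sets_with:  # a TF never regulates itself
            bad = sets_with[gene]
            ok[bad, :] = False
            ok[:, bad] = False
        ia, ii = np.nonzero(ok)
        if ia.size == 0:
            continue
        e = err[ia, ii]
        size = sizes[ia] + sizes[ii]
        if ia.size > config.max_candidates:
            keep = np.lexsort((lexrank[ii], lexrank[ia], size, e))[: config.max_candidates]
            keep.sort()
            ia, ii, e, size = ia[keep], ii[keep], e[keep], size[keep]

        y = expr.values.loc[gene].to_numpy(dtype=float)
        yy = float(y @ y)
        ysum = float(y.sum())
        sst = yy - ysum * ysum / n
        if sst <= 0.0:
            warnings.warn(f"zero-variance gene {gene!r}: fit score 0")
            sst = 0.0
        fit = _constrained_fit_batch(ia, ii, n, sst, yy, ysum, M @ y, s_sum, G)
        fitc = np.clip(fit, 0.0, 1.0)
        ev_arr = None
        if use_ev:
            denom = n_pairs[ia] + n_pairs[ii]
            ev_arr = np.where(
                denom > 0, (n_valid[ia] + n_valid[ii]) / np.maximum(denom, 1), 0.0
            )
            if config.no_pair_evidence_neutral:
                merged = np.where(denom > 0, (fitc + ev_arr) / 2.0, fitc)
            else:
                merged = (fitc + ev_arr) / 2.0
        else:
            merged = fitc
        best = int(np.lexsort((lexrank[ii], lexrank[ia], size, -merged))[0])
        ev_best: float | None = None
        if use_ev:
            no_pair = (n_pairs[ia[best]] + n_pairs[ii[best]]) == 0
            ev_best = None if (no_pair and config.no_pair_evidence_neutral) \
                else float(ev_arr[best])
        models[gene] = LocalModel(
            gene=gene,
            activators=members[ia[best]],
            inhibitors=members[ii[best]],
            discrete_score=float(e[best]),
            fit_score=float(fit[best]),
            evidence_score=ev_best,
            merged_score=float(merged[best]),
        )
    grn = GRN(models=models)
    if not models:
        warnings.warn("no gene passed min_gene_support: empty GRN")
    s = grn.summary()
    log.info(
        "inferred GRN: %d TFs with targets, %d genes, %d interactions",
        s["n_tfs"], s["n_genes"], s["n_interactions"],
    )
    return grn
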