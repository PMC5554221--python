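"""PPI-evidence scoring, score merging, model selection and enrichment.

Candidate programs are credited for cooperative TF pairs (unordered pairs
within the activator set, plus those within the inhibitor set) that appear
in the protein-protein-interaction evidence; the evidence score is the
validated fraction of those pairs. The final per-gene model maximizes the
unweighted mean of the component scores, and network-level enrichment of
evidence among the realized cooperative pairs is a one-sided
hypergeometric tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

from scipy.stats import hypergeom

from .data import EvidenceSet, RegulatorList
from .licorn import GRN, LocalModel

__all__ = [
    "ScoredSelection",
    "cooperative_pairs",
    "evidence_score",
    "merge_and_select",
    "evidence_enrichment",
]


@dataclass
class ScoredSelection:
    gene: str
    candidates: list[LocalModel]
    chosen_index: int

    @property
    def chosen(self) -> LocalModel:
        return self.candidates[self.chosen_index]


def cooperative_pairs(model: LocalModel) -> set[tuple[str, str]]:
    """Within-side unordered TF pairs of a local model."""
    pairs: set[tuple[str, str]] = set()
    for side in (model.activators, model.inhibitors):
        pairs.update(combinations(sorted(side), 2))
    return pairs


def evidence_score(
    model: LocalModel, evidence: EvidenceSet, neutral_no_pairs: bool = False
) -> float | None:
    """Fraction of the model's cooperative pairs present in the evidence.

    Models with no cooperative pair (fewer than two TFs on both sides)
    score 0 by default; with ``neutral_no_pairs`` they return None and are
    excluded from the merged mean instead.
    """
    pairs = cooperative_pairs(model)
    if not pairs:
        return None if neutral_no_pairs else 0.0
    hit = sum(1 for p in pairs if p in evidence)
    return hit / len(pairs)


def merge_and_select(candidates: list[LocalModel], use_evidence: bool) -> ScoredSelection:
    """Fill merged scores and select the best candidate.

    The fit score (adjusted R-squared) is clamped to [0, 1]; the merged
    score is its mean with the evidence score when evidence is used, else
    the clamped fit score alone. Ties are broken by fewer regulators, then
    lexicographic member lists.
    """
    if not candidates:
        raise ValueError("no candidate model for this gene")
    for m in candidates:
        fitc = min(1.0, max(0.0, m.fit_score if m.fit_score is not None else 0.0))
        parts = [fitc]
        if use_evidence and m.evidence_score is not None:
            parts.append(m.evidence_score)
        m.merged_score = sum(parts) / len(parts)
    best = min(
        range(len(candidates)),
        key=lambda i: (-candidates[i].merged_score, candidates[i].sort_key()),
    )
    return ScoredSelection(
        gene=candidates[0].gene, candidates=candidates, chosen_index=best
    )


def evidence_enrichment(grn: GRN, evidence: EvidenceSet, tfs: RegulatorList) -> float:
    """One-sided hypergeometric enrichment of evidence pairs in the GRN.

    Universe: all C(|TF|, 2) unordered TF pairs. Successes: evidence pairs
    (restricted to the TF list). Draws: the distinct cooperative pairs
    realized across selected models. Returns P(X >= observed overlap).
    """
    t = len(tfs)
    if t < 2:
        raise ValueError("evidence enrichment requires at least 2 TFs")
    universe = t * (t - 1) // 2
    ev = {p for p in evidence.pairs if p[0] in tfs and p[1] in tfs}
    realized: set[tuple[str, str]] = set()
    for m in grn.models.values():
        realized.update(cooperative_pairs(m))
    if not realized:
        warnings.warn("no cooperative pair realized in the GRN: enrichment p = 1")
        return 1.0
    overlap = len(realized & ev)
    return float(hypergeom.sf(overlap - 1, universe, len(ev), len(realized)))
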