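"""Ground-truthed synthetic data with the structure the analysis assumes.

The generator emulates a nitrogen-limitation time course: a monotonically
increasing carbon-to-nitrogen (C/N) ratio over ~26 time points with 3
technical replicates, piecewise phase-structured TF activity (each TF is
"on" in exactly one phase), and target-gene expression produced additively
from the mean expression of a planted co-activator set and a planted
co-inhibitor set plus Gaussian noise. Co-regulator sets are shared across
genes, which plants the cooperativity structure the network stages look
for; a partially covering / partially noisy PPI evidence set can be drawn
from the planted within-side pairs.

Every draw is reproducible from the seed, and :func:`score_recovery`
compares an inferred network against the planted signed edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EvidenceSet, ExpressionMatrix, RegulatorList
from .licorn import GRN

__all__ = [
    "PlantedModel",
    "SyntheticTruth",
    "generate_truth",
    "simulate_expression",
    "simulate_evidence",
    "score_recovery",
]

ACTIVE_LEVEL = 3.0     # TF expression step in its active phase (log2 units)
BASELINE = 8.0         # additive log2 baseline so values look like intensities
CN_START, CN_END = 7.89, 31.0   # C/N molar-ratio ramp of the emulated culture
TIME_START, TIME_END = 110.0, 170.0   # hours


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth regulatory program of one gene."""

    activators: tuple[str, ...]
    inhibitors: tuple[str, ...]
    alpha: float
    beta_a: float   # >= 0
    beta_i: float   # <= 0


@dataclass
class SyntheticTruth:
    """Planted models, phase structure and generative parameters."""

    tf_ids: list[str]
    gene_ids: list[str]
    models: dict[str, PlantedModel]
    phase_of_tf: dict[str, int]
    active_tfs: dict[int, tuple[str, ...]]
    coreg_pool: dict[int, list[tuple[str, ...]]]
    n_timepoints: int
    phase_boundaries: list[int]      # time indices starting phases 2..K
    cn_profile: np.ndarray
    time_h: np.ndarray
    drift: np.ndarray   # (n_tfs x n_timepoints) smooth per-TF drift
    noise_sd: float = 0.1
    replicate_sd: float = 0.05
    seed: int = 0

    @property
    def n_phases(self) -> int:
        return len(self.phase_boundaries) + 1

    def phase_labels(self) -> list[int]:
        """Phase number (1-based) of each time point."""
        lab = np.ones(self.n_timepoints, dtype=int)
        for b in self.phase_boundaries:
            lab[b:] += 1
        return lab.tolist()

    def edges(self) -> set[tuple[str, str, str]]:
        out = set()
        for gene, m in self.models.items():
            out.update((tf, gene, "activator") for tf in m.activators)
            out.update((tf, gene, "inhibitor") for tf in m.inhibitors)
        return out

    def planted_pairs(self) -> set[tuple[str, str]]:
        """Within-side cooperative TF pairs of the planted models."""
        pairs: set[tuple[str, str]] = set()
        for m in self.models.values():
            for side in (m.activators, m.inhibitors):
                pairs.update(combinations(sorted(side), 2))
        return pairs

    def regulator_list(self) -> RegulatorList:
        return RegulatorList(frozenset(self.tf_ids))

    def tf_profiles(self) -> np.ndarray:
        """Noise-free TF expression over time points (n_tfs x n_timepoints):
        an activity step in the TF's phase plus its private smooth drift."""
        labels = np.array(self.phase_labels())
        prof = np.empty((len(self.tf_ids), self.n_timepoints))
        for r, tf in enumerate(self.tf_ids):
            step = np.where(labels == self.phase_of_tf[tf], ACTIVE_LEVEL, 0.0)
            prof[r] = step + self.drift[r]
        return prof

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_timepoints": self.n_timepoints,
            "phase_boundaries": self.phase_boundaries,
            "noise_sd": self.noise_sd,
            "replicate_sd": self.replicate_sd,
            "tf_ids": self.tf_ids,
            "gene_ids": self.gene_ids,
            "phase_of_tf": self.phase_of_tf,
            "active_tfs": {str(k): list(v) for k, v in self.active_tfs.items()},
            "models": {
                g: {
                    "activators": list(m.activators),
                    "inhibitors": list(m.inhibitors),
                    "alpha": m.alpha,
                    "beta_a": m.beta_a,
                    "beta_i": m.beta_i,
                }
                for g, m in sorted(self.models.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _smooth_drift(
    rng: np.random.Generator,
    n_tfs: int,
    n_timepoints: int,
    amp_range: tuple[float, float] = (0.4, 0.7),
    corr_len: float = 1.5,
) -> np.ndarray:
    """Independent smooth per-TF drift signals, centered, with peak
    amplitude drawn from ``amp_range``.

    Gaussian-kernel smoothing of white noise gives each TF a private slow
    fluctuation; independent draws are mutually near-orthogonal, which is
    what makes co-regulator sets with identical phase activity
    statistically distinguishable. Max-normalization bounds the excursion
    so drift never crosses the discretization thresholds on its own.
    """
    from scipy.ndimage import gaussian_filter1d

    amp = rng.uniform(*amp_range, size=n_tfs)
    z = rng.standard_normal((n_tfs, n_timepoints))
    s = gaussian_filter1d(z, sigma=corr_len, axis=1, mode="reflect")
    sd = s.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    # saturating squash: near-telegraph waveform maximizes drift energy
    # under the |drift| <= amp bound that protects the discretization
    s = np.tanh(2.0 * s / sd)
    s = s - s.mean(axis=1, keepdims=True)
    peak = np.abs(s).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return amp[:, None] * s / peak


def generate_truth(
    n_tfs: int = 20,
    n_genes: int = 200,
    coreg_sizes: tuple[int, int] = (2, 3),
    n_phases: int = 4,
    seed: int = 0,
    n_timepoints: int = 26,
) -> SyntheticTruth:
    """Draw a ground truth: phase-partitioned TFs, a shared pool of
    co-regulator sets per phase, and one (activator-set, inhibitor-set)
    program per gene with sign-respecting coefficients.
    """
    lo, hi = min(coreg_sizes), max(coreg_sizes)
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid coreg_sizes range: {coreg_sizes}")
    if n_tfs < hi * 2:
        raise ValueError(
            f"n_tfs={n_tfs} infeasible: need at least 2 x max coreg size ({hi * 2})"
        )
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    if n_timepoints < n_phases:
        raise ValueError("n_timepoints must be >= n_phases")
    rng = np.random.default_rng([seed, 101])
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]

    # round-robin phase assignment keeps phase sizes balanced
    phase_of_tf = {tf: (i % n_phases) + 1 for i, tf in enumerate(tf_ids)}
    active: dict[int, list[str]] = {p: [] for p in range(1, n_phases + 1)}
    for tf, p in phase_of_tf.items():
        active[p].append(tf)
    phase_sizes = {p: len(v) for p, v in active.items()}
    if min(phase_sizes.values()) < hi:
        raise ValueError(
            f"phase TF groups of sizes {phase_sizes} cannot host sets of size {hi}"
        )

    # shared per-phase pool of co-regulator sets -> cooperativity structure
    pool: dict[int, list[tuple[str, ...]]] = {}
    for p in range(1, n_phases + 1):
        phase_tfs = active[p]
        n_sets = max(2, len(phase_tfs) - 1)
        seen: set[tuple[str, ...]] = set()
        sets: list[tuple[str, ...]] = []
        attempts = 0
        while len(sets) < n_sets and attempts < 50 * n_sets:
            attempts += 1
            size = int(rng.integers(lo, hi + 1))
            mem = tuple(sorted(rng.choice(phase_tfs, size=size, replace=False)))
            if mem not in seen:
                seen.add(mem)
                sets.append(mem)
        # every phase TF must appear in at least one set so each TF has a regulon
        covered = {t for st in sets for t in st}
        for t in phase_tfs:
            while t not in covered:
                partner = phase_tfs[int(rng.integers(len(phase_tfs)))]
                if partner == t:
                    continue
                mem = tuple(sorted((t, partner)))
                if mem not in seen:
                    seen.add(mem)
                    sets.append(mem)
                covered.add(t)
        pool[p] = sets

    models: dict[str, PlantedModel] = {}
    phases = list(range(1, n_phases + 1))
    for g in gene_ids:
        pa, pi = rng.choice(phases, size=2, replace=False)
        A = pool[int(pa)][int(rng.integers(len(pool[int(pa)])))]
        I = pool[int(pi)][int(rng.integers(len(pool[int(pi)])))]
        models[g] = PlantedModel(
            activators=A,
            inhibitors=I,
            alpha=float(rng.normal(0.0, 0.3)),
            beta_a=float(rng.uniform(0.6, 0.8)),
            beta_i=-float(rng.uniform(0.6, 0.8)),
        )

    boundaries = [round(p * n_timepoints / n_phases) for p in range(1, n_phases)]
    t = np.arange(n_timepoints)
    cn = CN_START * (CN_END / CN_START) ** (t / max(1, n_timepoints - 1))
    time_h = np.linspace(TIME_START, TIME_END, n_timepoints)
    return SyntheticTruth(
        tf_ids=tf_ids,
        gene_ids=gene_ids,
        models=models,
        phase_of_tf=phase_of_tf,
        active_tfs={p: tuple(v) for p, v in active.items()},
        coreg_pool=pool,
        n_timepoints=n_timepoints,
        phase_boundaries=boundaries,
        cn_profile=cn,
        time_h=time_h,
        drift=_smooth_drift(rng, n_tfs, n_timepoints),
        seed=seed,
    )


def simulate_expression(
    truth: SyntheticTruth,
    n_timepoints: int | None = None,
    n_replicates: int = 3,
    noise_sd: float | None = None,
    replicate_sd: float | None = None,
) -> ExpressionMatrix:
    """Simulate the gene x sample log2 expression matrix.

    TF rows follow the planted piecewise activity plus drift; each gene is
    alpha + beta_A * mean(activators) + beta_I * mean(inhibitors) plus
    N(0, noise_sd^2) biological noise per time point; replicates add
    N(0, replicate_sd^2). Metadata carries time_h, the increasing cn_ratio
    and the replicate group. Samples are ordered time-major
    (t01_r1, t01_r2, ...).
    """
    if n_timepoints is not None and n_timepoints != truth.n_timepoints:
        raise ValueError(
            "n_timepoints differs from the truth's; regenerate the truth instead"
        )
    n_t = truth.n_timepoints
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    noise_sd = truth.noise_sd if noise_sd is None else float(noise_sd)
    replicate_sd = truth.replicate_sd if replicate_sd is None else float(replicate_sd)
    if noise_sd < 0 or replicate_sd < 0:
        raise ValueError("standard deviations must be non-negative")

    rng = np.random.default_rng([truth.seed, 202])
    tf_prof = truth.tf_profiles()
    tf_idx = {tf: r for r, tf in enumerate(truth.tf_ids)}
    gene_prof = np.empty((len(truth.gene_ids), n_t))
    for r, g in enumerate(truth.gene_ids):
        m = truth.models[g]
        ma = tf_prof[[tf_idx[t] for t in m.activators]].mean(axis=0)
        mi = tf_prof[[tf_idx[t] for t in m.inhibitors]].mean(axis=0)
        gene_prof[r] = m.alpha + m.beta_a * ma + m.beta_i * mi
    if noise_sd > 0:
        gene_prof = gene_prof + rng.normal(0.0, noise_sd, size=gene_prof.shape)

    base = np.vstack([tf_prof, gene_prof]) + BASELINE
    ids = truth.tf_ids + truth.gene_ids
    cols: dict[str, np.ndarray] = {}
    meta_rows = {}
    for ti in range(n_t):
        for rep in range(1, n_replicates + 1):
            sid = f"t{ti + 1:02d}_r{rep}"
            col = base[:, ti]
            if replicate_sd > 0:
                col = col + rng.normal(0.0, replicate_sd, size=base.shape[0])
            cols[sid] = col
            meta_rows[sid] = {
                "time_h": float(truth.time_h[ti]),
                "cn_ratio": float(truth.cn_profile[ti]),
                "replicate_group": f"t{ti + 1:02d}",
            }
    values = pd.DataFrame(cols, index=ids)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").loc[list(values.columns)]
    return ExpressionMatrix(values, sample_meta=meta)


def simulate_evidence(
    truth: SyntheticTruth,
    coverage: float = 0.7,
    false_rate: float = 0.3,
    seed: int | None = None,
) -> EvidenceSet:
    """Draw a partially covering, partially spurious PPI evidence set.

    Each planted within-side pair is included with probability ``coverage``;
    ``round(false_rate * n_planted)`` additional pairs are sampled uniformly
    from the non-planted TF pairs.
    """
    if not (0.0 <= coverage <= 1.0) or not (0.0 <= false_rate <= 1.0):
        raise ValueError("coverage and false_rate must be in [0, 1]")
    rng = np.random.default_rng([seed if seed is not None else truth.seed, 303])
    planted = sorted(truth.planted_pairs())
    kept = {p for p in planted if rng.random() < coverage}
    tags = {p: "planted" for p in kept}
    n_false = int(round(false_rate * len(planted)))
    if n_false > 0:
        all_pairs = [p for p in combinations(sorted(truth.tf_ids), 2)
                     if p not in set(planted)]
        take = rng.choice(len(all_pairs), size=min(n_false, len(all_pairs)),
                          replace=False)
        for q in sorted(take):
            kept.add(all_pairs[int(q)])
            tags[all_pairs[int(q)]] = "spurious"
    return EvidenceSet(pairs=kept, source_tag=tags)


def score_recovery(inferred: GRN, truth: SyntheticTruth) -> dict[str, float]:
    """Precision/recall/F1 of inferred signed TF->gene edges vs the truth.

    An edge matches only if TF, gene and side all agree; an empty inferred
    network scores precision = recall = 0 by convention.
    """
    inf_edges = inferred.edges()
    true_edges = truth.edges()
    if not inf_edges:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0,
                "n_inferred": 0, "n_true": len(true_edges)}
    tp = len(inf_edges & true_edges)
    precision = tp / len(inf_edges)
    recall = tp / len(true_edges) if true_edges else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_inferred": len(inf_edges), "n_true": len(true_edges)}
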