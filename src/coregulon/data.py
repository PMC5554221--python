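"""Core containers and file I/O for the co-regulatory network pipeline.

All tabular files are tab-delimited UTF-8; lines starting with ``#`` are
comments. Orderings are deterministic everywhere (lexicographic fallback)
so repeated runs produce byte-identical outputs. Numeric output is written
at 6 significant digits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RegulatorList",
    "EvidenceSet",
    "PipelineConfig",
    "read_expression",
    "read_regulators",
    "read_evidence",
    "write_expression",
    "write_network",
    "fmt",
]

#: numeric formatting used by every writer (6 significant digits)
NUM_FMT = "%.6g"


def fmt(x: float) -> str:
    """Format a number at 6 significant digits; NaN becomes ``NA``."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return NUM_FMT % x


class ExpressionMatrix:
    """Genes x samples matrix of log2 expression with optional sample metadata.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with sample ids as columns. Values must
        be finite; identifiers must be unique.
    sample_meta:
        Optional per-sample table (index = sample id) carrying e.g.
        ``time_h`` (hours), ``cn_ratio`` (mol C / mol N) and
        ``replicate_group``. Used only for ordering and reporting.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifier(s): {dup}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifier(s): {dup}")
        if not np.isfinite(values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
            )
        self.values = values
        if sample_meta is not None:
            unknown = sample_meta.index.difference(values.columns)
            if len(unknown):
                warnings.warn(
                    f"metadata for unknown sample(s) ignored: {sorted(unknown)}"
                )
            sample_meta = sample_meta.reindex(values.columns)
        self.sample_meta = sample_meta

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass(frozen=True)
class RegulatorList:
    """Curated set of transcription-factor identifiers."""

    tf_ids: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "tf_ids", frozenset(self.tf_ids))

    def __contains__(self, tf: str) -> bool:
        return tf in self.tf_ids

    def __len__(self) -> int:
        return len(self.tf_ids)

    def sorted(self) -> list[str]:
        return sorted(self.tf_ids)

    def missing_from(self, expr: ExpressionMatrix) -> list[str]:
        """TF ids absent from the expression matrix (checked at pipeline start)."""
        return sorted(self.tf_ids - set(expr.gene_ids))


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EvidenceSet:
    """Undirected TF-TF evidence pairs (e.g. STRING-style PPI).

    ``pairs`` holds sorted 2-tuples, so (a, b) and (b, a) are one element;
    self-pairs are rejected. ``source_tag`` optionally labels each pair.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    source_tag: dict[tuple[str, str], str] = field(default_factory=dict)
    n_discarded: int = 0

    def __post_init__(self):
        norm = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair not allowed: {a!r}")
            norm.add(_norm_pair(a, b))
        self.pairs = norm
        self.source_tag = {_norm_pair(*p): t for p, t in self.source_tag.items()}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _norm_pair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline.

    Defaults follow the study conditions: ``min_coreg_support`` 0.2,
    ``min_target`` 10. ``discretization_k`` is the symmetric threshold (in
    units of the global standard deviation of the centered matrix).
    """

    min_gene_support: float = 0.1
    min_coreg_support: float = 0.2
    max_coreg: int = 4
    search_thresh: float = 0.5
    max_candidates: int = 20000
    min_target: int = 10
    discretization_k: float = 1.0
    min_common_genes: int = 5
    alpha: float = 0.01
    use_evidence: bool = True
    no_pair_evidence_neutral: bool = False
    include_tf_targets: bool = False
    max_phases: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("min_gene_support", "min_coreg_support", "search_thresh"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("max_coreg", "min_target", "min_common_genes", "max_candidates"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.discretization_k <= 0:
            raise ValueError("discretization_k must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML or JSON mapping; unknown keys are rejected."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, meta_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression table (first column gene id, header row
    of sample ids); optionally join a per-sample metadata table.

    Duplicate gene ids and non-numeric cells are hard errors naming the
    offending location; missing values are not supported.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifier(s) in {path}: {dup}")
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            g = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric expression value at gene {g!r}, sample {col!r}: "
                f"{raw.loc[g, col]!r}"
            )
        if converted.isna().any():
            g = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"missing expression value at gene {g!r}, sample {col!r}")
        num[col] = converted
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
        meta.index = meta.index.astype(str)
    return ExpressionMatrix(num, sample_meta=meta)


def read_regulators(path: str | Path) -> RegulatorList:
    """Read a plain-text regulator list, one identifier per line."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line.split("\t")[0])
    return RegulatorList(frozenset(ids))


def read_evidence(path: str | Path, tfs: RegulatorList) -> EvidenceSet:
    """Read two-column (plus optional score/source) tab-delimited TF pairs.

    Pairs are deduplicated as unordered; self-pairs are dropped with a
    warning; pairs touching an identifier outside ``tfs`` are discarded and
    counted in ``n_discarded``. An empty file yields an empty set.
    """
    pairs: set[tuple[str, str]] = set()
    tags: dict[tuple[str, str], str] = {}
    discarded = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"evidence line with fewer than 2 columns: {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                warnings.warn(f"self-pair dropped from evidence: {a!r}")
                continue
            if a not in tfs or b not in tfs:
                discarded += 1
                continue
            p = _norm_pair(a, b)
            pairs.add(p)
            if len(fields) >= 3:
                tags[p] = fields[2].strip()
    return EvidenceSet(pairs=pairs, source_tag=tags, n_discarded=discarded)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write any DataFrame as TSV with numbers at 6 significant digits."""
    with open(path, "w") as fh:
        fh.write(index_label + "\t" + "\t".join(str(c) for c in df.columns) + "\n")
        for idx, row in zip(df.index, df.itertuples(index=False)):
            cells = [
                fmt(v) if isinstance(v, (float, np.floating)) else str(v)
                for v in row
            ]
            fh.write(str(idx) + "\t" + "\t".join(cells) + "\n")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression (or influence-like) matrix as TSV, 6 sig. digits."""
    write_table(expr.values, path, index_label="gene_id")


def _network_edges(obj) -> list[tuple[str, str, str, float, bool]]:
    """Normalize a GRN or CoopNetwork to (source, target, side, weight, evidence)."""
    rows: list[tuple[str, str, str, float, bool]] = []
    if hasattr(obj, "models"):  # GRN
        for gene in sorted(obj.models):
            m = obj.models[gene]
            w = m.merged_score if m.merged_score is not None else float("nan")
            for tf in sorted(m.activators):
                rows.append((tf, gene, "activator", w, False))
            for tf in sorted(m.inhibitors):
                rows.append((tf, gene, "inhibitor", w, False))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
    elif hasattr(obj, "edges"):  # CoopNetwork
        for e in sorted(obj.edges, key=lambda e: e.pair):
            rows.append((e.pair[0], e.pair[1], "coop", float(e.shared_gene_count), e.evidence_flag))
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize network object of type {type(obj)!r}")
    return rows


def write_network(obj, path: str | Path, format: str = "edge-tsv") -> None:
    """Write a GRN or cooperativity network.

    Formats: ``edge-tsv`` (columns source, target, side, weight,
    evidence_flag), ``graphml`` (GraphML-style XML) and ``json``. Writing the
    same network twice yields byte-identical files.
    """
    rows = _network_edges(obj)
    if format == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tside\tweight\tevidence_flag\n")
            for s, t, side, w, ev in rows:
                fh.write(f"{s}\t{t}\t{side}\t{fmt(w)}\t{int(ev)}\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.DiGraph() if rows and rows[0][2] != "coop" else nx.Graph()
        nodes = sorted({r[0] for r in rows} | {r[1] for r in rows})
        g.add_nodes_from(nodes)
        for s, t, side, w, ev in rows:
            g.add_edge(s, t, side=side, weight=float(fmt(w)) if fmt(w) != "NA" else 0.0,
                       evidence_flag=int(ev))
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "json":
        payload = [
            {"source": s, "target": t, "side": side, "weight": None if fmt(w) == "NA" else float(fmt(w)),
             "evidence_flag": bool(ev)}
            for s, t, side, w, ev in rows
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown network format: {format!r}")
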