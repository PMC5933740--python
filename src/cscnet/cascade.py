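"""Upstream signaling-cascade extraction and scoring.

A cascade is a simple directed path inside one pathway graph from an entry
("beginning") node — a receptor/ligand that initiates signaling — to an
activated TF. All simple paths from every entry node to the TF are
enumerated (cycle-safe, length-capped), scored by the average combined log2
fold change of the path genes with positive combined fold change, and the
top ``top_k`` cascades per TF are kept, pooled across all pathways.

The positivity filter is on the log scale (log2FC > 0, i.e. linear FC > 1):
on the linear scale every fold change is positive and the filter would be
vacuous. With several datasets, each gene's fold changes are combined to a
single value first (mean of the available per-dataset log2FCs by default;
``min`` gives a conservative alternative); genes missing everywhere are
skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .errors import InvalidConfigError
from .types import Cascade, ExpressionProfile, PathwayGraph

logger = logging.getLogger(__name__)

ENTRY_POLICIES = ("declared", "indegree_zero", "declared_else_indegree_zero")
COMBINE_MODES = ("mean", "min")


@dataclass(frozen=True)
class CascadeConfig:
    """Extraction parameters.

    top_k: cascades kept per TF, pooled across pathways (default 3).
    max_path_length: cap on path length in nodes; bounds the exponential
        worst case of simple-path enumeration in cyclic graphs (default 20).
    entry_policy: where cascades may start — declared entry nodes, in-degree-0
        nodes, or declared with in-degree-0 fallback (default).
    combine: how per-dataset log2FCs are merged per gene before scoring.
    """

    top_k: int = 3
    max_path_length: int = 20
    entry_policy: str = "declared_else_indegree_zero"
    combine: str = "mean"

    def __post_init__(self):
        if self.top_k < 1:
            raise InvalidConfigError("top_k must be >= 1")
        if self.max_path_length < 2:
            raise InvalidConfigError("max_path_length must be >= 2")
        if self.entry_policy not in ENTRY_POLICIES:
            raise InvalidConfigError(f"entry_policy must be one of {ENTRY_POLICIES}")
        if self.combine not in COMBINE_MODES:
            raise InvalidConfigError(f"combine must be one of {COMBINE_MODES}")


def entry_nodes(g: PathwayGraph, cfg: CascadeConfig = CascadeConfig()) -> frozenset[str]:
    """Beginning nodes of a pathway under the configured policy.

    May be empty (e.g. a pure cycle with nothing declared); callers skip such
    pathways with a warning.
    """
    indeg0 = frozenset(
        n for n in g.nodes if not any(t == n for _, t in g.edges)
    )
    if cfg.entry_policy == "declared":
        return g.entry_nodes
    if cfg.entry_policy == "indegree_zero":
        return indeg0
    return g.entry_nodes if g.entry_nodes else indeg0


def enumerate_paths(
    g: PathwayGraph, tf: str, cfg: CascadeConfig = CascadeConfig()
) -> list[tuple[str, ...]]:
    """All simple paths from any entry node to ``tf``, at most
    ``max_path_length`` nodes, in lexicographic node-sequence order.

    Returns an empty list when the TF is absent from the pathway (the
    "not within any pathway" state) or when the pathway has no entries.
    """
    if tf not in g.nodes:
        return []
    entries = entry_nodes(g, cfg)
    if not entries:
        logger.warning("pathway %s: no entry nodes; skipped", g.pathway_id)
        return []
    G = g.to_networkx()
    paths: list[tuple[str, ...]] = []
    capped = False
    for entry in sorted(entries):
        if entry == tf:
            continue  # a cascade needs at least one signaling step
        for p in nx.all_simple_paths(G, entry, tf, cutoff=cfg.max_path_length - 1):
            if len(p) == cfg.max_path_length:
                capped = True
            paths.append(tuple(p))
    if capped:
        logger.warning(
            "pathway %s: path enumeration reached max_path_length=%d; "
            "longer cascades to %s may exist",
            g.pathway_id, cfg.max_path_length, tf,
        )
    paths.sort()
    return paths


def combined_fold_change(
    gene: str, profiles: Sequence[ExpressionProfile], combine: str = "mean"
) -> float | None:
    """Merge a gene's available per-dataset log2FCs; None if absent everywhere."""
    vals = [v for v in (p.get(gene) for p in profiles) if v is not None]
    if not vals:
        return None
    return sum(vals) / len(vals) if combine == "mean" else min(vals)


def score_cascade(
    nodes: Sequence[str],
    profiles: Sequence[ExpressionProfile],
    combine: str = "mean",
) -> tuple[float, int]:
    """Average combined log2FC of path genes with positive combined log2FC.

    Returns (score, n_scored); (0.0, 0) when no gene contributes.
    """
    if not nodes:
        raise ValueError("empty node sequence")
    contrib = []
    for gene in nodes:
        c = combined_fold_change(gene, profiles, combine)
        if c is not None and c > 0:
            contrib.append(c)
    if not contrib:
        return 0.0, 0
    return sum(contrib) / len(contrib), len(contrib)


def top_cascades(
    tf: str,
    pathways: Sequence[PathwayGraph],
    profiles: Sequence[ExpressionProfile],
    cfg: CascadeConfig = CascadeConfig(),
) -> list[Cascade]:
    """Best ``top_k`` cascades ending at ``tf``, pooled over all pathways.

    Ordering is total and deterministic: score descending, then shorter
    paths, then pathway id, then lexicographic node sequence. An empty list
    means the TF sits on no pathway cascade.
    """
    pool: list[Cascade] = []
    for g in pathways:
        for nodes in enumerate_paths(g, tf, cfg):
            score, n_scored = score_cascade(nodes, profiles, cfg.combine)
            pool.append(
                Cascade(pathway_id=g.pathway_id, nodes=nodes, score=score,
                        n_scored=n_scored)
            )
    pool.sort(key=lambda c: (-c.score, len(c.nodes), c.pathway_id, c.nodes))
    return pool[: cfg.top_k]
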