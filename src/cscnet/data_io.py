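"""Readers and writers for every external artifact.

Dialects
--------
All tabular files are UTF-8, tab-separated, with a mandatory header row.

* expression:  columns ``gene``, ``log2fc``; empty string or ``NA`` marks a
  missing fold change. Duplicate gene rows (per-probe output of upstream
  tools) are collapsed to the value with maximal ``|log2fc|``.
* regulatory network:  columns ``tf``, ``target``.
* pathway TSV:  columns ``pathway_id``, ``source``, ``target``, optional
  ``interaction``, optional ``is_entry``. A row with ``is_entry`` truthy and
  an empty ``target`` declares ``source`` as an entry node; nodes are
  reconstructed as edge endpoints plus declared entries.
* drug table:  columns ``drug``, ``target``.
* KGML subset:  ``entry`` elements of type ``gene`` become nodes keyed by the
  first comma-separated symbol of their ``graphics`` name; ``relation``
  elements become directed edges entry1 -> entry2 (optional first ``subtype``
  name kept as the interaction label). ``group``/``map``/``compound`` entries
  are ignored with a logged warning, as are relations touching them.

All writers emit canonically sorted rows with ``\\n`` newlines, so output is
byte-stable across runs and platforms. The core network is exported as
GraphML, SIF (with a ``<path>.nodes.tsv`` sidecar carrying node roles, since
SIF itself has no node attributes) or JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

from .errors import FormatError, UsageError
from .types import (
    Cascade,
    CoreNetwork,
    DrugTargetTable,
    EnrichmentResult,
    EnrichmentStat,
    ExpressionProfile,
    PathwayGraph,
    RegulatoryNetwork,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA"}


# ---------------------------------------------------------------------------
# low-level TSV helpers


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError:
        raise FormatError("empty file", path=path) from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns {missing}", path=path)
    return df


def _norm_cell(raw: str, path, line: int, what: str) -> str:
    try:
        return normalize_symbol(raw)
    except ValueError as exc:
        raise FormatError(f"bad {what}: {exc}", path=path, line=line) from None


def _write_rows(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _fmt(x: float) -> str:
    """Canonical numeric formatting for byte-stable tables."""
    return format(float(x), ".6g")


# ---------------------------------------------------------------------------
# expression


def read_expression(path, dataset_id: str) -> ExpressionProfile:
    """Read a per-gene log2 fold-change table.

    Duplicate gene rows are collapsed to the value of maximal absolute
    log2FC (ties to the larger signed value); a gene whose every row is
    missing stays in the universe with no value.
    """
    df = _read_tsv(path, ["gene", "log2fc"])
    best: dict[str, float] = {}
    universe: set[str] = set()
    for i, (gene_raw, fc_raw) in enumerate(zip(df["gene"], df["log2fc"])):
        line = i + 2  # header is line 1
        gene = _norm_cell(gene_raw, path, line, "gene symbol")
        universe.add(gene)
        token = str(fc_raw).strip()
        if token in _MISSING_TOKENS:
            continue
        try:
            value = float(token)
        except ValueError:
            raise FormatError(
                f"non-numeric log2fc {token!r} for gene {gene}", path=path, line=line
            ) from None
        if gene not in best or (abs(value), value) > (abs(best[gene]), best[gene]):
            best[gene] = value
    return ExpressionProfile(
        dataset_id=dataset_id, values=best, universe=frozenset(universe)
    )


def write_expression(profile: ExpressionProfile, path) -> None:
    rows = []
    for gene in sorted(profile.universe):
        v = profile.get(gene)
        rows.append((gene, "NA" if v is None else repr(float(v))))
    _write_rows(path, ("gene", "log2fc"), rows)


# ---------------------------------------------------------------------------
# regulatory network


def read_regulatory_network(path) -> RegulatoryNetwork:
    df = _read_tsv(path, ["tf", "target"])
    if len(df) == 0:
        raise FormatError("network file has no edges", path=path)
    edges = set()
    for i, (tf_raw, tg_raw) in enumerate(zip(df["tf"], df["target"])):
        line = i + 2
        tf = _norm_cell(tf_raw, path, line, "tf symbol")
        tg = _norm_cell(tg_raw, path, line, "target symbol")
        edges.add((tf, tg))
    return RegulatoryNetwork(frozenset(edges))


def write_regulatory_network(net: RegulatoryNetwork, path) -> None:
    _write_rows(path, ("tf", "target"), sorted(net.edges))


# ---------------------------------------------------------------------------
# pathways: TSV dialect


_TRUTHY = {"1", "true", "y", "yes"}


def read_pathway_tsv(path) -> list[PathwayGraph]:
    df = _read_tsv(path, ["pathway_id", "source", "target"])
    if len(df) == 0:
        raise FormatError("pathway file has no rows", path=path)
    has_inter = "interaction" in df.columns
    has_entry = "is_entry" in df.columns
    edges: dict[str, set[tuple[str, str]]] = {}
    labels: dict[str, dict[tuple[str, str], str]] = {}
    entries: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        pid = str(row.pathway_id).strip()
        if not pid:
            raise FormatError("blank pathway_id", path=path, line=line)
        edges.setdefault(pid, set())
        entries.setdefault(pid, set())
        labels.setdefault(pid, {})
        src = _norm_cell(row.source, path, line, "source symbol")
        is_entry = has_entry and str(row.is_entry).strip().lower() in _TRUTHY
        tgt_raw = str(row.target).strip()
        if not tgt_raw:
            if not is_entry:
                raise FormatError(
                    "row with empty target is only valid as an is_entry declaration",
                    path=path,
                    line=line,
                )
            entries[pid].add(src)
            continue
        tgt = _norm_cell(tgt_raw, path, line, "target symbol")
        edges[pid].add((src, tgt))
        if is_entry:
            entries[pid].add(src)
        if has_inter:
            inter = str(row.interaction).strip()
            if inter:
                labels[pid][(src, tgt)] = inter
    out = []
    for pid in sorted(edges):
        nodes = {n for e in edges[pid] for n in e} | entries[pid]
        out.append(
            PathwayGraph(
                pathway_id=pid,
                nodes=frozenset(nodes),
                edges=frozenset(edges[pid]),
                entry_nodes=frozenset(entries[pid]),
                edge_labels=dict(labels[pid]),
            )
        )
    return out


def write_pathway_tsv(pathways: Sequence[PathwayGraph], path) -> None:
    """Write pathways in the TSV dialect (entry declarations first).

    Isolated non-entry nodes are not representable in this dialect.
    """
    rows = []
    for g in sorted(pathways, key=lambda g: g.pathway_id):
        for e in sorted(g.entry_nodes):
            rows.append((g.pathway_id, e, "", "", "1"))
        for s, t in sorted(g.edges):
            rows.append((g.pathway_id, s, t, g.edge_labels.get((s, t), ""), ""))
    _write_rows(path, ("pathway_id", "source", "target", "interaction", "is_entry"), rows)


# ---------------------------------------------------------------------------
# pathways: KGML subset


def read_pathway_kgml(path) -> PathwayGraph:
    """Parse the supported KGML subset into a :class:`PathwayGraph`.

    Only ``entry type="gene"`` and ``relation`` elements are interpreted;
    a gene entry is keyed by the first comma-separated symbol of its
    ``graphics`` name. Entry nodes are left undeclared (inferred at use).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}", path=path) from None
    root = tree.getroot()
    pid = root.get("name") or root.get("title") or path.stem
    id_to_symbol: dict[str, str] = {}
    skipped: set[str] = set()
    nodes: set[str] = set()
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype != "gene":
            if eid is not None:
                skipped.add(eid)
            logger.warning(
                "pathway %s: ignoring entry id=%s of type %r", pid, eid, etype
            )
            continue
        graphics = entry.find("graphics")
        name = (graphics.get("name") if graphics is not None else None) or entry.get(
            "name", ""
        )
        first = name.split(",")[0].replace("...", "").strip()
        if not first:
            raise FormatError(f"gene entry id={eid} has no symbol", path=path)
        symbol = normalize_symbol(first)
        id_to_symbol[eid] = symbol
        nodes.add(symbol)
    edges: set[tuple[str, str]] = set()
    labels: dict[tuple[str, str], str] = {}
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        for eid in (e1, e2):
            if eid not in id_to_symbol and eid not in skipped:
                raise FormatError(
                    f"relation references undeclared entry id {eid!r}", path=path
                )
        if e1 in skipped or e2 in skipped:
            logger.warning(
                "pathway %s: ignoring relation %s->%s touching a non-gene entry",
                pid, e1, e2,
            )
            continue
        edge = (id_to_symbol[e1], id_to_symbol[e2])
        edges.add(edge)
        subtype = rel.find("subtype")
        if subtype is not None and subtype.get("name"):
            labels[edge] = subtype.get("name")
    return PathwayGraph(
        pathway_id=pid,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        entry_nodes=frozenset(),
        edge_labels=labels,
    )


# ---------------------------------------------------------------------------
# drugs


def read_drug_table(path) -> DrugTargetTable:
    df = _read_tsv(path, ["drug", "target"])
    rows = set()
    for i, (d_raw, t_raw) in enumerate(zip(df["drug"], df["target"])):
        line = i + 2
        drug = str(d_raw).strip()
        if not drug:
            raise FormatError("empty drug name", path=path, line=line)
        rows.add((drug, _norm_cell(t_raw, path, line, "target symbol")))
    return DrugTargetTable(frozenset(rows))


def write_drug_table(table: DrugTargetTable, path) -> None:
    _write_rows(path, ("drug", "target"), sorted(table.rows))


# ---------------------------------------------------------------------------
# core network exports


def write_core_network(core: CoreNetwork, path, format: str = "graphml") -> None:
    """Serialize the role-typed core network (GraphML / SIF / JSON).

    Node attribute ``role`` is written in every format; SIF carries roles in
    a ``<path>.nodes.tsv`` sidecar because the format has no node attributes.
    Output is byte-stable: nodes and edges are written in sorted order.
    """
    core.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        g = nx.DiGraph()
        for label, role in core.sorted_nodes():
            g.add_node(label, role=role)
        for s, t, kind in core.sorted_edges():
            g.add_edge(
                s, t, kind=kind,
                provenance=";".join(sorted(core.provenance.get((s, t, kind), ()))),
            )
        text = "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
        path.write_text(text, encoding="utf-8")
    elif format == "sif":
        lines = [f"{s}\t{kind}\t{t}" for s, t, kind in core.sorted_edges()]
        linked = {n for s, t, _ in core.edges for n in (s, t)}
        lines.extend(label for label, _ in core.sorted_nodes() if label not in linked)
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        _write_rows(
            Path(str(path) + ".nodes.tsv"), ("node", "role"), core.sorted_nodes()
        )
    elif format == "json":
        doc = {
            "nodes": [
                {"id": label, "role": role} for label, role in core.sorted_nodes()
            ],
            "edges": [
                {
                    "source": s,
                    "target": t,
                    "kind": kind,
                    "provenance": sorted(core.provenance.get((s, t, kind), ())),
                }
                for s, t, kind in core.sorted_edges()
            ],
        }
        path.write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        raise UsageError(f"unknown core-network format {format!r}")


def read_core_network(path) -> CoreNetwork:
    """Read a JSON core-network export back (inverse of format='json')."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    core = CoreNetwork()
    for n in doc["nodes"]:
        core.nodes[n["id"]] = n["role"]
    for e in doc["edges"]:
        key = (e["source"], e["target"], e["kind"])
        core.edges.add(key)
        core.provenance[key] = frozenset(e.get("provenance", ()))
    core.validate()
    return core


# ---------------------------------------------------------------------------
# result tables


def write_tf_table(
    results: Sequence[EnrichmentResult],
    profiles: Sequence[ExpressionProfile],
    within_pathways: dict[str, bool],
    path,
) -> None:
    """Write the activated-TF table: per-dataset p-value and log2FC columns
    plus a within_pathways flag (whether any retained cascade ends at the TF).
    """
    ids = [p.dataset_id for p in profiles]
    header = (
        ["tf"]
        + [f"p_value_{i}" for i in ids]
        + [f"log2fc_{i}" for i in ids]
        + ["within_pathways"]
    )
    rows = []
    for r in sorted(results, key=lambda r: (r.max_p, r.tf)):
        stats = {s.dataset_id: s for s in r.per_dataset}
        row = [r.tf]
        row += [_fmt(stats[i].p_value) for i in ids]
        for p in profiles:
            v = p.get(r.tf)
            row.append("NA" if v is None else _fmt(v))
        row.append("Y" if within_pathways.get(r.tf, False) else "N")
        rows.append(row)
    _write_rows(path, header, rows)


def read_tf_table(path, profiles: Sequence[ExpressionProfile]) -> list[EnrichmentResult]:
    """Read a TF table back into (count-free) enrichment results.

    Counts k/K/n/N are not serialized in the table; they are restored as
    zeros with the recorded p-values, which is sufficient for assembly.
    """
    ids = [p.dataset_id for p in profiles]
    df = _read_tsv(path, ["tf"] + [f"p_value_{i}" for i in ids])
    out = []
    for row in df.itertuples(index=False):
        stats = tuple(
            EnrichmentStat(i, 0, 0, 0, 0, float(getattr(row, f"p_value_{i}")))
            for i in ids
        )
        out.append(EnrichmentResult(tf=str(row.tf), per_dataset=stats, activated=True))
    return out


def write_cascade_table(cascades: Sequence[Cascade], path) -> None:
    """Cascade table: tf, pathway_id, rank (1-based within each TF, in the
    order cascades were selected), score, n_scored, `->`-joined path."""
    rows = []
    rank: dict[str, int] = {}
    for c in cascades:
        rank[c.tf] = rank.get(c.tf, 0) + 1
        rows.append(
            (c.tf, c.pathway_id, rank[c.tf], repr(float(c.score)), c.n_scored,
             "->".join(c.nodes))
        )
    _write_rows(path, ("tf", "pathway_id", "rank", "score", "n_scored", "path"), rows)


def read_cascade_table(path) -> list[Cascade]:
    df = _read_tsv(path, ["tf", "pathway_id", "rank", "score", "n_scored", "path"])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Cascade(
                pathway_id=str(row.pathway_id),
                nodes=tuple(str(row.path).split("->")),
                score=float(row.score),
                n_scored=int(row.n_scored),
            )
        )
    return out


def write_drug_summary(core: CoreNetwork, path) -> None:
    """Drug table: each overlaid drug with its matched targets, sorted."""
    by_drug: dict[str, set[str]] = {}
    for s, t, kind in core.edges:
        if kind == "targets":
            by_drug.setdefault(s, set()).add(t)
    rows = [(d, " ".join(sorted(ts))) for d, ts in sorted(by_drug.items())]
    _write_rows(path, ("drug", "targets"), rows)
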