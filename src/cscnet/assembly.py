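"""Core-network assembly: merge top cascades, activated TFs, commonly
up-regulated targets, and drug-target links into one role-typed graph.

Node roles mirror the standard rendering of such networks: ``start``
(signaling-initiating genes), ``transduction`` (interior signaling genes),
``tf`` (activated transcription factors), ``target`` (regulon genes up in
every dataset), and ``drug``. When one gene plays several parts the role is
resolved by precedence tf > start > transduction > target, so each label
carries exactly one role. Drugs are overlaid only when they hit the upstream
portion of the network (start/transduction nodes; optionally TFs).
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .errors import ConsistencyError
from .tf_activity import ActivityConfig
from .types import (
    Cascade,
    CoreNetwork,
    DrugTargetTable,
    EnrichmentResult,
    ExpressionProfile,
    RegulatoryNetwork,
    ROLE_PRECEDENCE,
)

logger = logging.getLogger(__name__)

_RANK = {role: i for i, role in enumerate(ROLE_PRECEDENCE)}


def common_up_targets(
    tf: str,
    net: RegulatoryNetwork,
    profiles: Sequence[ExpressionProfile],
    cfg: ActivityConfig = ActivityConfig(),
) -> frozenset[str]:
    """Targets of ``tf`` up-regulated (log2FC >= threshold) in every dataset.

    A missing fold change in any dataset disqualifies the gene.
    """
    thr = cfg.up_log2fc_threshold
    out = set()
    for tg in net.targets(tf):
        vals = [p.get(tg) for p in profiles]
        if all(v is not None and v >= thr for v in vals):
            out.add(tg)
    return frozenset(out)


def _claim_role(roles: dict[str, str], label: str, role: str) -> None:
    prev = roles.get(label)
    if prev is None or _RANK[role] < _RANK[prev]:
        roles[label] = role


def assemble(
    cascades: Sequence[Cascade],
    activated: Sequence[EnrichmentResult],
    net: RegulatoryNetwork,
    profiles: Sequence[ExpressionProfile],
    cfg: ActivityConfig = ActivityConfig(),
) -> CoreNetwork:
    """Build the role-typed core network.

    Cascade edges enter as ``signals`` (provenance: pathway id); each
    activated TF is linked to its commonly up-regulated targets by
    ``regulates`` edges (provenance: "regulon"). Activated TFs with neither
    cascade nor common target are kept as isolated ``tf`` nodes.
    """
    activated_tfs = {r.tf for r in activated}
    for c in cascades:
        if c.tf not in activated_tfs:
            raise ConsistencyError(
                f"cascade in {c.pathway_id} terminates at non-activated TF {c.tf}"
            )
    roles: dict[str, str] = {}
    core = CoreNetwork()
    for tf in activated_tfs:
        _claim_role(roles, tf, "tf")
    for c in cascades:
        _claim_role(roles, c.nodes[0], "start")
        for mid in c.nodes[1:-1]:
            _claim_role(roles, mid, "transduction")
        _claim_role(roles, c.nodes[-1], "tf")
        for s, t in zip(c.nodes, c.nodes[1:]):
            key = (s, t, "signals")
            core.edges.add(key)
            core.provenance[key] = core.provenance.get(key, frozenset()) | {
                c.pathway_id
            }
    for r in sorted(activated, key=lambda r: r.tf):
        for tg in sorted(common_up_targets(r.tf, net, profiles, cfg)):
            _claim_role(roles, tg, "target")
            key = (r.tf, tg, "regulates")
            core.edges.add(key)
            core.provenance[key] = frozenset({"regulon"})
    core.nodes = roles
    core.validate()
    return core


def overlay_drugs(
    core: CoreNetwork,
    drugs: DrugTargetTable,
    include_tf_targets: bool = False,
) -> CoreNetwork:
    """Return a copy of ``core`` with drug nodes overlaid.

    A drug enters iff at least one of its targets is a start or transduction
    node (plus tf nodes when ``include_tf_targets``); each matched (drug,
    gene) pair becomes one ``targets`` edge. Unmatched drugs are omitted.
    """
    eligible_roles = {"start", "transduction"} | (
        {"tf"} if include_tf_targets else set()
    )
    eligible = {n for n, role in core.nodes.items() if role in eligible_roles}
    out = core.copy()
    for drug in sorted(drugs.drugs):
        matched = sorted(drugs.targets_of(drug) & eligible)
        if not matched:
            continue
        if drug in out.nodes and out.nodes[drug] != "drug":
            raise ConsistencyError(
                f"drug label {drug!r} collides with a {out.nodes[drug]} node"
            )
        out.nodes[drug] = "drug"
        for gene in matched:
            key = (drug, gene, "targets")
            out.edges.add(key)
            out.provenance[key] = frozenset({"drug"})
    out.validate()
    return out


def summarize(
    core: CoreNetwork,
    activated: Sequence[EnrichmentResult],
    profiles: Sequence[ExpressionProfile],
    cascades: Sequence[Cascade],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular summaries of an assembled core network.

    Returns (tf_table, drug_table): the activated-TF table with per-dataset
    p-values and log2FCs plus a ``within_pathways`` flag (does any retained
    cascade end at the TF), and the overlaid-drug table with sorted target
    lists.
    """
    ids = [p.dataset_id for p in profiles]
    cascade_tfs = {c.tf for c in cascades}
    rows = []
    for r in sorted(activated, key=lambda r: (r.max_p, r.tf)):
        stats = {s.dataset_id: s for s in r.per_dataset}
        row: dict[str, object] = {"tf": r.tf}
        for i in ids:
            row[f"p_value_{i}"] = stats[i].p_value
        for p in profiles:
            v = p.get(r.tf)
            row[f"log2fc_{p.dataset_id}"] = float("nan") if v is None else v
        row["within_pathways"] = r.tf in cascade_tfs
        rows.append(row)
    tf_cols = (
        ["tf"] + [f"p_value_{i}" for i in ids] + [f"log2fc_{i}" for i in ids]
        + ["within_pathways"]
    )
    tf_table = pd.DataFrame(rows, columns=tf_cols)
    by_drug: dict[str, set[str]] = {}
    for s, t, kind in core.edges:
        if kind == "targets":
            by_drug.setdefault(s, set()).add(t)
    drug_table = pd.DataFrame(
        [(d, " ".join(sorted(ts))) for d, ts in sorted(by_drug.items())],
        columns=["drug", "targets"],
    )
    return tf_table, drug_table
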