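"""Synthetic study generator with planted, recoverable ground truth.

Emulates the four inputs of the analysis — two (or more) fold-change
profiles over a shared gene universe, a TF-target regulatory network, a
collection of directed pathway graphs, and a drug-target table — with known
planted structure so every downstream stage can be validated:

* a subset of TFs is planted as *activated*: their targets are up-regulated
  (log2FC >= 1, linear fold change >= 2) with probability ``p_up_active``
  per dataset, against a background probability ``p_up_background`` for all
  other genes;
* one signaling cascade (entry -> transduction genes -> TF) is embedded per
  active TF in a host pathway, surrounded by decoy nodes and edges (decoy
  cycles allowed, so extractors must tolerate cyclic graphs);
* a configurable fraction of drugs targets genes on the planted cascades.

Regulons (per-TF target sets) are drawn without replacement from a single
shared gene pool and are therefore pairwise disjoint: planted signal then
separates perfectly in the degenerate setting (p_up_active=1,
p_up_background=0) — no non-planted TF has any up-regulated target. Planted
activation is purely a property of the regulon; the TF's **own** fold change
is drawn from the null, mirroring the empirical observation that activated
regulators often show small or missing expression changes.

Up-regulated fold changes are drawn on the log2 scale from a normal
truncated below at 1.0, so the FC >= 2 threshold is meaningful by
construction; null fold changes come from a normal truncated above at 1.0,
so background genes never cross the threshold unless their Bernoulli up-flag
fires. Missingness is independent gene-by-dataset Bernoulli (profiles
contain NA values, as real fold-change tables do).

All generators are pure functions of (config, seed): each stage draws from
its own seed stream, so regenerating any single artifact is reproducible
regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from . import data_io
from .errors import ConsistencyError, InvalidConfigError
from .types import (
    DrugTargetTable,
    ExpressionProfile,
    PathwayGraph,
    RegulatoryNetwork,
)

# per-stage RNG stream tags (combined with the root seed)
_S_NETWORK, _S_TRUTH, _S_PATHWAYS, _S_EXPRESSION, _S_DRUGS = range(5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic generator.

    Defaults plant 5 active TFs out of 50 (mean regulon size 40) over a
    4000-gene universe, with per-dataset up-regulation probability 0.6 for
    active-regulon genes against a 0.1 background, two datasets, and 5%
    missing fold changes. ``p_up_active == p_up_background`` is the null
    (no-signal) mode used for calibration studies.
    """

    n_genes: int = 4000
    n_tfs: int = 50
    targets_per_tf: int = 40
    n_active_tfs: int = 5
    n_datasets: int = 2
    p_up_active: float = 0.6
    p_up_background: float = 0.1
    logfc_up_mean: float = 2.0
    logfc_up_sd: float = 0.6
    logfc_null_sd: float = 0.4
    missing_rate: float = 0.05
    n_pathways: int = 8
    pathway_depth: int = 4
    decoys_per_pathway: int = 6
    n_drugs: int = 20
    fraction_on_cascade: float = 0.7
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes, "n_tfs": self.n_tfs,
            "targets_per_tf": self.targets_per_tf,
            "n_active_tfs": self.n_active_tfs, "n_datasets": self.n_datasets,
            "n_pathways": self.n_pathways, "pathway_depth": self.pathway_depth,
            "decoys_per_pathway": self.decoys_per_pathway, "n_drugs": self.n_drugs,
        }
        for name, v in counts.items():
            if v < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {v}")
        if self.n_genes < 1 or self.n_tfs < 1 or self.targets_per_tf < 1:
            raise InvalidConfigError("n_genes, n_tfs, targets_per_tf must be >= 1")
        probs = {
            "p_up_active": self.p_up_active,
            "p_up_background": self.p_up_background,
            "missing_rate": self.missing_rate,
            "fraction_on_cascade": self.fraction_on_cascade,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0,1], got {v}")
        if self.p_up_active < self.p_up_background:
            raise InvalidConfigError(
                "p_up_active must be >= p_up_background (planted signal, or the "
                "null when equal)"
            )
        if self.n_active_tfs > self.n_tfs:
            raise InvalidConfigError("n_active_tfs must be <= n_tfs")
        if self.n_datasets < 1:
            raise InvalidConfigError("n_datasets must be >= 1")
        if self.targets_per_tf > self.n_genes:
            raise InvalidConfigError("targets_per_tf exceeds the gene universe")
        if self.logfc_up_sd <= 0 or self.logfc_null_sd <= 0:
            raise InvalidConfigError("log2FC standard deviations must be > 0")


@dataclass
class GroundTruth:
    """What was planted: active TFs, embedded cascades, on-cascade drugs."""

    active_tfs: frozenset[str] = frozenset()
    planted_cascades: tuple[tuple[str, ...], ...] = ()
    druggable_nodes: dict[str, frozenset[str]] = field(default_factory=dict)

    def cascade_nodes(self, include_tf: bool = True) -> frozenset[str]:
        out = set()
        for c in self.planted_cascades:
            out.update(c if include_tf else c[:-1])
        return frozenset(out)


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(cfg.seed)), stage])


def gene_labels(cfg: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(cfg.n_genes)]


def tf_labels(cfg: SimulationConfig) -> list[str]:
    return [f"TF{i:03d}" for i in range(cfg.n_tfs)]


def simulate_regulatory_network(cfg: SimulationConfig) -> RegulatoryNetwork:
    """TF-target network with pairwise-disjoint regulons.

    Regulon sizes are Poisson(targets_per_tf), floored at 1; targets are
    allocated without replacement from a permuted shared pool, so a gene
    belongs to at most one regulon and planted signal stays identifiable.
    """
    rng = _rng(cfg, _S_NETWORK)
    pool = list(rng.permutation(gene_labels(cfg)))
    sizes = np.maximum(1, rng.poisson(cfg.targets_per_tf, size=cfg.n_tfs))
    if int(sizes.sum()) > cfg.n_genes:
        raise InvalidConfigError(
            f"regulons require {int(sizes.sum())} genes but the universe has "
            f"{cfg.n_genes}; increase n_genes or decrease n_tfs/targets_per_tf"
        )
    edges = set()
    cursor = 0
    for tf, size in zip(tf_labels(cfg), sizes):
        for g in pool[cursor : cursor + int(size)]:
            edges.add((tf, g))
        cursor += int(size)
    return RegulatoryNetwork(frozenset(edges))


def plant_truth(cfg: SimulationConfig, net: RegulatoryNetwork) -> GroundTruth:
    """Choose the planted active TFs (cascades and drugs are filled later)."""
    rng = _rng(cfg, _S_TRUTH)
    active = rng.choice(sorted(net.tfs), size=cfg.n_active_tfs, replace=False)
    return GroundTruth(active_tfs=frozenset(str(t) for t in active))


def simulate_pathways(
    cfg: SimulationConfig, truth: GroundTruth
) -> list[PathwayGraph]:
    """Layered pathway graphs with one embedded entry->TF cascade per active TF.

    Cascade entry/transduction nodes use fresh labels (ENTRY*/SIG*) disjoint
    from the regulon gene pool. Decoy nodes and edges are added around the
    cascades — including a decoy cycle per pathway when there is room — with
    no edges into cascade nodes, so planted cascades remain the only
    entry->TF paths. Pathways beyond the planted ones are pure decoy graphs.
    Records the planted cascades on ``truth``.
    """
    if cfg.pathway_depth < 2:
        raise InvalidConfigError("pathway_depth must be >= 2")
    if cfg.n_pathways < 1:
        raise InvalidConfigError("n_pathways must be >= 1")
    rng = _rng(cfg, _S_PATHWAYS)
    active = sorted(truth.active_tfs)
    cascades: list[tuple[str, ...]] = []
    per_pathway: dict[int, list[tuple[str, ...]]] = {i: [] for i in range(cfg.n_pathways)}
    sig_counter = 0
    for i, tf in enumerate(active):
        entry = f"ENTRY{i:02d}"
        interior = [f"SIG{sig_counter + j:03d}" for j in range(cfg.pathway_depth - 2)]
        sig_counter += len(interior)
        nodes = tuple([entry] + interior + [tf])
        cascades.append(nodes)
        per_pathway[i % cfg.n_pathways].append(nodes)
    graphs = []
    for i in range(cfg.n_pathways):
        pid = f"PW{i:02d}"
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        entries: set[str] = set()
        for casc in per_pathway[i]:
            nodes.update(casc)
            entries.add(casc[0])
            edges.update(zip(casc, casc[1:]))
        decoys = [f"DEC{i:02d}_{j}" for j in range(cfg.decoys_per_pathway)]
        nodes.update(decoys)
        # sparse random decoy wiring plus a decoy ring (a cycle), so decoys
        # are never isolated and extractors must tolerate cyclic graphs
        for a in decoys:
            for b in decoys:
                if a != b and rng.random() < 0.2:
                    edges.add((a, b))
        if len(decoys) >= 2:
            edges.update(
                (decoys[j], decoys[(j + 1) % len(decoys)])
                for j in range(len(decoys))
            )
        cascade_members = {n for casc in per_pathway[i] for n in casc}
        if len(decoys) == 1 and cascade_members:
            edges.add((min(cascade_members), decoys[0]))
        for n in sorted(cascade_members):
            for b in decoys:
                if rng.random() < 0.15:
                    edges.add((n, b))
        graphs.append(
            PathwayGraph(
                pathway_id=pid,
                nodes=frozenset(nodes),
                edges=frozenset(edges),
                entry_nodes=frozenset(entries),
            )
        )
    truth.planted_cascades = tuple(cascades)
    return graphs


def simulate_expression(
    cfg: SimulationConfig,
    net: RegulatoryNetwork,
    truth: GroundTruth,
) -> list[ExpressionProfile]:
    """Fold-change profiles over a shared universe with planted up-regulation.

    The universe is the gene pool plus the TF labels plus any planted
    cascade nodes already recorded on ``truth``. Targets of active TFs and
    (non-TF) cascade genes are up-regulated with probability ``p_up_active``
    per dataset, everything else with ``p_up_background``; TFs themselves
    draw from the null unless their background flag fires. Missing values
    are injected gene-by-dataset at ``missing_rate``.
    """
    if not truth.active_tfs <= net.tfs:
        raise ConsistencyError("truth.active_tfs must be a subset of network TFs")
    rng = _rng(cfg, _S_EXPRESSION)
    tmap = net.target_map()
    elevated = set()
    for tf in truth.active_tfs:
        elevated.update(tmap.get(tf, ()))
    elevated.update(truth.cascade_nodes(include_tf=False))
    universe = sorted(
        set(gene_labels(cfg)) | set(tf_labels(cfg)) | truth.cascade_nodes()
    )
    is_elevated = np.array([g in elevated for g in universe])
    m = len(universe)
    # up-regulated log2FCs: normal truncated below at 1.0 (FC >= 2 by design)
    a_up = (1.0 - cfg.logfc_up_mean) / cfg.logfc_up_sd
    # null log2FCs: normal truncated above at 1.0 (never crosses the cutoff)
    b_null = 1.0 / cfg.logfc_null_sd
    profiles = []
    for d in range(cfg.n_datasets):
        p_up = np.where(is_elevated, cfg.p_up_active, cfg.p_up_background)
        up = rng.random(m) < p_up
        fc = np.empty(m)
        n_up = int(up.sum())
        fc[up] = truncnorm.rvs(
            a_up, np.inf, loc=cfg.logfc_up_mean, scale=cfg.logfc_up_sd,
            size=n_up, random_state=rng,
        )
        fc[~up] = truncnorm.rvs(
            -np.inf, b_null, loc=0.0, scale=cfg.logfc_null_sd,
            size=m - n_up, random_state=rng,
        )
        missing = rng.random(m) < cfg.missing_rate
        values = {
            g: float(v) for g, v, miss in zip(universe, fc, missing) if not miss
        }
        profiles.append(
            ExpressionProfile(
                dataset_id=f"dataset_{d + 1}",
                values=values,
                universe=frozenset(universe),
            )
        )
    return profiles


def simulate_drug_table(
    cfg: SimulationConfig,
    truth: GroundTruth,
    pathways: Sequence[PathwayGraph],
    fraction_on_cascade: Optional[float] = None,
) -> DrugTargetTable:
    """Drug-target pairs; a fraction of drugs hits planted-cascade genes.

    On-cascade drugs target upstream cascade nodes (entries and transduction
    genes, never the terminal TF) and are recorded in
    ``truth.druggable_nodes``; the rest target decoy pathway genes off every
    planted cascade.
    """
    frac = cfg.fraction_on_cascade if fraction_on_cascade is None else fraction_on_cascade
    if not (0.0 <= frac <= 1.0):
        raise InvalidConfigError("fraction_on_cascade must be in [0,1]")
    rng = _rng(cfg, _S_DRUGS)
    upstream = sorted(truth.cascade_nodes(include_tf=False))
    cascade_all = truth.cascade_nodes()
    off_pool = sorted(
        {n for g in pathways for n in g.nodes} - cascade_all
    ) or [f"OFFT{i:03d}" for i in range(cfg.n_drugs)]
    n_on = int(round(cfg.n_drugs * frac))
    rows = set()
    druggable: dict[str, frozenset[str]] = {}
    for i in range(cfg.n_drugs):
        drug = f"DRUG{i:02d}"
        on = i < n_on
        pool = upstream if on else off_pool
        if not pool:
            raise InvalidConfigError(
                "no cascade genes available to target; generate pathways first"
            )
        k = min(len(pool), 1 + int(rng.random() < 0.3))
        targets = sorted(str(t) for t in rng.choice(pool, size=k, replace=False))
        for t in targets:
            rows.add((drug, t))
        if on:
            druggable[drug] = frozenset(targets)
    truth.druggable_nodes = druggable
    return DrugTargetTable(frozenset(rows))


@dataclass
class SimulatedStudy:
    """A full synthetic study: all four inputs plus the planted truth."""

    config: SimulationConfig
    network: RegulatoryNetwork
    truth: GroundTruth
    pathways: list[PathwayGraph]
    profiles: list[ExpressionProfile]
    drugs: DrugTargetTable


def simulate_all(
    cfg: SimulationConfig, fraction_on_cascade: Optional[float] = None
) -> SimulatedStudy:
    """Generate network, truth, pathways, profiles and drugs in pipeline order."""
    net = simulate_regulatory_network(cfg)
    truth = plant_truth(cfg, net)
    pathways = simulate_pathways(cfg, truth)
    profiles = simulate_expression(cfg, net, truth)
    drugs = simulate_drug_table(cfg, truth, pathways, fraction_on_cascade)
    return SimulatedStudy(cfg, net, truth, pathways, profiles, drugs)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Serialize every input artifact plus the ground-truth JSON; returns the
    mapping of artifact name -> written path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for profile in study.profiles:
        p = outdir / f"expression_{profile.dataset_id}.tsv"
        data_io.write_expression(profile, p)
        paths[f"expression_{profile.dataset_id}"] = str(p)
    p = outdir / "network.tsv"
    data_io.write_regulatory_network(study.network, p)
    paths["network"] = str(p)
    p = outdir / "pathways.tsv"
    data_io.write_pathway_tsv(study.pathways, p)
    paths["pathways"] = str(p)
    p = outdir / "drugs.tsv"
    data_io.write_drug_table(study.drugs, p)
    paths["drugs"] = str(p)
    p = outdir / "ground_truth.json"
    doc = {
        "active_tfs": sorted(study.truth.active_tfs),
        "planted_cascades": [list(c) for c in study.truth.planted_cascades],
        "druggable_nodes": {
            d: sorted(ts) for d, ts in sorted(study.truth.druggable_nodes.items())
        },
    }
    p.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["ground_truth"] = str(p)
    return paths
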