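"""End-to-end orchestration: inputs (real or simulated) -> activated TFs ->
cascades -> core network -> drug overlay -> serialized outputs + manifest.

Every run writes a machine-readable ``manifest.json`` recording the config
hash, input checksums, seed and stage counts, so results can be traced to
their exact inputs; rerunning an identical config yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import data_io
from .assembly import assemble, overlay_drugs, summarize
from .cascade import CascadeConfig, top_cascades
from .errors import CscnetError, InvalidConfigError
from .synthetic_data import SimulationConfig, simulate_all, write_study
from .tf_activity import ActivityConfig, find_activated_tfs
from .types import Cascade, CoreNetwork, EnrichmentResult

logger = logging.getLogger(__name__)

FORMATS = ("json", "graphml", "sif")


class PipelineError(CscnetError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """One config for the whole pipeline.

    Exactly one of {real-input paths, simulation block} must be given. Real
    inputs: ``expression`` (>= 1 TSV paths; dataset ids are the file stems),
    ``network``, ``pathways_tsv`` and/or ``pathways_kgml``, optional
    ``drugs``.
    """

    outdir: str
    expression: tuple[str, ...] = ()
    network: Optional[str] = None
    pathways_tsv: Optional[str] = None
    pathways_kgml: tuple[str, ...] = ()
    drugs: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    cascades: CascadeConfig = field(default_factory=CascadeConfig)
    include_tf_targets: bool = False
    formats: tuple[str, ...] = FORMATS
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self):
        real = bool(self.expression or self.network or self.pathways_tsv
                    or self.pathways_kgml or self.drugs)
        if real and self.simulation is not None:
            raise InvalidConfigError(
                "config must name either real inputs or a simulation block, not both"
            )
        if not real and self.simulation is None:
            raise InvalidConfigError(
                "config must name real inputs or a simulation block"
            )
        if real and not (self.expression and self.network
                         and (self.pathways_tsv or self.pathways_kgml)):
            raise InvalidConfigError(
                "real-input mode requires expression, network and pathway paths"
            )
        for f in self.formats:
            if f not in FORMATS:
                raise InvalidConfigError(f"unknown output format {f!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = dict(doc)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "activity" in kwargs:
            kwargs["activity"] = ActivityConfig(**kwargs["activity"])
        if "cascades" in kwargs:
            kwargs["cascades"] = CascadeConfig(**kwargs["cascades"])
        for key in ("expression", "pathways_kgml", "formats"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class RunResult:
    manifest: dict
    outdir: Path
    core: CoreNetwork
    activated: list[EnrichmentResult]
    cascades: list[Cascade]


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name}: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run(cfg: PipelineConfig) -> RunResult:
    """Execute the full pipeline; returns the result bundle and writes all
    outputs plus the manifest under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_checksums: dict[str, str] = {}
    truth = None

    with _stage("inputs"):
        if cfg.simulation is not None:
            scfg = cfg.simulation
            if cfg.seed is not None:
                scfg = dataclasses.replace(scfg, seed=cfg.seed)
            study = simulate_all(scfg)
            paths = write_study(study, outdir / "inputs")
            input_checksums = {k: _file_sha256(p) for k, p in sorted(paths.items())}
            net, profiles, pathways, drugs = (
                study.network, study.profiles, study.pathways, study.drugs,
            )
            truth = study.truth
        else:
            profiles = [
                data_io.read_expression(p, Path(p).stem) for p in cfg.expression
            ]
            net = data_io.read_regulatory_network(cfg.network)
            pathways = []
            if cfg.pathways_tsv:
                pathways.extend(data_io.read_pathway_tsv(cfg.pathways_tsv))
            for k in cfg.pathways_kgml:
                pathways.append(data_io.read_pathway_kgml(k))
            drugs = data_io.read_drug_table(cfg.drugs) if cfg.drugs else None
            for p in list(cfg.expression) + [cfg.network, cfg.pathways_tsv,
                                             cfg.drugs, *cfg.pathways_kgml]:
                if p:
                    input_checksums[str(p)] = _file_sha256(p)

    with _stage("tf_activity"):
        activated = find_activated_tfs(net, profiles, cfg.activity)

    with _stage("cascades"):
        all_cascades: list[Cascade] = []
        for r in activated:
            all_cascades.extend(top_cascades(r.tf, pathways, profiles, cfg.cascades))

    with _stage("assembly"):
        core = assemble(all_cascades, activated, net, profiles, cfg.activity)
        if drugs is not None:
            core = overlay_drugs(core, drugs, cfg.include_tf_targets)

    with _stage("outputs"):
        for fmt in cfg.formats:
            ext = {"json": "json", "graphml": "graphml", "sif": "sif"}[fmt]
            data_io.write_core_network(core, outdir / f"core_network.{ext}", fmt)
        within = {c.tf for c in all_cascades}
        data_io.write_tf_table(
            activated, profiles, {tf: True for tf in within}, outdir / "tf_table.tsv"
        )
        data_io.write_cascade_table(all_cascades, outdir / "cascade_table.tsv")
        data_io.write_drug_summary(core, outdir / "drug_table.tsv")
        n_drug_nodes = sum(1 for r in core.nodes.values() if r == "drug")
        manifest = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed if cfg.seed is not None
            else (cfg.simulation.seed if cfg.simulation else None),
            "input_checksums": input_checksums,
            "counts": {
                "activated_tfs": len(activated),
                "cascades": len(all_cascades),
                "tfs_within_pathways": len(within),
                "drugs_overlaid": n_drug_nodes,
                "nodes": len(core.nodes),
                "edges": len(core.edges),
            },
        }
        if truth is not None:
            manifest["ground_truth_counts"] = {
                "active_tfs": len(truth.active_tfs),
                "planted_cascades": len(truth.planted_cascades),
                "on_cascade_drugs": len(truth.druggable_nodes),
            }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    return RunResult(
        manifest=manifest, outdir=outdir, core=core,
        activated=list(activated), cascades=all_cascades,
    )
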