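"""Activated-TF inference by hypergeometric enrichment of up-regulated targets.

A transcription factor is called *activated* when its target set (regulon) is
over-represented among up-regulated genes — fold change >= 2, i.e. log2FC >=
1 — in **every** dataset analyzed, by a one-sided Fisher's exact test
(upper-tail hypergeometric) at p <= alpha. The TF's own fold change plays no
role: activated regulators frequently show small or missing expression
changes themselves, which is exactly why regulon enrichment is used instead
of differential expression of the TF.

The 2x2 table per TF and dataset compares the number of up-regulated targets
(k) against the regulon size in the universe (K), given the total number of
up-regulated genes (n) among all genes considered (N). The universe
("all the genes tested") is configurable:

* ``network_and_measured`` (default): genes measured in the dataset that are
  also targets of some TF in the network — keeps K and n commensurable;
* ``measured``: every measured gene;
* ``network``: every network target, measured or not.

No multiple-testing correction is applied by default (raw p <= 0.05 in each
dataset); Benjamini-Hochberg per dataset is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import InvalidConfigError, UsageError
from .types import EnrichmentResult, EnrichmentStat, ExpressionProfile, RegulatoryNetwork

logger = logging.getLogger(__name__)

UNIVERSE_POLICIES = ("network_and_measured", "measured", "network")


@dataclass(frozen=True)
class ActivityConfig:
    """Thresholds for activated-TF inference.

    up_log2fc_threshold: log2 fold-change cutoff for "up-regulated"
        (default 1.0 = linear fold change 2, inclusive).
    alpha: per-dataset significance level (default 0.05, uncorrected).
    universe_policy: what counts as "all the genes tested" (see module doc).
    multiple_testing: None (default) or "bh" for per-dataset
        Benjamini-Hochberg adjustment before thresholding.
    """

    up_log2fc_threshold: float = 1.0
    alpha: float = 0.05
    universe_policy: str = "network_and_measured"
    multiple_testing: Optional[str] = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise InvalidConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not math.isfinite(self.up_log2fc_threshold):
            raise InvalidConfigError("up_log2fc_threshold must be finite")
        if self.universe_policy not in UNIVERSE_POLICIES:
            raise InvalidConfigError(
                f"universe_policy must be one of {UNIVERSE_POLICIES}"
            )
        if self.multiple_testing not in (None, "bh"):
            raise InvalidConfigError("multiple_testing must be None or 'bh'")


def up_regulated_set(
    profile: ExpressionProfile, cfg: ActivityConfig = ActivityConfig()
) -> frozenset[str]:
    """Genes with a present log2FC >= threshold; missing values never qualify."""
    thr = cfg.up_log2fc_threshold
    return frozenset(g for g, v in profile.values.items() if v >= thr)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive of the observed k.

    This is the one-sided Fisher's exact p-value for enrichment: the chance
    of drawing at least k special items (regulon members) in n draws (the
    up-regulated genes) from a pool of N items containing K special ones.
    Returns exactly 1.0 when k == 0.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if k > min(K, n) or K > N or n > N:
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    # clamp away float round-off; the exact tail lies in (0, 1]
    return min(1.0, max(p, float(np.nextafter(0.0, 1.0))))


def universe_for(
    profile: ExpressionProfile, net: RegulatoryNetwork, policy: str
) -> frozenset[str]:
    if policy == "network_and_measured":
        return profile.universe & net.all_targets
    if policy == "measured":
        return profile.universe
    if policy == "network":
        return net.all_targets
    raise InvalidConfigError(f"unknown universe policy {policy!r}")


def _dataset_stat(
    targets: frozenset[str],
    profile: ExpressionProfile,
    universe: frozenset[str],
    cfg: ActivityConfig,
    up: frozenset[str] | None = None,
) -> EnrichmentStat:
    if up is None:
        up = up_regulated_set(profile, cfg) & universe
    K_set = targets & universe
    k = len(K_set & up)
    K = len(K_set)
    n = len(up)
    N = len(universe)
    p = 1.0 if K == 0 else hypergeom_upper_tail(k, K, n, N)
    return EnrichmentStat(profile.dataset_id, k, K, n, N, p)


def test_tf(
    tf: str,
    net: RegulatoryNetwork,
    profiles: Sequence[ExpressionProfile],
    cfg: ActivityConfig = ActivityConfig(),
) -> EnrichmentResult:
    """Per-dataset enrichment of one TF's regulon; activated iff every
    p-value <= alpha. A regulon empty in a universe yields K=0, p=1."""
    if not profiles:
        raise UsageError("at least one expression profile is required")
    targets = net.targets(tf)
    if not targets:
        raise UsageError(f"{tf!r} is not a TF of the network")
    stats = tuple(
        _dataset_stat(targets, p, universe_for(p, net, cfg.universe_policy), cfg)
        for p in profiles
    )
    activated = all(s.p_value <= cfg.alpha for s in stats)
    return EnrichmentResult(tf=tf, per_dataset=stats, activated=activated)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    adj[order] = p[order] * m / np.arange(1, m + 1)
    adj[order] = np.minimum.accumulate(adj[order][::-1])[::-1]
    return np.minimum(adj, 1.0)


def test_all_tfs(
    net: RegulatoryNetwork,
    profiles: Sequence[ExpressionProfile],
    cfg: ActivityConfig = ActivityConfig(),
) -> list[EnrichmentResult]:
    """Enrichment results for every TF of the network (activated or not)."""
    if not profiles:
        raise UsageError("at least one expression profile is required")
    universes = [universe_for(p, net, cfg.universe_policy) for p in profiles]
    ups = [up_regulated_set(p, cfg) & u for p, u in zip(profiles, universes)]
    tmap = net.target_map()
    tfs = sorted(tmap)
    results = []
    for tf in tfs:
        targets = frozenset(tmap[tf])
        stats = tuple(
            _dataset_stat(targets, p, u, cfg, up)
            for p, u, up in zip(profiles, universes, ups)
        )
        results.append(EnrichmentResult(tf=tf, per_dataset=stats, activated=False))
    # significance calls, optionally after per-dataset BH adjustment
    pmat = np.array([[s.p_value for s in r.per_dataset] for r in results])
    if cfg.multiple_testing == "bh" and len(results):
        pmat = np.column_stack([_bh_adjust(pmat[:, j]) for j in range(pmat.shape[1])])
    out = []
    for i, r in enumerate(results):
        activated = bool(np.all(pmat[i] <= cfg.alpha))
        out.append(EnrichmentResult(tf=r.tf, per_dataset=r.per_dataset, activated=activated))
    return out


def find_activated_tfs(
    net: RegulatoryNetwork,
    profiles: Sequence[ExpressionProfile],
    cfg: ActivityConfig = ActivityConfig(),
) -> list[EnrichmentResult]:
    """Activated TFs only, sorted by worst per-dataset p ascending, then label."""
    results = [r for r in test_all_tfs(net, profiles, cfg) if r.activated]
    results.sort(key=lambda r: (r.max_p, r.tf))
    logger.info("activated TFs: %d of %d", len(results), len(net.tfs))
    return results
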