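# Methods

## Model and procedure

`cscnet` infers the core signaling network of a cancer-stem-cell population
from the conjunction of three evidence layers.

**1. TF activity by regulon enrichment.** For TF *t* in dataset *d*, the
2×2 contingency compares up-regulated targets against all targets, given the
up-regulated fraction of the testing universe. With universe size `N`,
up-regulated genes `n`, regulon-in-universe size `K` and up-regulated
targets `k`, the p-value is the inclusive upper tail of the hypergeometric
distribution, `P(X ≥ k)` — the standard one-sided Fisher's exact test for
enrichment. A TF is *activated* iff `p ≤ α` in **every** dataset. This
conjunction across independently sorted CSC populations (e.g. ALDH⁺ and
side-population contrasts) is the method's replication filter: a regulon must
be coordinately up-regulated in each contrast. The TF's own fold change is
deliberately ignored; driver TFs are frequently post-transcriptionally
activated and show small, negative or missing fold changes.

*Up-regulation* means linear fold change ≥ 2, i.e. log2FC ≥ 1, inclusive.
Missing fold changes are first-class: a gene measured without a value can
never count as up-regulated, and a target missing in any dataset cannot be a
"common" target.

*Universe policy.* "All the genes tested" is ambiguous in practice; the
default universe is (genes measured in the dataset) ∩ (genes appearing as
targets in the regulatory network), which keeps `K` and `n` commensurable —
a regulon can only be enriched relative to the space the network can name.
`measured` and `network` policies are available and logged.

*Multiplicity.* The default is the raw per-dataset `α = 0.05` rule; the
across-dataset conjunction already sharpens the familywise behavior
(≈ α² for two independent datasets). An optional per-dataset
Benjamini–Hochberg adjustment (`multiple_testing="bh"`) is provided for
users who prefer explicit FDR control; it is off by default.

**2. Upstream cascades.** A cascade is a simple directed path in one pathway
graph from an entry node to an activated TF. Entry nodes are the declared
pathway beginnings when present, else nodes of in-degree 0 (receptors and
ligands initiating signaling); a pathway with neither is skipped with a
warning. Enumeration uses `networkx.all_simple_paths` per (entry, TF) pair,
which is cycle-safe; an independent recursive-DFS oracle validates it in the
test suite on hundreds of random cyclic graphs.

*Scoring.* Each gene's per-dataset log2FCs are combined (mean of available
values by default; `min` is the conservative alternative); genes with
positive combined log2FC contribute, and the cascade score is the mean of
the contributors. The positivity filter is only meaningful on the log scale
(every linear fold change is positive), so "fold change > 0" is implemented
as log2FC > 0. The top `k = 3` cascades per TF are kept, pooled across all
pathways rather than per pathway — the cap controls the size of one TF's
upstream network, and pooling keeps the global best three regardless of
which map they came from.

*Tie-breaking and bounds.* Ordering is total: score descending, then path
length ascending (shorter mechanisms preferred at equal support), then
pathway id, then lexicographic node sequence — output is reproducible to the
byte. `max_path_length` (default 20 nodes) bounds the exponential worst case
of simple-path enumeration in cyclic graphs; a warning is logged whenever
the cap may have truncated, so silent loss is impossible.

**3. Assembly and drug overlay.** Cascade edges enter the core network as
`signals`; cascade heads get role `start`, interior genes `transduction`,
terminal TFs `tf`. Each activated TF is linked by `regulates` edges to its
targets up-regulated in every dataset (role `target`). When one gene plays
several parts, role precedence is `tf > start > transduction > target`: a
node is colored once, and TF identity anchors the analysis. Activated TFs
with no cascade and no common target remain as isolated `tf` nodes — absence
from pathway maps is reported (`within_pathways = N`), not hidden. A drug is
overlaid iff it targets a `start` or `transduction` node (the upstream
signaling); `include_tf_targets` widens matching to TF nodes. Exports
(GraphML / SIF / JSON / TSV tables) write nodes and edges in sorted order,
so identical inputs give byte-identical files; SIF carries node roles in a
`.nodes.tsv` sidecar because the format itself has no node attributes.

## Synthetic studies and what they do (not) show

The generator emulates the *shape* of the real inputs — two or more
fold-change tables over a shared universe, a TF-target network, cyclic
pathway graphs, a drug-target table — with planted, exactly recoverable
structure. Defaults, chosen to mirror a two-contrast CSC microarray study at
desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 4000 | shared gene universe |
| `n_tfs` / `targets_per_tf` | 50 / 40 | regulon count and mean size (Poisson) |
| `n_active_tfs` | 5 | planted activated TFs |
| `n_datasets` | 2 | independent CSC vs non-CSC contrasts |
| `p_up_active` / `p_up_background` | 0.6 / 0.1 | per-dataset up-probability, active regulon vs background |
| `logfc_up_mean` / `logfc_up_sd` | 2.0 / 0.6 | log2FC of up genes, truncated below at 1.0 |
| `logfc_null_sd` | 0.4 | null log2FC, truncated above at 1.0 |
| `missing_rate` | 0.05 | per-gene, per-dataset NA probability |
| `n_pathways` / `pathway_depth` | 8 / 4 | pathway count; cascade length in nodes |
| `n_drugs` / `fraction_on_cascade` | 20 / 0.7 | drugs; fraction targeting cascade genes |

Design choices that make ground truth exact:

- **Disjoint regulons.** Target sets are drawn without replacement from one
  shared pool, so no gene belongs to two regulons. Under clean signal
  (`p_up_active=1`, `p_up_background=0`) planted activation then separates
  perfectly: no non-planted TF has any up-regulated target. Real TRANSFAC
  regulons overlap heavily; the simplification buys identifiability of the
  planted truth at the cost of realism in between-TF correlation.
- **Truncated fold-change mixtures.** Up-regulated genes draw log2FC from a
  normal truncated below at 1.0; everything else from a normal truncated
  above at 1.0. The FC ≥ 2 threshold is therefore exact by construction;
  threshold sensitivity on noisy borderline genes is *not* exercised.
- **Fresh cascade labels.** Planted cascades use entry/transduction labels
  outside the regulon pool, so cascade recovery and TF recovery cannot
  confound each other.
- **Decoy structure.** Pathways carry decoy nodes with random wiring and a
  decoy ring (a genuine cycle), and cascade→decoy edges, but no edges into
  cascade nodes: extractors must tolerate cycles, while the planted cascade
  remains each pathway's only entry→TF path.
- **Null mode.** `p_up_active == p_up_background` is allowed and is the
  calibration setting (no planted signal); the config otherwise requires
  `p_up_active ≥ p_up_background`.
- **Determinism.** Every stage draws from its own seed stream derived from
  the root seed, so each artifact is reproducible independently of call
  order, and a pipeline rerun is byte-identical.

Passing tests on these studies show the machinery is correct — counts,
p-values, path enumeration, role assignment, serialization — and that the
statistical behavior matches theory (recall/precision of planted TFs, null
rejection rates). They do **not** show that the method's biological output
on real microarray contrasts is right: probe-level noise, regulon overlap,
annotation error and pathway incompleteness are all outside the generative
model.

## Numerical and degenerate-input conventions

- `P(X ≥ 0) = 1` exactly; computed tails are clamped to `(0, 1]` against
  float underflow. The implementation (`scipy.stats.hypergeom.sf`) agrees
  with exact rational enumeration to < 1e-12 for all universes ≤ 12.
- A regulon with no gene in the universe yields `K = 0, p = 1` — never an
  exception — so sparse universes degrade gracefully.
- Duplicate expression rows (per-probe output of upstream tools) collapse to
  the value of maximal |log2FC|, ties to the larger signed value; the rule
  is documented rather than silent.
- Composite regulator names (`TAL1_TCF4`-style) are opaque labels, kept
  verbatim, never split.
- Multi-symbol KGML gene entries are keyed by their first graphics-name
  symbol; non-gene entries (`map`, `group`, compounds) and relations
  touching them are skipped with logged warnings, and relations referencing
  undeclared entry ids are hard, located errors.
- Cascade scores of paths where no gene has positive combined fold change
  are exactly (0.0, 0); such cascades sort last but are not dropped.

## Known limitations

- The per-dataset hypergeometric test is discrete and therefore
  conservative: at regulon sizes around 40 its true size at nominal
  α = 0.05 is ≈ 0.03, not 0.05. This is a property of exact conditional
  tests, not an implementation artifact; the conjunction across datasets
  compounds it (observed two-dataset null rejection ≈ 0.001 at nominal
  0.0025). Users who need exact nominal size would require a randomized or
  mid-p variant, which is deliberately not the default because the inclusive
  tail is the field's standard Fisher convention.
- Edge signs (activation vs inhibition) are carried as labels but ignored by
  path search and scoring; an inhibitory chain scores like an activating
  one.
- Cascades never cross pathway boundaries, and simple-path enumeration above
  `max_path_length` nodes is truncated (with a warning) rather than
  completed.
- No probe→gene annotation mapping, no live KEGG/GEO/DrugBank access: all
  inputs are local files in the documented dialects.
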