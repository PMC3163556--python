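# Methods

## Overview

`drugscout` predicts the biological effects of a small-molecule drug along two
independent arms and reports their agreement.

The **structure arm** starts from a compound's SMILES structure. Likely human
metabolites are generated with empirical biotransformation rules, and the
parent plus metabolites are used as queries in a Tanimoto similarity search
against a compound–target knowledge base. Targets annotated to any
sufficiently similar database compound become the drug's *possible targets*;
that set is then expanded by one hop in a physical protein–protein
interaction (PPI) graph. Possible/expanded target sets of several drugs are
partitioned into common, pairwise-shared ("similar") and unique classes, and
each drug's target set is scored against one or more ontologies by
hypergeometric over-representation.

The **expression arm** calls differentially expressed genes (DEGs) from a
pre-normalized expression matrix for each drug-vs-control contrast and runs
the same over-representation analysis on the DEG lists.

Because the two arms share no inputs — one uses chemical structure and curated
interactions, the other measured transcription — concordance between their
category rankings is independent evidence for a predicted effect. The
concordance report gives top-k overlap (Jaccard), Spearman rank correlation
over shared categories, and the categories significant in both arms.

## Chemistry

**Fingerprints.** Similarity uses hashed linear-fragment fingerprints: all
bond paths of length 1..L (default L = 7) are enumerated and hashed into a
B-bit vector (default B = 1024), via RDKit's path fingerprint with branched
subgraphs disabled; single atoms are additionally hashed by element so a
one-atom molecule still has a nonempty signature. The descriptor string
(`linear-path;L=7;B=1024`) is recorded on every fingerprint: similarity
values are reproducible within this tool, but not numerically comparable to
values produced by other fingerprint schemes — the method depends on the
Tanimoto framework, not a particular fingerprint. The Tanimoto coefficient is
|A∩B|/|A∪B| on the on-bit sets, defined as 0 when both sets are empty.

**Similarity threshold.** Default 0.7, applied to the maximum similarity over
the parent and all its metabolites (one shared threshold; a database compound
similar to several queries is reported once at its maximum). Overridable per
run.

**Metabolism.** Rules are reaction SMARTS with a substructure pre-screen,
loaded from a TSV and fully user-replaceable. The shipped defaults are four
broad phase-I transformations: ester hydrolysis, amide hydrolysis, aromatic
hydroxylation, O-demethylation. Each rule is applied once at every matching
site (one product per site); `max_applications` permits repeated application
within a generation, and a `depth` parameter allows
metabolites-of-metabolites (default: single pass). Products are deduplicated
by canonical SMILES and products identical to the parent are dropped. The
anchor behaviour is that ester hydrolysis of fenofibrate yields fenofibric
acid, its known active metabolite. Stereochemistry-aware rules and
quantitative kinetics are out of scope.

## Knowledge base

Compound structures come from `.smi` files (SMILES, tab, id), interactions
from a TSV (`compound_id`, `protein_id`, `effect`, `directness`), the PPI
graph from a two-column TSV or three-column SIF edge list (undirected,
deduplicated, self-loops dropped with a warning), and ontologies from GMT
files. All loaders sort canonically so results are independent of input row
order, and enforce referential integrity (duplicate compound ids and dangling
interaction rows are errors, with offenders listed).

Proteins and genes share one symbol namespace; an optional two-column mapping
file translates foreign ids at load, dropping unmapped ids with a logged
count. Interactions keep their `direct`/`indirect` annotation but both kinds
are included when collecting possible targets; edge signs on the PPI graph
are not modeled.

## Enrichment

Over-representation uses the one-sided upper-tail hypergeometric probability
P(X ≥ k) for overlap k between the query (restricted to the universe) and a
category, computed through scipy's log-space survival function (stable for
universes up to ~1e5; verified against exact enumeration for all N ≤ 40).
The universe defaults to the union of the ontology's members and can be
overridden (e.g. with the knowledge-base protein space). Categories are
ranked by raw p (ties: larger overlap, then name); Benjamini–Hochberg
adjusted values are reported alongside and used for the "significant in both
arms" call (default level 0.05). Ranked-list (GSEA-style) statistics are
deliberately out of scope.

## Expression arm

Input is a normalized gene-by-sample intensity matrix (e.g. GCRMA output —
normalization itself is outside the package). Preprocessing floors
intensities at 10, removes genes with an absent detection call on every
array (when P/A/M calls are provided), and log2-transforms.

DEG calling applies a three-filter cascade per contrast (n ≥ 2 samples per
group required): a per-gene two-sample Student's t-test on log2 values at
p < 0.01; BH FDR < 5% across genes; and a per-gene Student's t-test at
p < 0.01 within the survivors. The original analysis tool this cascade
mirrors does not specify its "class comparison" statistic beyond a per-gene
test with FDR control, so both the first and third filters are implemented as
the same pooled-variance t-test: the third filter is a documented
near-duplicate, retained so the cascade's structure (and its recorded
per-filter outcomes) is preserved rather than guessing a hidden statistic.
Zero-variance genes receive p = 1.0 rather than an exception. The log2 ratio
is the difference of group means of the floored log2 values.

Finally, significant genes with |log2 ratio| ≥ 1.1 (2.1-fold; inclusive
boundary, applied after the significance filters) are split into up- and
down-regulated lists, which feed the enrichment module and the cross-drug
partition.

## Partition semantics

For k ≥ 2 named sets, each element of the union is classified by its
membership pattern: in all k sets → *common*; in exactly one pair →
that pair's *similar* class; in exactly one set → that drug's *unique*
class. Members of three-or-more-but-not-all sets only exist for k ≥ 4 and go
to a separate *multi* class. The classes are mutually disjoint and cover the
union; this is checked property-style against an independent per-element
classifier in the tests.

## Synthetic study generator

The generator emits every input the pipeline consumes, with ground truth,
as a pure function of a spec (seed included):

- **Compound clusters** are built by scaffold decoration: each cluster gets a
  four-ring scaffold assembled from a cluster-specific disjoint pair of ring
  blocks, and its compounds vary only a small substituent. Within-cluster
  pairwise Tanimoto must reach `cluster_tightness` (default 0.7) and
  between-cluster similarity must stay below 0.5; both are verified
  exhaustively at generation and scaffolds are resampled (bounded retries) on
  violation. Scaffold decoration, rather than random SMILES, keeps the
  clusters chemically meaningful and robust to the fingerprint scheme.
- **Interactions** give each cluster a characteristic disjoint block of
  proteins (default 12); each compound is annotated to 75–100% of its block
  plus up to two off-block proteins.
- The **PPI graph** is Erdős–Rényi with expected degree `graph_degree`
  (default 4) over `n_proteins` (default 300).
- The **ontology** (default 20 categories of size 5–25) contains one planted
  category drawn from cluster 0's target block, so enrichment signal flows
  through the whole compound → target → ontology chain and the end-to-end
  pipeline, not just the enrichment stage, is testable.
- The **expression matrix** shares the protein id space: per treatment group
  (default 5 samples per group, mirroring a typical in-vivo design) the
  drug's cluster-block genes are shifted up by `planted_log2_effect`
  (default 2.0, i.e. 4-fold), topped up with random extra genes of random
  direction to `planted_deg_count` (default 20 of 200 genes), with Gaussian
  log-scale noise σ = 0.25 on a log-normal baseline. A few decoy genes carry
  absent calls on every array to exercise the preprocessing filter.
  `planted_deg_count = 0` yields a null matrix for type-I calibration.

A ready-to-run study (`generate_run_directory` / the `fixtures` CLI command)
plants three query drugs: two from cluster 0 and one from cluster 1, so the
partition must show the two cluster-mates sharing strictly more targets with
each other than either shares with the outlier — the qualitative pattern a
real multi-drug comparison is expected to produce when two drugs act on a
shared axis.

What the generator does *not* emulate: real chemical diversity (thousands of
scaffolds, activity cliffs), curated interaction databases' biases and scale,
scale-free PPI topology, probe-level microarray artifacts, or correlated
gene expression. Passing tests on these fixtures demonstrate that the
machinery is correct and calibrated under its stated model, not that the
biological annotations it would be run with are accurate.

## Numerical and degenerate-input choices

- Tanimoto of two empty fingerprints is 0 by convention (avoids 0/0).
- Hypergeometric p is clamped into (0, 1]; k = 0 gives p = 1 exactly.
- BH adjustment rejects p outside (0, 1].
- Zero-variance genes: p = 1.0 (scipy returns NaN; mapped deterministically).
- Enrichment ties are broken by overlap then category name; similarity ties
  by compound id — all outputs are byte-deterministic under a fixed config
  and seed, and the run manifest records input hashes, parameters, seed and
  tool version.
- Problem sizes in the shipped study (30 compounds, 300 proteins, 20
  categories, 200 genes × 20 samples) are chosen so a full end-to-end run
  completes in seconds while every planted signal remains comfortably
  detectable at the stated noise levels.

## Known limitations

- The fingerprint and rule set are deliberately small and generic; absolute
  similarity values and metabolite coverage will differ from proprietary
  cheminformatics platforms even though the workflow is the same.
- The expression arm assumes approximately Gaussian log-intensities within
  groups and equal variances (pooled t-test); it does not model
  probe-to-gene summarization.
- Concordance is reported descriptively (overlap, Jaccard, Spearman); the
  package does not test the statistical significance of concordance itself.
- Network expansion treats all PPI edges equally; no edge signs, weights, or
  tissue specificity.
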