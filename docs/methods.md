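# Methods

This note documents the models and procedures implemented in `hgtscan`,
their assumptions, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## The index and its conventions

The HGT index of a transcript is `h = max_tau S_tau - S_Metazoa`, the
difference in bits between the best non-metazoan and the best metazoan
homology-search bitscore, with "best" per taxon meaning the maximal
bitscore among the retained top-k hits (k = 5), ties broken by minimal
E-value. A transcript enters the matched set only if its minimum E-value
across all six taxon partitions is at or below `epsilon1` (default 1e-5);
excluded transcripts are counted, never silently dropped.

Two conventions deserve flagging because the procedure is undefined without
them:

* **Absent side contributes 0 bits.** A transcript with no metazoan hit at
  all gets `h` equal to its best non-metazoan bitscore (and so almost
  always classifies as foreign). This is required for the no-metazoan-hit
  transcripts to appear among high-h foreign calls, as the dataset-level
  "fraction of foreign lacking a significant metazoan hit" statistic
  presumes. Absence is represented as a distinct no-hit state throughout;
  it is never conflated with a bitscore of 0, so "no metazoan hit" and
  "weak metazoan hit" remain distinguishable.
* **Boundaries.** `h >= theta` is foreign (the boundary value is foreign),
  `h <= 0` metazoan, in between indeterminate. Theta defaults to 30 bits
  and is a parameter, justified empirically by the ratio curves below, not
  hard-coded into any type.

The alien index `AI = ln(E_Met + c) - ln(E_best_non + c)` (c = 1e-200,
absent E treated as 1) is computed alongside for comparison studies. On
profiles whose E-values are Karlin–Altschul-consistent with their
bitscores, sign(h) = sign(AI); inconsistent inputs can produce
disagreements and are permitted.

Re-analysis at stricter cuts (1e-10, 1e-15) recomputes each per-taxon best
from the hits passing the stricter cut — it does not merely re-filter the
matched set — because a taxon whose only hits are marginal must drop out of
the comparison entirely, changing h, not just membership.

## Threshold justification

For each species the survival curve `pct(h)` is the exact percentage of
matched transcripts with index >= h, on an integer grid over [-200, 200].
The ratio `R(h) = pct1(h)/pct2(h)` between a test species and a background
species is reported pointwise with undefined points (background pct = 0)
flagged as missing, never as 0 or infinity; a plateau diagnostic reports
mean and sd of R over a configurable window (default h in [30, 100]).

Two length-controlled models check that between-species differences are not
assembly artifacts: a binomial GLM of the foreign call on species and
contig length, and an ANCOVA with response `sign(h) * sqrt(|h|)`. The
signed square root is an interpretation: the transform is applied to the
magnitude of h, but the sign is retained so that negative mean responses
remain expressible. The variance decomposition is sequential (type-I) with
length entered first, computed from nested OLS fits because the formula
machinery would otherwise reorder the categorical term ahead of the
covariate. Whether a marginal decomposition was intended is unknowable from
the procedure's description; the sequential choice is labelled in the
output.

## Phylogenetic verification

Trees are consumed, not inferred: inputs are Newick files whose internal
node labels are branch supports (e.g. aLRT values), or per-taxon support
tables. All semantics are unrooted — a "clade" is one side of an edge, and
supports live on edges. For a rooted binary input the root splits one
unrooted edge into two labelled root edges; the label as written annotates
the clade beneath it, so a direct side match takes precedence over a
complement match when both exist.

For the focal transcript, per taxon tau the extractor reports the support
of the best edge with exactly the tau leaves on one side, and of the best
edge with exactly {focal} plus the tau leaves; additionally the best
support of any edge separating the focal leaf from every metazoan leaf (the
evidence for rejecting metazoan monophyly). Group assignment uses
precedence 1, 3, 5, 4, 2:

1. only metazoan hits, or focal-with-Metazoa support >= s_min;
2. (fallback) nothing strongly supported;
3. fewer than `min_nonfocal` (default 3) non-focal leaves, or fewer than 2
   taxa;
4. an edge with support >= s_min separates focal from all metazoan leaves;
5. focal-with-tau support >= s_min for a single non-metazoan taxon.

Group 5 outranks 4 because it is the more specific statement and the groups
are reported as disjoint. An absent support never satisfies a threshold
test. The threshold s_min defaults to 0.75; since "strongly rejected" has
no canonical numeric value, a calibration helper fits s_min by maximising
agreement with a supplied column of recorded classifications.

The neighbour-joining bootstrap builder (`build_support_tree`) is a
deliberately simple stand-in used to exercise this classifier on synthetic
alignments: NJ on p-distances with bootstrap proportions as supports. It is
not a likelihood method, carries no substitution model, and is labelled
accordingly; real analyses should supply externally inferred trees.

## Genome linkage

Alignment chaining is greedy in descending bitscore (ties: ascending
E-value, then ascending transcript start), with four acceptance rules:
E <= `epsilon2` (1e-3); transcript-interval disjointness from previously
accepted matches; alignment strictly longer than `l_min` (40 bp); and same
contig as a previous acceptance OR both this match and a previous
acceptance within `d_end` (1000 bp, inclusive, measured from the nearer
alignment end to the nearer contig end). The first accepted match is exempt
from the fourth rule — otherwise nothing could ever be accepted. Coverage
is the summed accepted transcript-interval length divided by transcript
length.

Overlap is tested on transcript coordinates because coverage is defined
against the transcript and exon chains naturally partition it; a
genomic-coordinate mode is available behind `overlap_on="genome"` since the
original rule statement does not specify which was meant.

Co-localisation: a transcript is "on" a contig if an accepted match lies on
it; for every contig carrying a foreign transcript the report counts
metazoan co-residents and foreign co-residents of a *different* donor
taxon, and globally the fraction of placed foreign transcripts with at
least one such co-resident — the signature that separates integrated
foreign genes from contaminating organisms, whose reads cannot share
contigs with host genes.

## Pathway enrichment

EC calls take the EC number(s) of the best-bitscore *annotated* match
("first-annotated" policy: the literal first row after filtering the hit
list to annotated subjects; a stricter "best-overall" policy that drops
transcripts whose overall best hit is unannotated is available).
Multi-EC subjects contribute all their ECs; partial EC codes with trailing
dashes are distinct from complete codes.

Each EC's colour is a pure function of the set of categories observed for
it: {met} green, {for} red, {ind} grey, {for,ind} pink, {met,ind}
light-green, and any set containing both met and for orange. The
enrichment universe is the N unique ECs present; K of them carry a foreign
contribution (red, pink or orange). Per pathway with n member ECs in the
universe and k of those foreign-contributing, p = P(X >= k) for
X ~ Hypergeometric(N, K, n), BH-corrected across all tested pathways;
pathways with n = 0 are excluded and reported. Pathway membership is
evaluated per pathway against globally unique ECs (an EC in several
pathways counts in each); the alternative multiplicity reading is not
implemented. In the enzyme summary, "foreign-only" counts red ECs and
"shared" counts orange, so the two shares sum to the commonly quoted
foreign-contribution total when pink is empty; the enrichment's foreign set
always includes pink.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes — it
is the study-conditions definition for all tests, not a tuning knob.

* **Lengths**: lognormal with log-mean ln(341) and log-sd 0.73 (matching a
  short-read assembly with median ~341 bp and mean ~445 bp), truncated to
  the observed contig range [118, 3674] bp.
* **Scores**: `S = rate * L + Normal(0, sd)` with rate 0.6 bits/bp against
  the own-lineage partition and 0.3 against the others (sd 2.0). The
  linear length dependence reproduces the length–h correlation that the
  GLM/ANCOVA stage controls for. With these defaults the own/cross
  separation at the minimum length is ~35 bits, more than 10 noise sd, so
  downstream foreign-fraction recovery is essentially noiseless.
* **E-values**: `E = (m n) 2^(-S)` with fixed effective search space
  m n = 4e9, keeping E and S consistent as in Karlin–Altschul statistics.
* **Composition**: foreign fraction 0.10 by default; donor taxa drawn from
  (Eubacteria, Archaea, Fungi, Plantae, Other Eukaryotes) with weights
  (0.59, 0.01, 0.23, 0.06, 0.11). Cross-lineage hits drop out with
  probability 0.3, which yields a realistic share of foreign transcripts
  with no metazoan hit at all.
* **Trees**: the focal leaf nests inside its true donor clade with
  Beta(8, 2) supports; with probability `misleading_rate` (default 0.02)
  it is regrafted into the metazoan clade instead. No support model for
  misleading trees is canonical; regrafting with the same support
  distribution is the implemented choice and the rate is a parameter.
* **Genome**: placed transcripts tile fully as 1–5 exons (each > 40 bp)
  with intron gaps; foreign contaminants (rate 0.10) get no placement;
  placed foreign transcripts share a contig with a metazoan transcript at
  rate 0.80. A small fraction of placements (5%) split two exons across
  two contigs with both break-side segments inside the 1000-bp end window,
  exercising the maximum-intron rule. Cross-contig splits are restricted
  to exactly two exons because arbitrary splits can legitimately lose
  middle exons under the greedy rule order, which would break the
  generator's coverage-equals-truth guarantee.
* **EC maps**: under the null each EC samples its transcripts uniformly
  from the transcriptome; ECs of spiked pathways sample from the foreign
  pool with probability `spike_share` (default 0.9).

One integer seed drives all generators through fixed independent
substreams, so outputs are bit-for-bit reproducible and stage-independent.

What the generator does **not** model: sequence-level evolution (no
alignments, no codon/indel processes), read simulation or assembly,
paralogy, compositional biases, or correlated hits across taxa. Passing
tests therefore demonstrate that the pipeline's rules and statistics are
implemented correctly and recover known structure; they do not certify
performance on real search output, where score noise is not Gaussian and
taxon dropout is not independent.

## Problem sizes and numerics

The default test suite runs the full pipeline at n = 5,000 transcripts
(the scale used for parameter-recovery checks: |f̂ − f| <= 0.015 at
f = 0.10) and smaller studies (n = 300–2,000) elsewhere; replicate-based
calibration checks use 10 replicates at n = 2,000 and the null-FDR check
200 enrichment replicates. Exact-count survival curves and the greedy
chain are deterministic; the only stochastic components are the generators
and the bootstrap stand-in, all seeded. Hypergeometric tails come from
`scipy.stats.hypergeom.sf`, BH from `statsmodels.stats.multitest`;
both are cross-checked against exhaustive enumeration and the literal
step-up rule in the test suite. NJ trees use Biopython's deterministic
implementation. Degenerate inputs fail loudly: empty profiles, zero-variance
ANCOVA responses, all-trimmed alignments, unknown contig lengths needed by
the end-distance rule, and negative E-values are all contract violations
with dedicated error types.

## Known limitations

* Tree inference is out of scope; the NJ stand-in is for synthetic tests
  only.
* The per-transcript replication of published supplementary tables
  requires those tables as TSV exports; they are not redistributed with
  the package (see `tests/test_acceptance.py` for the expected location
  and schema).
* The enrichment universe treats ECs as exchangeable under the null;
  phylogenetic correlation between enzymes of one operon-like acquisition
  is not modelled.
* Exact column headers of published supplementary tables vary; the
  summary-table reader ships a best-effort default dialect and accepts a
  custom column mapping.
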