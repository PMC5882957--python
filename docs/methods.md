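# Methods

## The analysis model

The pipeline treats a multi-tissue time-course experiment as a grid of
conditions: tissues T = {endometrium, ovary, oviduct} crossed with days
D = {0, 3, 6, 9, 12, 15, 18}, with r = 3 replicates per cell.  Per-gene
expression change is summarised as a log2 fold-change profile against
day 0 of the same tissue:

    L(g, t, d) = log2( (mean_r FPKM(g, t, d) + 1) / (mean_r FPKM(g, t, 0) + 1) )

The +1 pseudocount mirrors the log2(FPKM + 1) convention used for all
log-scale transforms in the package.  Replicates are averaged as plain
FPKM means before the ratio; day-0 columns are excluded from the profile
matrix (they are identically zero and would distort correlations).  The
18-dimensional concatenated profile (all tissues, all non-baseline days)
is the object on which gene–gene correlations are computed; this is the
only reading under which edges between genes expressed in different
tissues can arise at all.

### Stringent gene filter

A gene is retained for network construction iff (R1) q < 0.05 in at
least one tissue x day, (R2) it is not an excluded biotype (rRNA by
default) nor a de novo transcript with more than two gene symbols, and
(R3) max |log2FC| >= 3.0.  The exclusion report attributes each removed
gene to its first failing rule (R1 -> R2 -> R3), so the buckets
partition the removed set; the attribution order affects only the
report, never the kept set.  Genes lacking annotation are treated as
keepable (unknown biotype, one symbol).

### PCIT

For every unordered trio {x, y, z} the three first-order partial
correlations are computed,

    r_xy.z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))   (and cyclic),

the trio tolerance is ε = (|r_xy.z/r_xy| + |r_xz.y/r_xz| + |r_yz.x/r_yz|)/3,
and edge (x, y) is flagged non-significant if some z gives
|r_xy| < ε·|r_xz| **and** |r_xy| < ε·|r_yz| (strict inequalities: ties
retain the edge).  With only two genes the single edge is significant.

Numerical guards, needed because planted (and some real) data contain
correlations at exactly ±1:

* a ratio term whose direct correlation is below 1e−12 in magnitude is
  skipped; the tolerance averages the remaining terms, and a trio with
  no valid term imposes no elimination;
* square-root arguments are clamped at 0, and a vanishing partial
  denominator (< 1e−12) yields a partial of 0;
* edges with |r| < 1e−8 are non-significant outright.

The production implementation vectorises over the third gene z
(O(n) passes of O(n²) array work, ~25 s at n = 900 on one CPU);
`pcit_mask_reference` is a literal triple loop over trios with identical
scalar rules, kept as an independent oracle — the two agree entry for
entry on random sample-correlation matrices including degenerate
duplicate/collinear profiles.

### Network, partition, bridging

Significant edges with |r| > 0.90 form the network (edge weight = r;
`threshold_mode="r2"` switches the cut to r² > 0.90).  Each gene is
assigned to the tissue and day of its maximum |log2FC| (ties break by
declared tissue order, then earliest day — the condition column order).
Tissue sub-networks are the induced subgraphs on same-tissue genes minus
nodes with no intra-tissue edge (reported as excluded).  Bridging genes
are genes whose neighbour labels span >= 2 tissues (the gene's own label
is irrelevant); the core network is the subgraph they induce, and bridge
connectivity counts full-network edges with >= 1 bridging endpoint.
Core sub-structure is reported as connected components only — no
community detection is attempted.

### Companion analyses

* k-means on median-centred profiles: seeded k-means++ initialisation,
  Lloyd iterations with lowest-index tie-break, 10 restarts keeping the
  lowest within-cluster sum of squares; deterministic given the seed.
  `choose_k` maximises mean silhouette width over a candidate range
  (ties to the smaller k).  Uniform single-shot initialisation was
  rejected after it converged to bad local optima on a third of seeds.
* PAM: classic build + swap on Euclidean distances; PCA: SVD of the
  column-mean-centred sample matrix on log2(FPKM + 1), unscaled.
* Condition correlations: Pearson between condition columns across a
  declared gene set (>= 3 genes); zero-variance columns are flagged and
  zeroed off-diagonal.
* Enrichment: exact hypergeometric upper tail P[X >= k] (scipy, computed
  in log space), fold enrichment (k/n)/(K/N), BH step-up q-values, and
  the conventional display cut-offs (−log10 p > 1.0, hit count > 3) as
  flags.  The DAVID service's modified (EASE) score and its proprietary
  backgrounds are deliberately not replicated.
* qPCR: ΔCT against the geometric mean of the reference-gene CTs, ΔΔCT
  against a calibrator sample, RQ = 2^−ΔΔCT; concordance between two
  log2FC sets is ordinary least squares plus Pearson r/r².

## The synthetic-data generator

The generator emulates the study design so that every stage has a known
answer.  Its defaults are the study conditions: 3 tissues x 7 days x 3
replicates, peak effect size 4.0 on the log2 scale (above the 3.0
filter cut-off), replicate noise sd 0.5 on the log2 scale, ~890
structured genes plus 100 background genes.

**Archetypes.**  Five temporal programmes, 0 at day 0: endometrial up
and down (days 6–12, peak day 9), ovarian up and down (days 3–12, peak
day 9), and a broad oviductal down-regulation (days 3–18, peak day 12).
Module sizes default to 290/330/192 genes across the three tissues,
mirroring the relative sub-network sizes of the motivating study.

**FPKM model.**  FPKM(g, t, d, rep) = B_g · F_{g,t} · 2^(L(g,t,d) + ε),
with baseline B_g log-normal(6.2, 0.4) (median ≈ 490 FPKM — network
genes are well-expressed, and the mean is set high enough that the +1
pseudocount cannot compress a planted |log2FC| >= 3 below the filter
cut-off even in the low-baseline tail), a per-gene-per-tissue offset
F log-normal(0, 0.6) emulating tissue-specific absolute expression
(this is what makes samples ordinate by tissue in PCA), and
ε ~ N(0, noise_sd) independent per replicate.

**Per-gene variation.**  Each structured gene's profile is scaled by a
magnitude factor u (log-normal sd 0.15, clipped to [1.0, 1.5]) and its
active entries are perturbed multiplicatively (sd 0.05, clipped at
±0.12).  The shape perturbation is essential: exactly duplicated
profiles give correlation matrices with r = 1 blocks, whose PCIT trios
are degenerate (0/0 partials) and behave erratically.  The magnitude
factor is deliberately moderate — strong magnitude spread creates real
Euclidean substructure inside a module, which is a different planted
structure than five shape archetypes.

**Bridging geometry.**  At a |r| > 0.90 threshold a gene cannot be
strongly correlated with pure modules of two tissues simultaneously:
profiles of different tissues live on disjoint condition blocks, so
their directions are nearly orthogonal and cos²θ₁ + cos²θ₂ <= 1 caps
the pair at ~0.71 each.  Cross-tissue edges therefore require *mixture*
genes.  Each bridged tissue pair (endometrium–ovary, endometrium–oviduct,
ovary–oviduct) gets a family of two-archetype mixtures parameterised by
a mixing angle θ from the first tissue's axis:

* a *straddle pair* of bridging slots at θ = 31° and 56.5°, mutually
  correlated above the threshold (the planted bridging genes; 60 by
  default, ~10 genes per slot);
* *connector* genes at θ ≈ 6° and 84°, correlated both with the pure
  module and with the nearer bridging slot, which tie the bridge
  cluster into the tissue sub-networks without themselves acquiring
  cross-tissue neighbours.

Mixtures are rescaled so the dominant-tissue peak equals the effect
size; the resulting dominance gap (peak ratio ≈ 1.9) keeps a bridging
gene's tissue assignment stable under noise.  The angles were fixed at
design time against the measured structural correlations and three
failure channels: noise flipping a bridging gene's tissue label (which
would relabel its module edges as cross-tissue), connectors reaching
across the boundary, and module genes brushing against opposite-label
mixtures.  The ovary enters both of its families with the opposite sign
to the partner tissue (endoUp x ovaryDown, ovaryUp x oviductDown), so
the core genes move oppositely in the ovary — condition columns of the
ovary then anticorrelate with the other tissues' columns over the core
set (mean ≈ −0.3 to −0.4), reproducing the motivating observation.  The
endometrium–oviduct family also pairs opposite signs because same-sign
mixtures lose the mean-centring boost and their straddle correlation
falls below the edge threshold.

**q-values.**  Cuffdiff-style q-values are replaced by a calibrated
surrogate keyed to the planted truth: Uniform(0, 0.01) where the
planted |log2FC| >= 3.0 at that tissue x day, else Uniform(0.2, 1).
This makes the truth-consistency invariant (q < 0.05 iff planted
activity) exact by construction.

**What the generator does not model** — and hence what passing recovery
tests do not establish about real data: read-level sampling, library
size and batch effects, transcript-length bias, correlated noise across
genes, q-values from a genuine differential test, annotation errors,
and any mismatch between the planted mixture geometry and real bridging
biology.  The recovery results validate the pipeline's logic, not the
biological claims.

## Problem sizes and determinism

All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical output
tables, and TSV writers use full 17-digit precision so every on-disk
format round-trips exactly.  The test suite and the acceptance script
run the full design (~890 filtered genes, 63 samples) for the
noise-free check, ten seeds at noise 0.5 for the noisy recovery
averages, 200 random matrices (n <= 30) for the PCIT oracle comparison,
and one 900-gene PCIT run for the scale check — a few minutes in total
on one CPU.

## Known limitations

* PCIT keeps only first-order partials (per its definition); regulatory
  chains longer than one intermediary are not distinguished.
* The max-|log2FC| tissue assignment is a deterministic stand-in for
  the visual cluster-based assignment used in the motivating analysis;
  a majority-cluster alternative would require the clustering stage as
  input and is not implemented.
* Silhouette-based k selection assumes roughly balanced, convex
  clusters; it inherits k-means' bias on elongated shapes.
* The SIF format carries topology only; attributes survive only via the
  side TSV tables or GraphML.
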