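# estronet

Multi-tissue time-course gene co-expression network analysis, built for
integrated reproductive-cycle transcriptomics.  The motivating setting is
the porcine oestrous cycle: endometrium, ovary and oviduct sampled on
days 0, 3, 6, 9, 12, 15 and 18 (three animals per day), with the goal of
finding, beyond the tissue-specific expression programmes, the small set
of *bridging genes* whose co-expression neighbourhood spans two or more
tissues and which form the core network coupling the tissues' cycles.

## What it does

Starting from an FPKM expression matrix and a table of differential
expression calls (log2 fold change vs day 0 plus q-values), the pipeline

1. **filters genes stringently** — a gene enters the network only if it
   is significant (q < 0.05) in at least one tissue x day, is not an
   rRNA or ambiguous multi-symbol de novo transcript, and reaches
   |log2FC| >= 3.0 somewhere;
2. **computes Pearson correlations** between the surviving genes over
   the full (tissue x day) log2FC profile, and applies **PCIT** — the
   partial-correlation-with-information-theory test.  For every gene
   trio {x, y, z} it computes the first-order partials, e.g.
   r_xy·z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),
   a trio tolerance ε = mean of |partial/direct| ratios, and discards
   edge (x, y) if some z satisfies |r_xy| < ε|r_xz| and |r_xy| < ε|r_yz|;
3. **builds the network** from significant edges with |r| > 0.90
   (an r² > 0.90 mode is available), assigns each gene to the tissue and
   day of its maximum |log2FC|, and partitions the graph into
   tissue-specific sub-networks;
4. **extracts bridging genes** — genes whose direct neighbours carry at
   least two distinct tissue labels — and rebuilds the **core network**
   they induce, reporting its connectivity to the rest of the graph;
5. adds the companion analyses: seeded k-means (with silhouette-based
   choice of k) and PAM clustering of expression profiles, sample PCA,
   condition-vs-condition correlation matrices over a gene set,
   per-condition fold-change "wave" summaries, hypergeometric gene-set
   enrichment with Benjamini–Hochberg correction, 2^−ΔΔCT qPCR
   quantification against the geometric mean of reference genes, and
   qPCR/RNA-seq log2FC concordance regression.

Because the real study data are not required, the package ships a
first-class **synthetic-data generator** that emulates the full design —
planted tissue-specific temporal modules (five expression archetypes),
planted bridging and connector genes built as two-archetype mixtures,
background genes, replicate noise, and a calibrated q-value surrogate —
and emits the complete ground truth, so every stage can be scored
(`estronet.synthetic_data.score_recovery`).

## Worked example

```python
import dataclasses
from estronet import SyntheticDesign
from estronet.pipeline import run_recovery

design = dataclasses.replace(SyntheticDesign(), noise_sd=0.0, seed=11)
scores = run_recovery(design)
for key in ("n_kept", "bridging_precision", "bridging_recall",
            "tissue_assignment_accuracy", "n_bridging_detected"):
    print(key, scores[key])
```

prints

```
n_kept 890
bridging_precision 1.0
bridging_recall 1.0
tissue_assignment_accuracy 1.0
n_bridging_detected 60
```

i.e. on a noise-free simulated cycle the three-rule filter keeps exactly
the 890 planted structured genes, every one of the 60 planted bridging
genes is recovered with no false positives, and each module gene is
assigned to its planted tissue.  The partition in
`scores["objects"]["partition"]` holds the three tissue sub-networks and
the core network; with replicate noise at the study level (sd 0.5 on the
log2 scale) bridging precision and recall stay above 0.9 on average.

The same pipeline is scriptable from the shell:

```bash
estronet simulate --out-dir sim --seed 11
estronet filter sim/deg.tsv --out kept.txt --report report.tsv
estronet run-all --out-dir run --seed 11     # full pipeline, YAML-configurable
```

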