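"""Stringent three-rule gene filter selecting genes for network construction.

A gene enters the co-expression network only if it

* R1 -- is significant (q below ``q_max``) in at least one tissue x day;
* R2 -- is not an excluded biotype (rRNA by default) and not a de novo
  transcript mapping to more than two gene symbols;
* R3 -- reaches ``|log2FC| >= min_abs_log2fc`` (default 3.0) in at least
  one tissue x day.

The exclusion report attributes each removed gene to the *first* failing
rule in the order R1, R2, R3, so the per-rule gene lists partition the
removed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .expression_io import validate_deg_table

__all__ = [
    "GCNFilterConfig",
    "GeneAnnotation",
    "FilterReport",
    "gcn_gene_filter",
    "count_degs",
    "read_annotation",
]


@dataclass(frozen=True)
class GCNFilterConfig:
    q_max: float = 0.05
    min_abs_log2fc: float = 3.0
    excluded_biotypes: frozenset[str] = frozenset({"rRNA"})
    exclude_multi_symbol: bool = True
    max_symbols: int = 2  # de novo transcripts with more symbols are dropped

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError(f"q_max must be in (0, 1], got {self.q_max}")
        if self.min_abs_log2fc < 0:
            raise ValueError(f"min_abs_log2fc must be >= 0, got {self.min_abs_log2fc}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: biotype, symbol count, de novo flag.

    Genes absent from the mapping are treated as keepable: biotype
    ``unknown`` with a single symbol, not de novo.
    """

    records: Mapping[str, tuple[str, int, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, (_, n_sym, _) in self.records.items():
            if n_sym < 0:
                raise ValueError(f"gene {gene!r}: symbol count must be >= 0")

    def lookup(self, gene: str) -> tuple[str, int, bool]:
        return self.records.get(gene, ("unknown", 1, False))


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read an annotation TSV with columns gene, biotype, n_symbols, is_de_novo."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "biotype": str})
    records = {
        r["gene"]: (r["biotype"], int(r["n_symbols"]), bool(r["is_de_novo"]))
        for _, r in df.iterrows()
    }
    return GeneAnnotation(records)


@dataclass
class FilterReport:
    """Per-rule lists of removed genes (first-failing-rule attribution)."""

    removed_r1_no_significance: list[str]
    removed_r2_annotation: list[str]
    removed_r3_low_fold_change: list[str]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (g, rule)
            for rule, genes in (
                ("R1_no_significance", self.removed_r1_no_significance),
                ("R2_annotation", self.removed_r2_annotation),
                ("R3_low_fold_change", self.removed_r3_low_fold_change),
            )
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["gene", "rule"])

    @property
    def removed(self) -> set[str]:
        return (
            set(self.removed_r1_no_significance)
            | set(self.removed_r2_annotation)
            | set(self.removed_r3_low_fold_change)
        )


def gcn_gene_filter(
    deg: pd.DataFrame,
    annotation: GeneAnnotation | None = None,
    config: GCNFilterConfig | None = None,
) -> tuple[list[str], FilterReport]:
    """Apply the three-rule filter; returns (kept genes, exclusion report).

    Kept genes preserve their order of first appearance in the DEG table.
    """
    deg = validate_deg_table(deg)
    annotation = annotation or GeneAnnotation()
    config = config or GCNFilterConfig()

    best = deg.groupby("gene", sort=False).agg(
        min_q=("q", "min"), max_abs_fc=("log2fc", lambda s: s.abs().max())
    )
    kept: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    r3: list[str] = []
    for gene in dict.fromkeys(deg["gene"]):
        min_q = best.at[gene, "min_q"]
        max_fc = best.at[gene, "max_abs_fc"]
        biotype, n_symbols, de_novo = annotation.lookup(gene)
        if not min_q < config.q_max:
            r1.append(gene)
        elif biotype in config.excluded_biotypes or (
            config.exclude_multi_symbol and de_novo and n_symbols > config.max_symbols
        ):
            r2.append(gene)
        elif not max_fc >= config.min_abs_log2fc:
            r3.append(gene)
        else:
            kept.append(gene)
    return kept, FilterReport(r1, r2, r3)


def count_degs(
    deg: pd.DataFrame, q_max: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition DEG counts and same-day pairwise tissue overlaps.

    Returns ``(counts, overlaps)``: ``counts`` has one row per
    (tissue, day) with the number of genes at q < q_max; ``overlaps`` has
    one row per (tissue_a, tissue_b, day) with the number of genes
    significant in both tissues on that day.
    """
    if len(deg) == 0:
        return (
            pd.DataFrame(columns=["tissue", "day", "n_deg"]),
            pd.DataFrame(columns=["tissue_a", "tissue_b", "day", "n_overlap"]),
        )
    deg = validate_deg_table(deg)
    sig = deg[deg["q"] < q_max]
    counts = (
        sig.groupby(["tissue", "day"], sort=True)
        .size()
        .rename("n_deg")
        .reset_index()
    )
    tissues = sorted(deg["tissue"].unique())
    days = sorted(deg["day"].unique())
    overlap_rows = []
    sets = {
        (t, d): set(sig.loc[(sig["tissue"] == t) & (sig["day"] == d), "gene"])
        for t in tissues
        for d in days
    }
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1 :]:
            for d in days:
                overlap_rows.append((ta, tb, d, len(sets[(ta, d)] & sets[(tb, d)])))
    overlaps = pd.DataFrame(
        overlap_rows, columns=["tissue_a", "tissue_b", "day", "n_overlap"]
    )
    return counts, overlaps
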