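"""Gene-set enrichment arithmetic, qPCR relative quantification and
cross-platform concordance.

Enrichment uses the exact hypergeometric upper tail P[X >= k] against a
user-supplied gene-set collection (GMT format) with Benjamini-Hochberg
correction; the conventional display cut-offs (-log10 p above 1.0 and a
minimum hit count) are exposed as flags.  qPCR expression is quantified
with the 2^-ddCT method against the geometric mean of designated
reference genes; concordance between two log2FC data sets is an ordinary
least-squares fit plus Pearson statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "bh_fdr",
    "QpcrTable",
    "relative_expression_ddct",
    "platform_concordance",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against.

    Construction intersects every set with the universe; the number of
    members dropped that way is recorded in ``n_dropped``.
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str]
    universe: set[str]
    n_dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("gene-set universe is empty")
        trimmed = {}
        for sid, members in self.sets.items():
            inside = set(members) & self.universe
            self.n_dropped[sid] = len(set(members)) - len(inside)
            trimmed[sid] = inside
        self.sets = trimmed


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file (set id <TAB> description <TAB> member genes...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
            descriptions[parts[0]] = parts[1]
    return GeneSetCollection(sets, descriptions, set(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in collection.sets:
            members = "\t".join(sorted(collection.sets[sid]))
            desc = collection.descriptions.get(sid, "")
            fh.write(f"{sid}\t{desc}\t{members}\n" if members else f"{sid}\t{desc}\n")


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving w.r.t. input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_count: int = 3,
    min_neglog10p: float = 1.0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list.

    One row per gene set with columns ``set_id, description, k, n, K, N,
    fold_enrichment, p, q, neglog10p, passing``; p is the exact upper
    tail P[X >= k] (computed in log space by scipy's hypergeometric
    survival function), q is BH-adjusted across all tested sets, and
    ``passing`` flags sets with -log10 p > ``min_neglog10p`` and
    k > ``min_count``.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene list is empty")
    outside = query - collection.universe
    query_in = query & collection.universe
    if not query_in:
        raise ValueError("query is disjoint from the universe")
    N = len(collection.universe)
    n = len(query_in)
    rows = []
    for sid, members in collection.sets.items():
        K = len(members)
        k = len(query_in & members)
        # upper tail P[X >= k]; k = 0 gives p = 1 by convention
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(max(p, 0.0), 1.0)
        fold = (k / n) / (K / N) if K else 0.0
        rows.append(
            {
                "set_id": sid,
                "description": collection.descriptions.get(sid, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    with np.errstate(divide="ignore"):
        table["neglog10p"] = -np.log10(table["p"].to_numpy())
    table["passing"] = (table["neglog10p"] > min_neglog10p) & (table["k"] > min_count)
    table.attrs["n_query_outside_universe"] = len(outside)
    return table


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrTable:
    """CT measurements: one row per (sample, gene) with designated
    reference genes and a calibrator sample."""

    ct: pd.DataFrame  # columns: sample_id, gene, ct
    reference_genes: tuple[str, ...]
    calibrator: str

    def __post_init__(self) -> None:
        missing = {"sample_id", "gene", "ct"} - set(self.ct.columns)
        if missing:
            raise ValueError(f"CT table lacks columns: {sorted(missing)}")
        if not np.isfinite(self.ct["ct"]).all():
            raise ValueError("CT values must be finite")
        samples = self.ct["sample_id"].unique()
        if self.calibrator not in samples:
            raise ValueError(f"calibrator sample {self.calibrator!r} not measured")
        for sample in samples:
            have = set(self.ct.loc[self.ct["sample_id"] == sample, "gene"])
            lacking = set(self.reference_genes) - have
            if lacking:
                raise ValueError(
                    f"sample {sample!r} lacks reference gene(s) {sorted(lacking)}"
                )

    def ct_of(self, sample: str, gene: str) -> float:
        sel = self.ct[(self.ct["sample_id"] == sample) & (self.ct["gene"] == gene)]
        if len(sel) == 0:
            raise ValueError(f"no CT value for sample {sample!r}, gene {gene!r}")
        return float(sel["ct"].iloc[0])


def relative_expression_ddct(qpcr: QpcrTable, target: str) -> pd.Series:
    """Per-sample relative quantity of a target gene by the 2^-ddCT method.

    dCT(sample) = CT_target - geometric mean of the reference CTs;
    ddCT = dCT(sample) - dCT(calibrator); RQ = 2^-ddCT (so the calibrator
    sample has RQ exactly 1).
    """
    samples = list(dict.fromkeys(qpcr.ct["sample_id"]))
    dct = {}
    for sample in samples:
        ref_cts = np.array([qpcr.ct_of(sample, g) for g in qpcr.reference_genes])
        geo_mean = float(np.exp(np.mean(np.log(ref_cts))))
        dct[sample] = qpcr.ct_of(sample, target) - geo_mean
    ddct = {s: dct[s] - dct[qpcr.calibrator] for s in samples}
    return pd.Series(
        {s: 2.0 ** (-ddct[s]) for s in samples}, name=f"RQ_{target}"
    )


# ---------------------------------------------------------------------------
# cross-platform concordance


def platform_concordance(
    log2fc_a: pd.Series | Mapping[object, float],
    log2fc_b: pd.Series | Mapping[object, float],
) -> dict[str, float]:
    """Agreement between two log2FC data sets matched by key.

    Fits B on A by ordinary least squares and reports ``pearson_r``,
    ``r_squared``, ``slope``, ``intercept``, ``n`` (matched finite pairs)
    and ``n_dropped`` (keys missing or non-finite on either side).
    """
    a = pd.Series(log2fc_a, dtype=float)
    b = pd.Series(log2fc_b, dtype=float)
    keys = a.index.intersection(b.index)
    n_total = len(a.index.union(b.index))
    av, bv = a.loc[keys].to_numpy(), b.loc[keys].to_numpy()
    finite = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[finite], bv[finite]
    if len(av) < 3:
        raise ValueError(f"need >= 3 matched pairs, got {len(av)}")
    fit = stats.linregress(av, bv)
    return {
        "pearson_r": float(fit.rvalue),
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(av)),
        "n_dropped": int(n_total - len(av)),
    }
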