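"""Synthetic multi-tissue oestrous-cycle expression data with planted structure.

The generator emulates a 3-tissue x 7-day x 3-replicate time-course design
(endometrium, ovary, oviduct sampled on days 0, 3, 6, 9, 12, 15, 18 of the
cycle, three animals per day).  It plants:

* tissue-specific temporal co-expression modules, one per expression
  archetype (two endometrial, two ovarian, one oviductal profile);
* *bridging genes* -- genes carrying a mixture of two archetypes from two
  different tissues, so that their co-expression neighbourhood spans two
  tissue-specific sub-networks;
* *connector genes* -- weaker two-tissue mixtures that tie the bridging
  genes into the pure tissue modules without themselves having
  cross-tissue network neighbours;
* unstructured background genes.

Every planted fact (archetype membership, bridging flag, true log2 fold
change per condition) is emitted as a :class:`SyntheticTruth`, so each
downstream stage of the pipeline can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, condition_label

__all__ = [
    "Archetype",
    "SyntheticDesign",
    "SyntheticTruth",
    "default_archetypes",
    "default_module_sizes",
    "simulate_dataset",
    "score_recovery",
    "write_truth",
    "read_truth",
]

DEFAULT_TISSUES = ("endometrium", "ovary", "oviduct")
DEFAULT_DAYS = (0, 3, 6, 9, 12, 15, 18)

BACKGROUND = "background"


@dataclass(frozen=True)
class Archetype:
    """A planted temporal expression profile for one tissue.

    ``profile`` holds one signed multiplier in [-1, 1] per day of the
    design, in day order, and is exactly 0 at the baseline day.  The
    realised log2 fold change of a member gene is
    ``effect_size * profile[d]`` in the archetype's tissue and 0 elsewhere.
    """

    id: str
    tissue: str
    profile: tuple[float, ...]

    def validate(self, days: Sequence[int], baseline_day: int = 0) -> None:
        if len(self.profile) != len(days):
            raise ValueError(
                f"archetype {self.id!r}: profile length {len(self.profile)} "
                f"!= number of days {len(days)}"
            )
        i = list(days).index(baseline_day)
        if self.profile[i] != 0:
            raise ValueError(
                f"archetype {self.id!r}: profile must be 0 at baseline day "
                f"{baseline_day}, got {self.profile[i]}"
            )
        if any(abs(v) > 1 for v in self.profile):
            raise ValueError(f"archetype {self.id!r}: multipliers must lie in [-1, 1]")


def default_archetypes(days: Sequence[int] = DEFAULT_DAYS) -> list[Archetype]:
    """The five default expression archetypes.

    Two endometrial profiles (up / down) peaking between days 6 and 12,
    two ovarian profiles (up / down) active between days 3 and 12, and a
    broad oviductal down-regulation spanning most of the cycle.
    """
    days = list(days)
    if 0 not in days:
        raise ValueError(f"day list must contain the baseline day 0, got {days}")
    if days.count(0) != 1:
        raise ValueError(f"baseline day 0 must appear exactly once in {days}")

    # multipliers keyed by day; days absent from the map are 0
    shapes: dict[str, tuple[str, dict[int, float]]] = {
        "endometrium_up": ("endometrium", {6: 0.7, 9: 1.0, 12: 0.8}),
        "endometrium_down": ("endometrium", {6: -0.7, 9: -1.0, 12: -0.8}),
        "ovary_up": ("ovary", {3: 0.5, 6: 0.9, 9: 1.0, 12: 0.7}),
        "ovary_down": ("ovary", {3: -0.5, 6: -0.9, 9: -1.0, 12: -0.7}),
        "oviduct_down": (
            "oviduct",
            {3: -0.4, 6: -0.7, 9: -0.9, 12: -1.0, 15: -0.8, 18: -0.5},
        ),
    }
    archetypes = []
    for arch_id, (tissue, by_day) in shapes.items():
        profile = tuple(float(by_day.get(d, 0.0)) for d in days)
        arch = Archetype(arch_id, tissue, profile)
        arch.validate(days)
        archetypes.append(arch)
    return archetypes


def default_module_sizes() -> dict[str, int]:
    """Default pure-module gene counts (~900 structured genes in total
    together with the bridging and connector genes)."""
    return {
        "endometrium_up": 155,
        "endometrium_down": 135,
        "ovary_up": 175,
        "ovary_down": 155,
        "oviduct_down": 192,
    }


# Bridging scaffold geometry.  Each tissue pair is bridged by a "family"
# of two-archetype mixture genes parameterised by a mixing angle theta
# measured from the first archetype's axis: theta=0 is a pure first-tissue
# gene, theta=90 deg a pure second-tissue gene.  Bridging genes sit in a
# straddle pair of slots either side of 45 deg, close enough that the two
# slots are correlated above the network threshold; connector genes sit
# near each axis, correlated with the pure module and with the nearer
# bridging slot but not with anything across the tissue boundary.  The
# angles are tuned per family so that (i) the straddle-pair correlation
# clears the 0.90 edge threshold with margin, (ii) bridging genes keep a
# strong dominance gap (peak |log2FC| ratio ~1.9) so the tissue
# assignment of a bridging gene is stable under noise, and (iii)
# cross-boundary correlations to module genes stay low.
# Each family maps to (bridge angle 1, bridge angle 2, conn angle 1,
# conn angle 2); the ovary enters both of its families with the opposite
# sign to its partner tissue, planting the negative ovary-vs-other
# condition correlation.
DEFAULT_FAMILIES: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("endometrium_up", "ovary_down"): (31.0, 56.5, 6.0, 84.0),
    ("endometrium_up", "oviduct_down"): (31.0, 56.5, 6.0, 84.0),
    ("ovary_up", "oviduct_down"): (31.0, 56.5, 6.0, 84.0),
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the simulated study.

    The defaults reproduce the study design the pipeline targets: three
    tissues, seven days, three replicates, a stringent-filter effect size
    of 4.0 on the log2 scale (comfortably above the |log2FC| >= 3 network
    cut-off) and ~900 structured genes.
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    days: tuple[int, ...] = DEFAULT_DAYS
    replicates: int = 3
    module_sizes: Mapping[str, int] = field(default_factory=default_module_sizes)
    n_bridging: int = 60
    connectors_per_side: int = 3
    n_background: int = 100
    effect_size: float = 4.0
    fc_jitter_sd: float = 0.15
    fc_jitter_range: tuple[float, float] = (1.0, 1.5)
    shape_jitter_sd: float = 0.05
    shape_jitter_max: float = 0.12
    noise_sd: float = 0.5
    baseline_log_mean: float = 6.2
    baseline_log_sd: float = 0.4
    tissue_baseline_log_sd: float = 0.6
    q_active_max: float = 0.01
    q_inactive_min: float = 0.2
    active_min_abs_log2fc: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        days = list(self.days)
        if days.count(0) != 1:
            raise ValueError(f"days must contain baseline day 0 exactly once: {days}")
        if not self.effect_size > 0:
            raise ValueError(f"effect_size must be > 0, got {self.effect_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 < self.q_active_max < self.q_inactive_min <= 1):
            raise ValueError(
                "q bounds must satisfy 0 < q_active_max < q_inactive_min <= 1, "
                f"got {self.q_active_max}, {self.q_inactive_min}"
            )
        for name in ("n_bridging", "n_background", "connectors_per_side"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.fc_jitter_range
        if not (0 < lo <= hi) or self.fc_jitter_sd < 0:
            raise ValueError("fc jitter parameters must satisfy 0 < lo <= hi, sd >= 0")
        if self.shape_jitter_sd < 0 or not (0 <= self.shape_jitter_max < 1):
            raise ValueError("shape jitter parameters out of range")
        if any(v < 0 for v in self.module_sizes.values()):
            raise ValueError("module sizes must be >= 0")
        for par in (
            self.effect_size,
            self.noise_sd,
            self.baseline_log_mean,
            self.baseline_log_sd,
            self.tissue_baseline_log_sd,
        ):
            if not math.isfinite(par):
                raise ValueError("design parameters must be finite")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset.

    ``table`` has one row per gene with columns ``gene``, ``archetype``
    (primary archetype id or ``background``), ``secondary_archetype``
    (empty for single-archetype genes), ``is_bridging``, ``is_connector``
    and ``mix_angle_deg``.  ``true_log2fc`` is the planted gene x
    condition log2 fold-change matrix (conditions exclude the baseline
    day).
    """

    table: pd.DataFrame
    true_log2fc: pd.DataFrame
    archetypes: dict[str, Archetype]
    tissues: tuple[str, ...]
    days: tuple[int, ...]

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def bridging_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_bridging"], "gene"])

    @property
    def background_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["archetype"] == BACKGROUND, "gene"])

    @property
    def structured_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["archetype"] != BACKGROUND, "gene"])

    def primary_tissue(self) -> pd.Series:
        """Tissue of each structured gene's primary archetype (index: gene)."""
        t = self.table[self.table["archetype"] != BACKGROUND]
        return pd.Series(
            [self.archetypes[a].tissue for a in t["archetype"]],
            index=list(t["gene"]),
            name="tissue",
        )

    def __eq__(self, other: object) -> bool:  # round-trip support
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.table.equals(other.table)
            and self.true_log2fc.equals(other.true_log2fc)
            and self.archetypes == other.archetypes
            and self.tissues == other.tissues
            and self.days == other.days
        )


def _conditions(tissues: Sequence[str], days: Sequence[int]) -> list[tuple[str, int]]:
    return [(t, d) for t in tissues for d in days if d != 0]


def _archetype_condition_vector(
    arch: Archetype, tissues: Sequence[str], days: Sequence[int]
) -> np.ndarray:
    """Unit-peak profile of an archetype over the (tissue, day != 0) grid."""
    by_day = dict(zip(days, arch.profile))
    return np.array(
        [by_day[d] if t == arch.tissue else 0.0 for t, d in _conditions(tissues, days)]
    )


def _mixture_lfc(
    first: np.ndarray, second: np.ndarray, angle_deg: float, effect_size: float
) -> np.ndarray:
    """True log2FC vector of a two-archetype mixture gene.

    The mixture ``cos(theta) * first + sin(theta) * second`` is rescaled so
    its dominant-tissue peak equals ``effect_size``; the mixing angle only
    sets the *shape* (and hence all correlations), not the peak height.
    """
    th = math.radians(angle_deg)
    v = math.cos(th) * first + math.sin(th) * second
    scale = effect_size / max(math.cos(th), math.sin(th))
    return scale * v


def simulate_dataset(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate an FPKM matrix, a DEG table and the planted truth.

    FPKM of gene *g* in (tissue *t*, day *d*, replicate *r*) is

    ``baseline_g * tissue_factor_{g,t} * 2 ** (L(g, t, d) + eps)``

    with ``L`` the planted log2FC (0 at day 0), ``eps ~ N(0, noise_sd)``
    independent per replicate, ``baseline_g`` log-normal and
    ``tissue_factor`` a per-gene-per-tissue log-normal offset emulating
    tissue-specific absolute expression.  The DEG table recomputes log2FC
    from replicate-mean FPKM with a pseudocount of 1 against day 0, and
    draws q-values from a uniform mixture keyed to whether the planted
    |log2FC| clears ``active_min_abs_log2fc`` at that condition.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    tissues, days = design.tissues, design.days
    archetypes = {a.id: a for a in default_archetypes(days)}
    for a in archetypes.values():
        if a.tissue not in tissues:
            raise ValueError(f"archetype {a.id!r} references unknown tissue {a.tissue!r}")
    conditions = _conditions(tissues, days)
    arch_vec = {
        aid: _archetype_condition_vector(a, tissues, days) for aid, a in archetypes.items()
    }

    # ---- gene roster with planted true log2FC ---------------------------
    rows = []  # (gene, primary, secondary, is_bridging, is_connector, angle, lfc)

    def add(prefix, idx, primary, secondary, bridging, connector, angle, lfc):
        rows.append(
            (f"{prefix}{idx:04d}", primary, secondary, bridging, connector, angle, lfc)
        )

    i = 0
    for aid, size in design.module_sizes.items():
        if aid not in archetypes:
            raise ValueError(f"module_sizes references unknown archetype {aid!r}")
        for _ in range(size):
            add("G", i, aid, "", False, False, 0.0, design.effect_size * arch_vec[aid])
            i += 1

    families = {
        f: angles
        for f, angles in DEFAULT_FAMILIES.items()
        if f[0] in archetypes and f[1] in archetypes
    }
    # bridging genes: straddle-pair slots, round-robin over families
    fam_list = list(families)
    n_fam = len(fam_list)
    for j in range(design.n_bridging):
        fam = fam_list[j % n_fam]
        first, second = arch_vec[fam[0]], arch_vec[fam[1]]
        angle = families[fam][(j // n_fam) % 2]
        primary, secondary = (fam[0], fam[1]) if angle < 45 else (fam[1], fam[0])
        lfc = _mixture_lfc(first, second, angle, design.effect_size)
        add("B", j, primary, secondary, True, False, angle, lfc)
    # connector genes: near-axis mixtures on both sides of every family
    k = 0
    for fam, (_, _, conn1, conn2) in families.items():
        first, second = arch_vec[fam[0]], arch_vec[fam[1]]
        for angle, primary, secondary in (
            (conn1, fam[0], fam[1]),
            (conn2, fam[1], fam[0]),
        ):
            for _ in range(design.connectors_per_side):
                lfc = _mixture_lfc(first, second, angle, design.effect_size)
                add("C", k, primary, secondary, False, True, angle, lfc)
                k += 1
    for j in range(design.n_background):
        add("N", j, BACKGROUND, "", False, False, 0.0, np.zeros(len(conditions)))

    genes = [r[0] for r in rows]
    lfc_true = np.vstack([r[6] for r in rows])
    # Per-gene fold-change magnitude jitter: a pure rescaling of the
    # planted profile, so pairwise correlations are unchanged.  The lower
    # clip keeps every structured gene's peak above the activity cut-off.
    jitter = np.clip(
        rng.lognormal(0.0, design.fc_jitter_sd, len(genes)), *design.fc_jitter_range
    )
    # Per-gene, per-condition multiplicative shape jitter on the active
    # entries.  Member genes of a module are thus highly (not perfectly)
    # correlated; exactly duplicated profiles would be degenerate inputs
    # for partial-correlation tests.
    shape = 1.0 + np.clip(
        rng.normal(0.0, design.shape_jitter_sd, lfc_true.shape),
        -design.shape_jitter_max,
        design.shape_jitter_max,
    )
    lfc_true = lfc_true * jitter[:, None] * np.where(lfc_true != 0, shape, 1.0)
    truth_table = pd.DataFrame(
        {
            "gene": genes,
            "archetype": [r[1] for r in rows],
            "secondary_archetype": [r[2] for r in rows],
            "is_bridging": [r[3] for r in rows],
            "is_connector": [r[4] for r in rows],
            "mix_angle_deg": [float(r[5]) for r in rows],
        }
    )
    true_log2fc = pd.DataFrame(
        lfc_true, index=genes, columns=[condition_label(t, d) for t, d in conditions]
    )

    # ---- FPKM ------------------------------------------------------------
    n_genes = len(genes)
    baseline = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, n_genes)
    tissue_factor = rng.lognormal(
        0.0, design.tissue_baseline_log_sd, (n_genes, len(tissues))
    )
    cond_index = {c: j for j, c in enumerate(conditions)}

    sample_ids, meta_rows = [], []
    fpkm_cols = []
    for ti, t in enumerate(tissues):
        for d in days:
            for r in range(1, design.replicates + 1):
                sid = f"{t}_d{d:02d}_r{r}"
                sample_ids.append(sid)
                meta_rows.append((sid, t, d, r))
                lfc = (
                    np.zeros(n_genes)
                    if d == 0
                    else lfc_true[:, cond_index[(t, d)]]
                )
                noise = (
                    rng.normal(0.0, design.noise_sd, n_genes)
                    if design.noise_sd > 0
                    else np.zeros(n_genes)
                )
                fpkm_cols.append(baseline * tissue_factor[:, ti] * 2.0 ** (lfc + noise))
    fpkm = pd.DataFrame(np.column_stack(fpkm_cols), index=genes, columns=sample_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "tissue", "day", "replicate"]
    )
    expr = ExpressionMatrix(fpkm, metadata, tissues=tissues, days=days)

    # ---- DEG table -------------------------------------------------------
    deg_rows = []
    for ti, t in enumerate(tissues):
        base_cols = [f"{t}_d00_r{r}" for r in range(1, design.replicates + 1)]
        mean0 = fpkm[base_cols].mean(axis=1).to_numpy()
        for d in days:
            if d == 0:
                continue
            cols = [f"{t}_d{d:02d}_r{r}" for r in range(1, design.replicates + 1)]
            mean_d = fpkm[cols].mean(axis=1).to_numpy()
            log2fc = np.log2((mean_d + 1.0) / (mean0 + 1.0))
            active = (
                np.abs(lfc_true[:, cond_index[(t, d)]])
                >= design.active_min_abs_log2fc
            )
            q = np.where(
                active,
                rng.uniform(0.0, design.q_active_max, n_genes),
                rng.uniform(design.q_inactive_min, 1.0, n_genes),
            )
            for gi, g in enumerate(genes):
                deg_rows.append((g, t, d, log2fc[gi], q[gi]))
    deg = pd.DataFrame(deg_rows, columns=["gene", "tissue", "day", "log2fc", "q"])

    truth = SyntheticTruth(
        table=truth_table,
        true_log2fc=true_log2fc,
        archetypes=archetypes,
        tissues=tuple(tissues),
        days=tuple(days),
    )
    return expr, deg, truth


# ---------------------------------------------------------------------------
# scoring pipeline output against the planted truth


def score_recovery(truth: SyntheticTruth, kept, assignment, partition, net) -> dict:
    """Score a pipeline run against the planted ground truth.

    Parameters are the filter output (``kept`` gene list), the tissue
    assignment, the sub-network partition and the full network.  Returns
    a dict with bridging precision/recall, tissue-assignment accuracy on
    pure module genes, per-tissue sub-network node-set agreement with the
    planted primary-tissue gene sets, and two topology indicators: do all
    inter-tissue edges run between planted bridging genes, and does one
    connected component span all tissues (the triangular layout).
    """
    import networkx as nx

    kept_set = set(kept)
    truth_bridging = truth.bridging_genes & kept_set
    detected = set(partition.bridging)
    tp = len(detected & truth_bridging)
    precision = tp / len(detected) if detected else float("nan")
    recall = tp / len(truth_bridging) if truth_bridging else float("nan")

    labels = assignment.label_map()
    tt = truth.table
    pure = tt[
        (tt["archetype"] != BACKGROUND) & ~tt["is_bridging"] & ~tt["is_connector"]
    ]
    calls = [
        labels.get(g) == truth.archetypes[a].tissue
        for g, a in zip(pure["gene"], pure["archetype"])
        if g in labels
    ]
    accuracy = float(np.mean(calls)) if calls else float("nan")

    primary = truth.primary_tissue()
    subnet_exact = {}
    for tissue, sub in partition.subnetworks.items():
        expected = {g for g in kept_set if primary.get(g) == tissue}
        subnet_exact[tissue] = set(sub.nodes) == expected

    cross_ok = all(
        u in truth_bridging and v in truth_bridging
        for u, v in net.edges
        if labels.get(u) != labels.get(v)
    )
    non_isolated = [n for n in net if net.degree(n) > 0]
    spanning = False
    if non_isolated:
        comp = max(nx.connected_components(net.subgraph(non_isolated)), key=len)
        spanning = {labels[n] for n in comp} >= set(truth.tissues)

    return {
        "n_kept": len(kept_set),
        "kept_equals_structured": kept_set == truth.structured_genes,
        "bridging_precision": precision,
        "bridging_recall": recall,
        "n_bridging_detected": len(detected),
        "tissue_assignment_accuracy": accuracy,
        "subnetworks_exact": subnet_exact,
        "cross_tissue_edges_only_bridging": cross_ok,
        "tissues_connected_through_bridges": bool(spanning and cross_ok),
    }


# ---------------------------------------------------------------------------
# truth round-trip


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the truth as two tab-separated tables.

    ``<path>`` holds the per-gene table; ``<path stem>.log2fc.tsv`` next to
    it holds the planted gene x condition log2FC matrix.  A header line of
    key=value pairs records tissues, days and archetype definitions so the
    pair of files round-trips losslessly.
    """
    path = Path(path)
    arch_spec = ";".join(
        f"{a.id}:{a.tissue}:" + ",".join(repr(v) for v in a.profile)
        for a in truth.archetypes.values()
    )
    header = (
        f"#tissues={','.join(truth.tissues)}"
        f"\t#days={','.join(str(d) for d in truth.days)}"
        f"\t#archetypes={arch_spec}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        truth.table.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    truth.true_log2fc.to_csv(
        path.with_suffix(".log2fc.tsv"),
        sep="\t",
        index_label="gene",
        float_format="%.17g",  # full precision: the table round-trips exactly
    )


def read_truth(path: str | Path) -> SyntheticTruth:
    """Inverse of :func:`write_truth`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        table = pd.read_csv(fh, sep="\t", dtype={"gene": str})
    fields = dict(
        item.lstrip("#").split("=", 1) for item in header.rstrip("\n").split("\t")
    )
    tissues = tuple(fields["tissues"].split(","))
    days = tuple(int(d) for d in fields["days"].split(","))
    archetypes = {}
    if fields["archetypes"]:
        for spec in fields["archetypes"].split(";"):
            aid, tissue, prof = spec.split(":")
            profile = tuple(float(v) for v in prof.split(","))
            archetypes[aid] = Archetype(aid, tissue, profile)
    table["secondary_archetype"] = table["secondary_archetype"].fillna("").astype(str)
    table["is_bridging"] = table["is_bridging"].astype(bool)
    table["is_connector"] = table["is_connector"].astype(bool)
    true_log2fc = pd.read_csv(
        path.with_suffix(".log2fc.tsv"),
        sep="\t",
        index_col="gene",
        float_precision="round_trip",
    ).astype(float)
    true_log2fc.index = true_log2fc.index.astype(str)
    return SyntheticTruth(
        table=table,
        true_log2fc=true_log2fc,
        archetypes=archetypes,
        tissues=tissues,
        days=days,
    )
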