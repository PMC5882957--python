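"""Expression / DEG table I/O and log2 fold-change profile construction.

Core containers:

* :class:`ExpressionMatrix` -- FPKM values (genes x samples) plus sample
  metadata (tissue, day, replicate);
* DEG tables -- plain :class:`pandas.DataFrame` with columns
  ``gene, tissue, day, log2fc, q``;
* :class:`ProfileMatrix` -- per-gene log2FC against the baseline day over
  an ordered (tissue, day) condition grid; this is the object the
  correlation / network stages consume.

All on-disk formats are UTF-8 tab-separated tables with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProfileMatrix",
    "condition_label",
    "parse_condition_label",
    "read_expression",
    "write_expression",
    "read_deg_table",
    "write_deg_table",
    "validate_deg_table",
    "log2fc_profiles",
    "deg_to_profiles",
    "zscore_rows",
    "select_fc_bins",
]

DEG_COLUMNS = ["gene", "tissue", "day", "log2fc", "q"]


def condition_label(tissue: str, day: int) -> str:
    """Canonical text label of a (tissue, day) condition, e.g. ``ovary:9``."""
    return f"{tissue}:{day}"


def parse_condition_label(label: str) -> tuple[str, int]:
    tissue, day = label.rsplit(":", 1)
    return tissue, int(day)


@dataclass
class ExpressionMatrix:
    """FPKM matrix with attached sample metadata.

    ``data``: genes x samples, non-negative finite values.
    ``metadata``: one row per sample with columns
    ``sample_id, tissue, day, replicate``; sample order matches ``data``
    columns.  ``tissues`` and ``days`` fix the declared condition order
    used by every downstream profile and network stage.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame
    tissues: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    days: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        md = self.metadata
        missing = {"sample_id", "tissue", "day", "replicate"} - set(md.columns)
        if missing:
            raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
        md = md.copy()
        md["day"] = md["day"].astype(int)
        if self.tissues is None:
            self.tissues = tuple(dict.fromkeys(md["tissue"]))
        else:
            self.tissues = tuple(self.tissues)
        if self.days is None:
            self.days = tuple(sorted(set(md["day"])))
        else:
            self.days = tuple(int(d) for d in self.days)

        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if md["sample_id"].duplicated().any():
            dupes = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate metadata sample ids: {dupes[:5]}")

        meta_ids = list(md["sample_id"])
        matrix_ids = list(self.data.columns)
        for sid in meta_ids:
            if sid not in set(matrix_ids):
                raise ValueError(f"metadata sample {sid!r} absent from expression matrix")
        for sid in matrix_ids:
            if sid not in set(meta_ids):
                raise ValueError(f"matrix sample {sid!r} absent from metadata")
        for _, row in md.iterrows():
            if row["tissue"] not in self.tissues:
                raise ValueError(
                    f"sample {row['sample_id']!r} has unknown tissue {row['tissue']!r}"
                )
            if row["day"] not in self.days:
                raise ValueError(
                    f"sample {row['sample_id']!r} has unknown day {row['day']!r}"
                )
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            bad = self.data.index[~np.isfinite(vals).all(axis=1)][:5].tolist()
            raise ValueError(f"non-finite FPKM values for genes {bad}")
        if (vals < 0).any():
            bad = self.data.index[(vals < 0).any(axis=1)][:5].tolist()
            raise ValueError(f"negative FPKM values for genes {bad}")
        # align metadata row order to matrix column order
        md = md.set_index("sample_id").loc[matrix_ids].reset_index()
        self.metadata = md

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_for(self, tissue: str, day: int) -> list[str]:
        md = self.metadata
        sel = md[(md["tissue"] == tissue) & (md["day"] == day)]
        return list(sel["sample_id"])

    def log2_fpkm(self) -> pd.DataFrame:
        """log2(FPKM + 1) transform of the matrix."""
        return np.log2(self.data + 1.0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.tissues == other.tissues
            and self.days == other.days
            and self.metadata.equals(other.metadata)
            and self.data.shape == other.data.shape
            and np.allclose(self.data.to_numpy(), other.data.to_numpy(), atol=1e-9)
            and list(self.data.index) == list(other.data.index)
            and list(self.data.columns) == list(other.data.columns)
        )


@dataclass
class ProfileMatrix:
    """Gene x condition matrix of log2 fold changes vs the baseline day.

    Columns are ordered as the declared tissue order crossed with
    ascending non-baseline days, labelled ``tissue:day``.
    """

    data: pd.DataFrame
    tissues: tuple[str, ...]
    days: tuple[int, ...]
    baseline_day: int = 0

    def __post_init__(self) -> None:
        expected = [
            condition_label(t, d)
            for t in self.tissues
            for d in sorted(self.days)
            if d != self.baseline_day
        ]
        if list(self.data.columns) != expected:
            raise ValueError(
                f"profile columns {list(self.data.columns)} do not match the "
                f"declared condition order {expected}"
            )
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("profile matrix contains non-finite values")

    @property
    def conditions(self) -> list[tuple[str, int]]:
        return [parse_condition_label(c) for c in self.data.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def max_abs_log2fc(self) -> pd.Series:
        return self.data.abs().max(axis=1)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")

    @classmethod
    def read(
        cls,
        path: str | Path,
        tissues: Sequence[str] | None = None,
        days: Sequence[int] | None = None,
        baseline_day: int = 0,
    ) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
        df.index = df.index.astype(str)
        df = df.astype(float)
        conds = [parse_condition_label(c) for c in df.columns]
        if tissues is None:
            tissues = tuple(dict.fromkeys(t for t, _ in conds))
        if days is None:
            days = tuple(sorted({d for _, d in conds} | {baseline_day}))
        return cls(df, tuple(tissues), tuple(int(d) for d in days), baseline_day)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    tissues: Sequence[str] | None = None,
    days: Sequence[int] | None = None,
) -> ExpressionMatrix:
    """Read an FPKM matrix TSV (genes x samples, index column ``gene``)
    and a sample-metadata TSV, validating them against each other."""
    data = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    data.index = data.index.astype(str)
    metadata = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    return ExpressionMatrix(
        data,
        metadata,
        tissues=tuple(tissues) if tissues is not None else None,
        days=tuple(days) if days is not None else None,
    )


def write_expression(
    expr: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    expr.data.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.17g")
    expr.metadata.to_csv(metadata_path, sep="\t", index=False)


def validate_deg_table(deg: pd.DataFrame) -> pd.DataFrame:
    missing = set(DEG_COLUMNS) - set(deg.columns)
    if missing:
        raise ValueError(f"DEG table lacks columns: {sorted(missing)}")
    if len(deg) == 0:
        raise ValueError("DEG table is empty")
    deg = deg.copy()
    deg["day"] = deg["day"].astype(int)
    dup = deg.duplicated(subset=["gene", "tissue", "day"])
    if dup.any():
        first = deg.loc[dup, ["gene", "tissue", "day"]].iloc[0].tolist()
        raise ValueError(f"duplicate DEG record for (gene, tissue, day) = {first}")
    if not np.isfinite(deg["log2fc"]).all():
        bad = deg.loc[~np.isfinite(deg["log2fc"]), "gene"].iloc[0]
        raise ValueError(f"non-finite log2fc for gene {bad!r}")
    if ((deg["q"] < 0) | (deg["q"] > 1)).any():
        bad = deg.loc[(deg["q"] < 0) | (deg["q"] > 1), "gene"].iloc[0]
        raise ValueError(f"q-value outside [0, 1] for gene {bad!r}")
    return deg


def read_deg_table(path: str | Path) -> pd.DataFrame:
    deg = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "tissue": str}, float_precision="round_trip"
    )
    return validate_deg_table(deg)


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    deg.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# profile construction


def log2fc_profiles(expr: ExpressionMatrix, baseline_day: int = 0) -> ProfileMatrix:
    """Per-gene log2FC profiles vs the baseline day.

    For each gene, tissue and non-baseline day:
    ``log2((mean replicate FPKM at day d + 1) / (mean at baseline + 1))``.
    Replicates are averaged as plain FPKM means before the ratio.
    """
    cols = {}
    for tissue in expr.tissues:
        base_samples = expr.samples_for(tissue, baseline_day)
        if not base_samples:
            raise ValueError(f"tissue {tissue!r} has no baseline day {baseline_day} samples")
        mean0 = expr.data[base_samples].mean(axis=1)
        for day in sorted(expr.days):
            if day == baseline_day:
                continue
            samples = expr.samples_for(tissue, day)
            if not samples:
                raise ValueError(f"tissue {tissue!r} has no samples for day {day}")
            mean_d = expr.data[samples].mean(axis=1)
            cols[condition_label(tissue, day)] = np.log2((mean_d + 1.0) / (mean0 + 1.0))
    df = pd.DataFrame(cols, index=expr.data.index)
    return ProfileMatrix(df, expr.tissues, expr.days, baseline_day)


def deg_to_profiles(
    deg: pd.DataFrame,
    tissues: Sequence[str],
    days: Sequence[int],
    baseline_day: int = 0,
    fill: str = "strict",
) -> ProfileMatrix:
    """Arrange a DEG table into a ProfileMatrix with the declared condition
    order.  ``fill='zero'`` fills missing (gene, tissue, day) cells with 0;
    the default strict policy raises naming the first missing cell."""
    if fill not in ("strict", "zero"):
        raise ValueError(f"unknown fill policy {fill!r}")
    deg = validate_deg_table(deg)
    deg = deg[deg["day"] != baseline_day]
    wide = deg.pivot(index="gene", columns=["tissue", "day"], values="log2fc")
    expected = [
        (t, d) for t in tissues for d in sorted(days) if d != baseline_day
    ]
    missing_cols = [c for c in expected if c not in wide.columns]
    if missing_cols:
        if fill == "strict":
            raise ValueError(
                f"no DEG records for condition (tissue, day) = {missing_cols[0]}"
            )
        for c in missing_cols:
            wide[c] = np.nan
    wide = wide[expected]
    if wide.isna().any().any():
        if fill == "strict":
            col = wide.columns[wide.isna().any()][0]
            gene = wide.index[wide[col].isna()][0]
            raise ValueError(
                f"missing DEG record for (gene, tissue, day) = "
                f"({gene!r}, {col[0]!r}, {col[1]})"
            )
        wide = wide.fillna(0.0)
    wide.columns = [condition_label(t, d) for t, d in expected]
    wide = wide.loc[list(dict.fromkeys(deg["gene"]))]  # first-appearance order
    wide.index.name = "gene"
    return ProfileMatrix(wide, tuple(tissues), tuple(int(d) for d in days), baseline_day)


# ---------------------------------------------------------------------------
# transforms


def zscore_rows(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Row-wise z-score with sample standard deviation (divisor n - 1).

    Constant rows map to all-zero rows rather than NaN.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("zscore_rows requires a 2-D matrix with >= 2 columns")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def select_fc_bins(profiles: ProfileMatrix, fc_threshold: float) -> list[str]:
    """Genes whose maximum |log2FC| over all conditions reaches the given
    linear fold-change threshold (e.g. 8 selects max |log2FC| >= 3)."""
    if not fc_threshold > 1:
        raise ValueError(f"fc_threshold must be > 1, got {fc_threshold}")
    cut = np.log2(fc_threshold)
    m = profiles.max_abs_log2fc()
    return list(m.index[m >= cut])
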