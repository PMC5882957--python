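"""Pearson correlation, the PCIT significance test and network assembly.

PCIT (partial correlation with information theory) decides which pairwise
co-expression correlations are significant by examining every unordered
gene trio {x, y, z}.  For a trio it computes the three first-order partial
correlations, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

and the trio tolerance

    eps = (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|) / 3 .

An edge (x, y) is flagged non-significant if some third gene z satisfies
|r_xy| < eps * |r_xz| and |r_xy| < eps * |r_yz|; edges never eliminated by
any trio are significant.  The network then keeps the significant edges
whose correlation magnitude clears a hard threshold (0.90 by default).

Numerical guards (degenerate correlations are common on planted noise-free
data): ratio terms whose direct correlation is below 1e-12 in magnitude
are skipped and the tolerance averages the remaining terms; square-root
arguments are clamped at 0 and a vanishing partial-correlation denominator
yields a partial of 0; edges with |r| < 1e-8 are non-significant outright.
``pcit_mask_reference`` is a literal three-nested-loop transcription of
the same rules, kept as an independent check on the vectorised routine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression_io import ProfileMatrix

__all__ = [
    "PcitDiagnostics",
    "pearson_profiles",
    "pcit_mask",
    "pcit_mask_reference",
    "build_network",
]

_TINY_DIRECT = 1e-12  # ratio terms with |direct r| below this are skipped
_MIN_EDGE_R = 1e-8  # edges weaker than this are never significant
_TINY_DENOM = 1e-12  # vanishing partial-correlation denominator


def pearson_profiles(
    profiles: ProfileMatrix | pd.DataFrame, on_zero_variance: str = "error"
) -> pd.DataFrame:
    """Gene-gene Pearson correlations over the full condition vector.

    ``on_zero_variance``: ``'error'`` (default) raises naming the first
    zero-variance gene; ``'drop'`` silently removes such genes.
    Returns a symmetric DataFrame with unit diagonal.
    """
    data = profiles.data if isinstance(profiles, ProfileMatrix) else profiles
    if data.shape[1] < 3:
        raise ValueError(
            f"need >= 3 condition columns for correlations, got {data.shape[1]}"
        )
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = sd == 0
    if flat.any():
        bad = list(data.index[flat])
        if on_zero_variance == "drop":
            data = data.loc[~flat]
            values = values[~flat]
        else:
            raise ValueError(
                f"zero-variance profile for gene(s) {bad[:5]}; "
                "use on_zero_variance='drop' to remove them"
            )
    if values.shape[0] == 1:
        r = np.ones((1, 1))
    else:
        r = np.corrcoef(values)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=data.index, columns=data.index)


@dataclass
class PcitDiagnostics:
    """Summary of the trio computations behind a PCIT mask."""

    n_genes: int
    n_trios: int
    tolerance_mean: float
    tolerance_min: float
    tolerance_max: float
    n_edges_input: int  # off-diagonal |r| >= 1e-8 pairs (upper triangle)
    n_edges_significant: int


def _validate_corr(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {r.shape}")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-10):
        raise ValueError("correlation matrix does not have a unit diagonal")
    if not np.isfinite(r).all():
        raise ValueError("correlation matrix has non-finite entries")
    return r


def pcit_mask(
    r: pd.DataFrame | np.ndarray,
) -> tuple[pd.DataFrame | np.ndarray, PcitDiagnostics]:
    """Vectorised PCIT significance mask.

    Returns ``(mask, diagnostics)`` where ``mask`` is boolean, symmetric,
    with a False diagonal; ``mask[x, y]`` is True iff edge (x, y) survives
    every trio test.  Accepts and returns either DataFrame or ndarray.
    """
    index = r.index if isinstance(r, pd.DataFrame) else None
    rv = _validate_corr(r.to_numpy() if isinstance(r, pd.DataFrame) else r)
    n = rv.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 genes, got {n}")

    abs_r = np.abs(rv)
    off_diag = ~np.eye(n, dtype=bool)
    candidate = (abs_r >= _MIN_EDGE_R) & off_diag
    eliminated = np.zeros((n, n), dtype=bool)

    tol_sum = 0.0
    tol_min = np.inf
    tol_max = -np.inf
    n_trios = 0

    one_minus = np.maximum(1.0 - rv * rv, 0.0)
    sqrt_om = np.sqrt(one_minus)
    iu = np.triu_indices(n, k=1)
    valid_a = abs_r >= _TINY_DIRECT
    safe_abs_r = np.where(valid_a, abs_r, 1.0)

    if n >= 3:
        # preallocated n x n work buffers, reused across z
        buf1 = np.empty((n, n))
        buf2 = np.empty((n, n))
        tol = np.empty((n, n))
        counts = np.empty((n, n))
        for z in range(n):
            rz = rv[:, z]
            abs_rz = abs_r[:, z]
            som_z = sqrt_om[:, z]  # sqrt(1 - r_xz^2) per x

            # term A: |r_xy.z| / |r_xy|
            np.outer(som_z, som_z, out=buf1)  # denominator of r_xy.z
            ok_a = buf1 > _TINY_DENOM
            np.outer(rz, rz, out=buf2)
            np.subtract(rv, buf2, out=buf2)  # numerator r_xy - r_xz r_yz
            np.divide(buf2, buf1, out=buf2, where=ok_a)
            buf2[~ok_a] = 0.0
            np.abs(buf2, out=buf2)
            np.divide(buf2, safe_abs_r, out=buf2)
            buf2[~valid_a] = 0.0
            np.add(buf2, 0.0, out=tol)  # tol accumulates the ratio sum
            counts[:] = valid_a

            # term B: |r_xz.y| / |r_xz|; entry (x, y) of buf2
            np.multiply(sqrt_om, som_z[None, :], out=buf1)  # sqrt((1-rxy^2)(1-ryz^2))
            ok_b = buf1 > _TINY_DENOM
            np.multiply(rv, rz[None, :], out=buf2)
            np.subtract(rz[:, None], buf2, out=buf2)  # r_xz - r_xy r_yz
            np.divide(buf2, buf1, out=buf2, where=ok_b)
            buf2[~ok_b] = 0.0
            np.abs(buf2, out=buf2)
            valid_b = abs_rz >= _TINY_DIRECT
            np.divide(buf2, np.where(valid_b, abs_rz, 1.0)[:, None], out=buf2)
            buf2[~valid_b, :] = 0.0
            tol += buf2
            counts += valid_b[:, None]
            # term C: |r_yz.x| / |r_yz| is the transpose of term B
            tol += buf2.T
            counts += valid_b[None, :]

            usable = counts > 0
            np.divide(tol, counts, out=tol, where=usable)
            tol[~usable] = 0.0

            np.multiply(tol, abs_rz[:, None], out=buf1)
            np.less(abs_r, buf1, out=ok_a)
            np.multiply(tol, abs_rz[None, :], out=buf1)
            cond = ok_a & (abs_r < buf1) & usable
            cond[z, :] = False
            cond[:, z] = False
            np.fill_diagonal(cond, False)
            eliminated |= cond

            # diagnostics over unordered trios: pairs x < y, both != z
            sel = (iu[0] != z) & (iu[1] != z)
            tz = tol[iu][sel]
            uz = usable[iu][sel]
            if uz.any():
                vals = tz[uz]
                tol_sum += float(vals.sum())
                tol_min = min(tol_min, float(vals.min()))
                tol_max = max(tol_max, float(vals.max()))
            n_trios += int(sel.sum())
    # each unordered trio {x, y, z} was visited 3 times (once per member as z)
    n_trios //= 3 if n >= 3 else 1

    mask = candidate & ~eliminated
    mask = mask & mask.T  # elimination is symmetric already; make it explicit

    diag = PcitDiagnostics(
        n_genes=n,
        n_trios=n_trios,
        tolerance_mean=tol_sum / max(1, 3 * n_trios) if n >= 3 else float("nan"),
        tolerance_min=tol_min if np.isfinite(tol_min) else float("nan"),
        tolerance_max=tol_max if np.isfinite(tol_max) else float("nan"),
        n_edges_input=int(candidate[iu].sum()),
        n_edges_significant=int(mask[iu].sum()),
    )
    if index is not None:
        return pd.DataFrame(mask, index=index, columns=index), diag
    return mask, diag


def pcit_mask_reference(r: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Literal triple-loop PCIT, used as an independent oracle in tests.

    Implements exactly the rules documented in the module docstring, one
    scalar trio at a time.  O(n^3); intended for small n only.
    """
    rv = _validate_corr(r.to_numpy() if isinstance(r, pd.DataFrame) else r)
    n = rv.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 genes, got {n}")
    mask = np.abs(rv) >= _MIN_EDGE_R
    np.fill_diagonal(mask, False)

    def partial(rxy: float, rxz: float, ryz: float) -> float:
        denom = np.sqrt(max(1.0 - rxz**2, 0.0) * max(1.0 - ryz**2, 0.0))
        if denom <= _TINY_DENOM:
            return 0.0
        return (rxy - rxz * ryz) / denom

    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                rxy, rxz, ryz = rv[x, y], rv[x, z], rv[y, z]
                terms = []
                if abs(rxy) >= _TINY_DIRECT:
                    terms.append(abs(partial(rxy, rxz, ryz)) / abs(rxy))
                if abs(rxz) >= _TINY_DIRECT:
                    terms.append(abs(partial(rxz, rxy, ryz)) / abs(rxz))
                if abs(ryz) >= _TINY_DIRECT:
                    terms.append(abs(partial(ryz, rxy, rxz)) / abs(ryz))
                if not terms:
                    continue
                tol = sum(terms) / len(terms)
                if abs(rxy) < tol * abs(rxz) and abs(rxy) < tol * abs(ryz):
                    mask[x, y] = mask[y, x] = False
                    break
    return mask


def build_network(
    r: pd.DataFrame,
    mask: pd.DataFrame | np.ndarray,
    min_abs_r: float = 0.90,
    node_attrs: pd.DataFrame | Mapping | None = None,
    threshold_mode: str = "abs",
) -> nx.Graph:
    """Thresholded co-expression network from correlations and a PCIT mask.

    Edge (x, y) is included iff the mask is True and the correlation
    clears the threshold: ``|r| > min_abs_r`` in the default ``'abs'``
    mode, ``r^2 > min_abs_r`` in ``'r2'`` mode.  Isolated nodes are kept.
    ``node_attrs`` (indexed by gene, e.g. the tissue-assignment table)
    must cover every gene when given.
    """
    if not (0 <= min_abs_r < 1):
        raise ValueError(f"min_abs_r must be in [0, 1), got {min_abs_r}")
    if threshold_mode not in ("abs", "r2"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    genes = list(r.index)
    rv = _validate_corr(r.to_numpy())
    mv = mask.to_numpy() if isinstance(mask, pd.DataFrame) else np.asarray(mask)
    if mv.shape != rv.shape:
        raise ValueError(f"mask shape {mv.shape} does not match correlations {rv.shape}")

    if node_attrs is not None and not isinstance(node_attrs, pd.DataFrame):
        node_attrs = pd.DataFrame(node_attrs).T
    if node_attrs is not None:
        missing = [g for g in genes if g not in node_attrs.index]
        if missing:
            raise ValueError(f"node attribute table missing gene(s) {missing[:5]}")

    graph = nx.Graph()
    graph.graph["min_abs_r"] = min_abs_r
    graph.graph["threshold_mode"] = threshold_mode
    for g in genes:
        attrs = node_attrs.loc[g].to_dict() if node_attrs is not None else {}
        graph.add_node(g, **attrs)
    strength = rv**2 if threshold_mode == "r2" else np.abs(rv)
    xs, ys = np.where(np.triu(mv & (strength > min_abs_r), k=1))
    for x, y in zip(xs.tolist(), ys.tolist()):
        graph.add_edge(genes[x], genes[y], r=float(rv[x, y]))
    return graph
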