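"""PCIT: partial-correlation-with-information-theory edge significance.

For every trio of genes (x, y, z) the three first-order partial
correlations are computed; the trio's local tolerance is the average of
the partial-to-direct ratios

    eps = mean(r_xy.z / r_xy, r_xz.y / r_xz, r_yz.x / r_yz)

(ratios whose direct correlation is numerically zero are excluded from
the average).  The pair (x, y) is declared NON-significant only if every
admissible conditioning gene z dominates it, i.e.

    |r_xy| < |eps * r_xz|  and  |r_xy| < |eps * r_yz|   for all z,

otherwise the pair keeps its significance.  Thresholds therefore come
from the data itself rather than from a fixed cut-off.

Two implementations are provided: a plain-Python triple loop
(:func:`pcit_reference`, the normative behaviour) and a numba-compiled
twin (:func:`pcit_fast`) with identical operation order, so their edge
sets agree exactly, not approximately.
"""
from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np

from .datatypes import AwmMatrix, CoassociationNetwork

_DENOM_TOL = 1e-12


def pearson_profile_correlations(awm: AwmMatrix) -> np.ndarray:
    """Pearson correlations between all pairs of gene effect profiles."""
    vals = awm.values.to_numpy(float)
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 trait columns for profile correlations")
    sd = vals.std(axis=1)
    flat = [g for g, s in zip(awm.genes, sd) if s == 0]
    if flat:
        raise ValueError(f"constant effect profiles for genes: {flat}")
    r = np.corrcoef(vals)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z.

    The correlation between x and y that remains after removing the
    linear influence of z.
    """
    for name, v in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    denom = (1.0 - r_xz * r_xz) * (1.0 - r_yz * r_yz)
    if denom <= 0.0:
        raise ValueError("partial correlation undefined: |r_xz| or |r_yz| is 1")
    return (r_xy - r_xz * r_yz) / math.sqrt(denom)


def _pair_significant_py(r: np.ndarray, x: int, y: int) -> bool:
    """Normative per-pair decision: dominated by every admissible z?"""
    n = r.shape[0]
    rxy = r[x, y]
    if rxy == 0.0:
        return False
    any_valid = False
    for z in range(n):
        if z == x or z == y:
            continue
        rxz = r[x, z]
        ryz = r[y, z]
        d1 = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
        d2 = (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
        d3 = (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
        if d1 <= 0.0 or d2 <= 0.0 or d3 <= 0.0:
            continue  # partials undefined for this trio
        pxy = (rxy - rxz * ryz) / math.sqrt(d1)
        pxz = (rxz - rxy * ryz) / math.sqrt(d2)
        pyz = (ryz - rxy * rxz) / math.sqrt(d3)
        s = 0.0
        c = 0
        if abs(rxy) >= _DENOM_TOL:
            s += pxy / rxy
            c += 1
        if abs(rxz) >= _DENOM_TOL:
            s += pxz / rxz
            c += 1
        if abs(ryz) >= _DENOM_TOL:
            s += pyz / ryz
            c += 1
        if c == 0:
            continue  # tolerance undefined; trio skipped for this pair
        eps = s / c
        any_valid = True
        dominated = abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz)
        if not dominated:
            return True
    # every admissible z dominated the pair (or no trio evidence at all)
    return not any_valid


def pcit_reference(r: np.ndarray) -> np.ndarray:
    """Brute-force triple-loop PCIT; the normative implementation."""
    r = np.asarray(r, float)
    n = r.shape[0]
    sig = np.zeros((n, n), dtype=bool)
    if n < 3:
        warnings.warn("PCIT needs at least 3 genes; all nonzero pairs kept", stacklevel=2)
        for x in range(n):
            for y in range(x + 1, n):
                sig[x, y] = sig[y, x] = r[x, y] != 0.0
        return sig
    for x in range(n):
        for y in range(x + 1, n):
            s = _pair_significant_py(r, x, y)
            sig[x, y] = sig[y, x] = s
    return sig


def _make_fast_kernel():
    import numba

    @numba.njit(fastmath=False)
    def kernel(r):  # pragma: no cover - exercised via pcit_fast
        n = r.shape[0]
        sig = np.zeros((n, n), dtype=np.bool_)
        for x in range(n):
            for y in range(x + 1, n):
                rxy = r[x, y]
                if rxy == 0.0:
                    continue
                any_valid = False
                significant = False
                for z in range(n):
                    if z == x or z == y:
                        continue
                    rxz = r[x, z]
                    ryz = r[y, z]
                    d1 = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                    d2 = (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                    d3 = (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                    if d1 <= 0.0 or d2 <= 0.0 or d3 <= 0.0:
                        continue
                    pxy = (rxy - rxz * ryz) / math.sqrt(d1)
                    pxz = (rxz - rxy * ryz) / math.sqrt(d2)
                    pyz = (ryz - rxy * rxz) / math.sqrt(d3)
                    s = 0.0
                    c = 0
                    if abs(rxy) >= _DENOM_TOL:
                        s += pxy / rxy
                        c += 1
                    if abs(rxz) >= _DENOM_TOL:
                        s += pxz / rxz
                        c += 1
                    if abs(ryz) >= _DENOM_TOL:
                        s += pyz / ryz
                        c += 1
                    if c == 0:
                        continue
                    eps = s / c
                    any_valid = True
                    if not (
                        abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz)
                    ):
                        significant = True
                        break
                if significant or not any_valid:
                    sig[x, y] = True
                    sig[y, x] = True
        return sig

    return kernel


_FAST_KERNEL = None


def pcit_fast(r: np.ndarray) -> np.ndarray:
    """Compiled PCIT with operation order identical to the reference."""
    global _FAST_KERNEL
    r = np.ascontiguousarray(np.asarray(r, float))
    n = r.shape[0]
    if n < 3:
        return pcit_reference(r)
    if _FAST_KERNEL is None:
        _FAST_KERNEL = _make_fast_kernel()
    return _FAST_KERNEL(r)


def pcit(r: np.ndarray, method: str = "fast") -> np.ndarray:
    """Symmetric boolean matrix of PCIT-significant pairs."""
    if method == "fast":
        return pcit_fast(r)
    if method == "reference":
        return pcit_reference(r)
    raise ValueError(f"unknown PCIT method {method!r}")


def build_network(
    r: np.ndarray,
    significant: np.ndarray,
    genes: list[str],
    pc_threshold: float = 0.80,
    provenance: dict[str, str] | None = None,
) -> CoassociationNetwork:
    """Edges = PCIT-significant pairs with |r| >= threshold (inclusive).

    The sign of r is kept as edge metadata but plays no role in the
    topology.  All genes appear as nodes; isolated ones simply have
    degree zero.
    """
    r = np.asarray(r, float)
    significant = np.asarray(significant, bool)
    if r.shape != significant.shape or r.shape[0] != len(genes):
        raise ValueError("correlation/significance matrices and gene list misaligned")
    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, provenance=(provenance or {}).get(gene))
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if significant[i, j] and abs(r[i, j]) >= pc_threshold:
                g.add_edge(genes[i], genes[j], r=float(r[i, j]))
    return CoassociationNetwork(g)


def network_from_awm(
    awm: AwmMatrix, pc_threshold: float = 0.80, method: str = "fast"
) -> tuple[CoassociationNetwork, np.ndarray, np.ndarray]:
    """AWM -> (network, r matrix, significance matrix) in one call."""
    r = pearson_profile_correlations(awm)
    sig = pcit(r, method=method)
    prov = awm.gene_info["provenance"].to_dict()
    net = build_network(r, sig, awm.genes, pc_threshold, prov)
    return net, r, sig
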