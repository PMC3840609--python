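"""Independent reference computations used to check the implementation.

Everything here is deliberately naive: recursive kinship coefficients,
precision-matrix partial correlations, brute-force selection scans.
None of it shares code with the package.
"""
from __future__ import annotations

import numpy as np


def kinship(ped: dict[str, tuple[str | None, str | None]], a: str, b: str, _memo=None) -> float:
    """Recursive kinship coefficient phi(a, b); A = 2 * phi."""
    if _memo is None:
        _memo = {}
    key = (a, b) if a <= b else (b, a)
    if key in _memo:
        return _memo[key]
    order = {x: i for i, x in enumerate(_topo(ped))}
    if order[a] < order[b]:
        a, b = b, a  # a is the younger (later) animal
    sa, da = ped[a]
    if a == b:
        phi = 0.5 * (1.0 + (kinship(ped, sa, da, _memo) if sa and da else 0.0))
    else:
        phi = 0.0
        if sa:
            phi += 0.5 * kinship(ped, sa, b, _memo)
        if da:
            phi += 0.5 * kinship(ped, da, b, _memo)
    _memo[key] = phi
    return phi


def _topo(ped):
    out, seen = [], set()

    def visit(x):
        if x in seen or x is None:
            return
        s, d = ped[x]
        visit(s)
        visit(d)
        seen.add(x)
        out.append(x)

    for x in ped:
        visit(x)
    return out


def relationship_matrix(ped: dict[str, tuple[str | None, str | None]]) -> np.ndarray:
    animals = list(ped)
    memo: dict = {}
    A = np.array([[2.0 * kinship(ped, a, b, memo) for b in animals] for a in animals])
    return A


def partial_from_precision(r3: np.ndarray) -> float:
    """r_01.2 from the inverse of a 3x3 correlation matrix."""
    p = np.linalg.inv(r3)
    return -p[0, 1] / np.sqrt(p[0, 0] * p[1, 1])


def random_correlation(n_vars: int, rng: np.random.Generator, n_obs: int | None = None) -> np.ndarray:
    """Correlation matrix of random Gaussian data (always valid PSD)."""
    x = rng.standard_normal((n_obs or (n_vars + 5), n_vars))
    return np.corrcoef(x, rowvar=False)


def ancestors(ped: dict[str, tuple[str | None, str | None]], a: str) -> set[str]:
    """Exhaustive ancestor walk (cycle-safe via visited set)."""
    out: set[str] = set()
    stack = [p for p in ped[a] if p]
    while stack:
        x = stack.pop()
        if x in out:
            continue
        out.add(x)
        stack.extend(p for p in ped.get(x, (None, None)) if p)
    return out


def ols_fit(y: np.ndarray, X: np.ndarray):
    """(beta, rss) by plain least squares."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def pcit_trio_oracle(r: np.ndarray) -> np.ndarray:
    """Direct evaluation of the PCIT decision rule, written independently.

    A pair is non-significant only when every conditioning gene with a
    defined tolerance dominates it.
    """
    n = r.shape[0]
    sig = np.zeros((n, n), bool)
    for x in range(n):
        for y in range(n):
            if x >= y:
                continue
            rxy = r[x, y]
            if rxy == 0:
                continue
            verdicts = []
            for z in range(n):
                if z in (x, y):
                    continue
                rxz, ryz = r[x, z], r[y, z]
                d1 = (1 - rxz**2) * (1 - ryz**2)
                d2 = (1 - rxy**2) * (1 - ryz**2)
                d3 = (1 - rxy**2) * (1 - rxz**2)
                if min(d1, d2, d3) <= 0:
                    continue
                partials = {
                    "xy": (rxy - rxz * ryz) / np.sqrt(d1),
                    "xz": (rxz - rxy * ryz) / np.sqrt(d2),
                    "yz": (ryz - rxy * rxz) / np.sqrt(d3),
                }
                ratios = []
                for key, direct in (("xy", rxy), ("xz", rxz), ("yz", ryz)):
                    if abs(direct) >= 1e-12:
                        ratios.append(partials[key] / direct)
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                verdicts.append(abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz))
            keep = (not verdicts) or (not all(verdicts))
            sig[x, y] = sig[y, x] = keep
    return sig
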