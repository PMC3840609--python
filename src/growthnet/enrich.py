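"""Binomial over-representation test with Bonferroni correction.

Given a gene list (e.g. the network's nodes), a reference gene list and
a gene-to-term annotation, each term is tested for over-representation
with an exact binomial upper tail: with n annotated list genes and a
term covering a fraction p of annotated reference genes,

    p_raw = P(X >= n_observed),  X ~ Binomial(n, p).

Genes without any annotation are excluded from both totals; the
correction multiplies by the number of terms tested and caps at 1.
Annotation content (GO, pathways, ...) is supplied by the user.
"""
from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _as_mapping(annotation) -> dict[str, set[str]]:
    if isinstance(annotation, pd.DataFrame):
        gcol, tcol = annotation.columns[:2]
        out: dict[str, set[str]] = {}
        for g, t in zip(annotation[gcol].astype(str), annotation[tcol].astype(str)):
            out.setdefault(g, set()).add(t)
        return out
    return {str(g): set(map(str, ts)) for g, ts in dict(annotation).items()}


def binomial_enrichment(
    network_genes: set[str],
    reference_genes: set[str],
    annotation,
) -> pd.DataFrame:
    """Per-term over-representation of ``network_genes`` vs the reference.

    ``annotation`` is a gene -> terms mapping or a two-column (gene,
    term) DataFrame.  Returns one row per term with columns ``term``,
    ``n_reference``, ``n_observed``, ``n_expected``, ``p_raw`` and
    ``p_bonferroni``, sorted by raw p-value.
    """
    ann = _as_mapping(annotation)
    if not ann:
        raise ValueError("annotation is empty")
    network_genes = set(map(str, network_genes))
    reference_genes = set(map(str, reference_genes))
    stray = network_genes - reference_genes
    if stray:
        log.warning("%d list genes absent from the reference were dropped", len(stray))
        network_genes = network_genes & reference_genes

    annotated_ref = {g for g in reference_genes if ann.get(g)}
    annotated_net = {g for g in network_genes if ann.get(g)}
    if not annotated_net:
        raise ValueError("no annotated genes in the input list")
    n = len(annotated_net)
    big_n = len(annotated_ref)

    terms = sorted({t for g in annotated_ref for t in ann[g]})
    rows = []
    for term in terms:
        n_ref = sum(1 for g in annotated_ref if term in ann[g])
        n_obs = sum(1 for g in annotated_net if term in ann[g])
        p = n_ref / big_n
        p_raw = float(stats.binom.sf(n_obs - 1, n, p)) if n_obs > 0 else 1.0
        rows.append((term, n_ref, n_obs, n * p, min(p_raw, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "n_reference", "n_observed", "n_expected", "p_raw"]
    )
    out["p_bonferroni"] = (out["p_raw"] * len(terms)).clip(upper=1.0)
    return out.sort_values(["p_raw", "term"]).reset_index(drop=True)
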