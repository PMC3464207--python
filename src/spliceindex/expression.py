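"""Gene-level differential expression and gene-set overrepresentation.

The gene test is the same pooled two-sample Student t as the splicing caller,
applied to log2 gene signals; selection uses the 1.5-fold change and 0.15
FDR cutoffs with Benjamini-Hochberg step-up q-values; overrepresentation of a
reference gene set among the selected genes is a Pearson chi-square on the
2x2 membership table (df=1, no continuity correction), with a Fisher exact
fallback reported when an expected cell drops below 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .splicecall import ttest_two_tailed

__all__ = [
    "bh_fdr",
    "differential_expression",
    "select_changed_genes",
    "geneset_chi2",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def differential_expression(gene_signal: pd.DataFrame, genotypes: pd.Series) -> pd.DataFrame:
    """Per-gene fold change (mutant/control, linear) and pooled-t P with BH q."""
    ctrl = genotypes.index[genotypes == "control"]
    mut = genotypes.index[genotypes == "mutant"]
    log2 = np.log2(gene_signal)
    rows = []
    for gene in gene_signal.index:
        a = log2.loc[gene, ctrl].to_numpy(dtype=float)
        b = log2.loc[gene, mut].to_numpy(dtype=float)
        t, p = ttest_two_tailed(a, b)
        rows.append(
            dict(
                gene_id=gene,
                mean_control=float(gene_signal.loc[gene, ctrl].mean()),
                mean_mutant=float(gene_signal.loc[gene, mut].mean()),
                fold_change=float(2.0 ** (b.mean() - a.mean())),
                t=t,
                p=p,
            )
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def select_changed_genes(
    results: pd.DataFrame, min_fold: float = 1.5, max_fdr: float = 0.15
) -> dict[str, list[str]]:
    """Genes changed at least ``min_fold``-fold with q <= ``max_fdr`` (inclusive),
    split into up- and down-regulated lists; ``top_n_down`` style ranking is
    available by sorting the returned results frame on fold change."""
    fc = results["fold_change"]
    sig = results["q"] <= max_fdr
    up = results.loc[sig & (fc >= min_fold), "gene_id"].tolist()
    down = results.loc[sig & (fc <= 1.0 / min_fold), "gene_id"].tolist()
    return {"up": up, "down": down}


def geneset_chi2(selected, reference_set, universe) -> tuple[float, float, np.ndarray]:
    """Overrepresentation of ``reference_set`` among ``selected`` within ``universe``.

    Pearson chi-square without continuity correction on the 2x2 membership
    table, df=1.  When any expected cell is below 1 a warning carries the
    Fisher exact P alongside.
    """
    sel = set(selected)
    ref = set(reference_set)
    uni = set(universe)
    if not sel <= uni or not ref <= uni:
        raise ValueError("selected and reference sets must lie within the universe")
    a = len(sel & ref)
    b = len(sel - ref)
    c = len(ref - sel)
    d = len(uni - sel - ref)
    table = np.array([[a, b], [c, d]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("degenerate 2x2 table (empty margin)")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    if np.any(expected < 1):
        _, fisher_p = stats.fisher_exact(table.astype(int))
        warnings.warn(f"expected cell < 1; Fisher exact P = {fisher_p:.3g}")
    return chi2, p, table
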