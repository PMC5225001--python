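"""Over-representation analysis of gene sets against functional annotation.

One-sided Fisher's exact test (hypergeometric upper tail) of a foreground
gene set against GO-domain and pathway term annotation, with
Benjamini-Hochberg FDR applied separately within each annotation domain
(BP, MF, CC, pathway), mirroring how the four definitions are usually
reported as separate panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

DOMAINS = ("BP", "MF", "CC", "pathway")


@dataclass(frozen=True)
class TermAnnotation:
    """A functional term: GO category or pathway with its member genes."""

    term_id: str
    label: str
    domain: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")


def annotation_universe(annotation: Iterable[TermAnnotation]) -> frozenset[str]:
    """All genes mentioned by at least one term."""
    out: set[str] = set()
    for t in annotation:
        out |= t.genes
    return frozenset(out)


def fisher_enrichment(
    foreground: Iterable[str],
    annotation: Iterable[TermAnnotation],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided over-representation test per term.

    For a term with ``K`` background members, foreground of size ``n`` drawn
    from a background of size ``N``, the over-representation p-value of an
    observed overlap ``k`` is the hypergeometric upper tail ``P(X >= k)``.
    Terms with ``k = 0`` are excluded from the tested family; BH adjustment
    runs separately within each domain.

    Returns columns: term_id, label, domain, k, n, K, N, pvalue, fdr,
    fold_enrichment, neg_log2_p.
    """
    from .de import bh_fdr

    fg = set(foreground)
    bg = set(background)
    if len(bg) < 2:
        raise ValueError("background must contain at least 2 genes")
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground genes outside the background: {sorted(stray)}")
    N, n = len(bg), len(fg)

    rows = []
    for term in annotation:
        members = term.genes & bg
        K = len(members)
        k = len(fg & members)
        if k == 0 or K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        fe = (k / n) / (K / N) if n else 0.0
        rows.append((term.term_id, term.label, term.domain, k, n, K, N, p, fe))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "label", "domain", "k", "n", "K", "N", "pvalue", "fold_enrichment"],
    )
    out["fdr"] = np.nan
    for dom, idx in out.groupby("domain").groups.items():
        out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "pvalue"].to_numpy())
    out["neg_log2_p"] = -np.log2(out["pvalue"])
    return out[
        ["term_id", "label", "domain", "k", "n", "K", "N",
         "pvalue", "fdr", "fold_enrichment", "neg_log2_p"]
    ]


def significant_terms(
    results: pd.DataFrame, alpha: float = 0.05, fdr: float = 0.05
) -> pd.DataFrame:
    """Terms passing both gates (p < alpha and FDR < fdr), most significant
    first (descending -log2 p)."""
    if results.empty:
        return results.copy()
    keep = (results["pvalue"] < alpha) & (results["fdr"] < fdr)
    return (
        results.loc[keep]
        .sort_values("neg_log2_p", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
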