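"""Seed-complementarity target prediction and anti-correlation filtering.

Candidate miRNA targets are found by exact canonical seed matching on
3'UTRs (site classes 6mer, 7mer-A1, 7mer-m8, 8mer; no G:U wobble), scored
by a fixed per-class weight, and then reduced by the negative-correlation
rule: a prediction survives only when the miRNA is significantly
differentially expressed and the gene is significantly differentially
expressed in the opposite direction.  Seed prediction alone massively
over-calls; the anti-correlation intersection is what makes the target
lists small enough to interpret.

Site classes on the UTR sense strand, for a miRNA with seed positions 2-8:

    6mer      reverse complement of positions 2-7
    7mer-A1   6mer followed by an A (facing miRNA position 1)
    7mer-m8   reverse complement of positions 2-8
    8mer      7mer-m8 followed by an A
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seq import revcomp_rna, to_rna

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Per-site weights: one strong site (7mer-m8/8mer) or two weak ones reach
#: the default emission threshold of 2.
SITE_WEIGHTS = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 1.5, "6mer": 1.0}


@dataclass(frozen=True)
class SeedSite:
    """One seed match on a UTR; positions are 1-based inclusive on the
    sense strand."""

    gene_id: str
    start: int
    end: int
    site_class: str

    _CLASS_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.end - self.start + 1 != self._CLASS_LENGTH[self.site_class]:
            raise ValueError("site interval does not match its class length")


def seed_patterns(mirna: str) -> dict[str, str]:
    """UTR match patterns of the four site classes for one miRNA."""
    m = to_rna(mirna)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt to define a seed")
    core6 = revcomp_rna(m[1:7])
    core7 = revcomp_rna(m[1:8])
    return {"8mer": core7 + "A", "7mer-m8": core7, "7mer-A1": core6 + "A", "6mer": core6}


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_seed_sites(mirna: str, utr: str, gene_id: str = "") -> list[SeedSite]:
    """All seed sites of one miRNA on one UTR.

    Overlapping matches are all reported, but a match whose interval is
    contained in a longer-class match at the same locus is suppressed
    (an 8mer is not additionally counted as its nested 7mers and 6mer).
    """
    pats = seed_patterns(mirna)
    u = to_rna(utr)
    raw: list[tuple[int, int, str]] = []  # (start0, end0, class)
    for cls in SITE_CLASSES:
        for pos in _find_all(u, pats[cls]):
            raw.append((pos, pos + len(pats[cls]) - 1, cls))
    sites: list[SeedSite] = []
    for s, e, cls in raw:
        ln = e - s + 1
        nested = any(
            (s2 <= s and e <= e2) and (e2 - s2 + 1) > ln for s2, e2, _ in raw
        )
        if not nested:
            sites.append(SeedSite(gene_id=gene_id, start=s + 1, end=e + 1, site_class=cls))
    sites.sort(key=lambda x: (x.start, x.end))
    return sites


def predict_targets(
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    min_score: float = 2.0,
    weights: Mapping[str, float] = SITE_WEIGHTS,
) -> pd.DataFrame:
    """Candidate (miRNA, gene) pairs with per-class site counts and score.

    score = 3*n_8mer + 2*n_7mer-m8 + 1.5*n_7mer-A1 + 1*n_6mer; pairs with
    score >= ``min_score`` are emitted.
    """
    rows = []
    for mid, mseq in mirnas.items():
        pats = seed_patterns(mseq)  # validates length once per miRNA
        del pats
        for gid, useq in utrs.items():
            sites = find_seed_sites(mseq, useq, gene_id=gid)
            if not sites:
                continue
            n = {cls: sum(1 for s in sites if s.site_class == cls) for cls in SITE_CLASSES}
            score = sum(weights[cls] * n[cls] for cls in SITE_CLASSES)
            if score >= min_score:
                rows.append(
                    (mid, gid, n["8mer"], n["7mer-m8"], n["7mer-A1"], n["6mer"], score)
                )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "n_8mer", "n_7mer_m8", "n_7mer_a1", "n_6mer", "score"],
    )


def negative_correlation_filter(
    predictions: pd.DataFrame,
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Keep predictions anti-correlated with the mRNA response.

    A pair (m, g) survives iff m is a significant DE miRNA, g passes
    p < ``alpha`` and FDR < ``fdr`` in the mRNA table, and the two log2
    fold changes have opposite signs.  The output is a subset of the input
    with ``passed_negative_correlation`` set.
    """
    required = {"gene_id", "log2fc", "pvalue", "fdr"}
    missing = required - set(mrna_de.columns)
    if missing:
        raise ValueError(f"mrna_de lacks columns: {sorted(missing)}")
    mrna = mrna_de.set_index("gene_id") if mrna_de.index.name != "gene_id" else mrna_de

    sig_mirnas = mirna_de.index[mirna_de["significant"]]
    mirna_sign = np.sign(mirna_de["log2fc"])

    keep = []
    for row in predictions.itertuples(index=True):
        if row.mirna_id not in sig_mirnas:
            continue
        if row.gene_id not in mrna.index:
            continue
        g = mrna.loc[row.gene_id]
        if not (g["pvalue"] < alpha and g["fdr"] < fdr):
            continue
        if np.sign(g["log2fc"]) == -mirna_sign[row.mirna_id] != 0:
            keep.append(row.Index)
    out = predictions.loc[keep].copy()
    out["passed_negative_correlation"] = True
    return out


def targets_by_mirna(filtered: pd.DataFrame) -> dict[str, frozenset[str]]:
    """miRNA id -> set of surviving target genes."""
    return {
        mid: frozenset(sub["gene_id"])
        for mid, sub in filtered.groupby("mirna_id", sort=True)
    }
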