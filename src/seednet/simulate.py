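"""Synthetic study generator with known planted truth.

Emulates a two-condition, unreplicated small-RNA sequencing experiment on a
species with an incomplete miRNA annotation (the zebrafish situation): a
species-ordered mature-miRNA reference, Truseq-style small-RNA FASTQ
libraries, a fast count-matrix path for differential-expression tests, an
mRNA differential-expression table with 3'UTRs hosting seed sites for
planted regulator-target pairs, and GO/pathway-style annotation with
planted enriched terms.

Every generator is fully determined by its ``seed``; the planted truth is
recoverable from the outputs by brute force (seed-site scan, sign
comparison), which is what the test suite does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import TermAnnotation
from .seq import RNA_ALPHABET, kmers, revcomp_rna, species_of, to_dna, to_rna

#: Species search order used throughout: focal species first, then the
#: mammalian references used to rescue reads absent from the focal database.
DEFAULT_SPECIES_ORDER = ("dre", "rno", "mmu", "hsa")

#: Default planted differentially expressed miRNAs: nine downregulated and
#: three upregulated, two of them only present in rodent references
#: ("cross-species" features the focal database lacks).
DOWN_MIRNAS = (
    "dre-miR-142a-3p",
    "dre-miR-142b-5p",
    "dre-miR-144-3p",
    "dre-miR-146a",
    "dre-miR-190a",
    "dre-miR-219-5p",
    "dre-miR-301b-3p",
    "dre-miR-459-5p",
    "rno-miR-33-5p",
)
UP_MIRNAS = (
    "dre-miR-735-3p",
    "dre-miR-735-5p",
    "mmu-miR-6240",
)

#: Minimum overlap guaranteeing unambiguous read-to-reference assignment.
UNIQUE_KMER = 17

_REJECTION_CAP = 10_000


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into every synthetic artifact.

    Attributes
    ----------
    de_mirnas:
        ``(mirna_id, species_tag, signed log2 effect)`` per differentially
        expressed miRNA.  Positive effect = upregulated under treatment.
    target_map:
        miRNA id -> set of gene ids carrying an anti-correlated planted
        mRNA effect and at least one seed site in their UTR.
    enriched_terms:
        ``(term_id, domain_tag, planted overlap size)`` per planted
        enriched annotation term.
    seed:
        Root seed; fully determines all generator outputs.
    """

    de_mirnas: tuple[tuple[str, str, float], ...]
    target_map: dict[str, frozenset[str]]
    enriched_terms: tuple[tuple[str, str, int], ...]
    seed: int

    def __post_init__(self) -> None:
        ids = {m for m, _, _ in self.de_mirnas}
        orphans = set(self.target_map) - ids
        if orphans:
            raise ValueError(f"target_map miRNAs absent from de_mirnas: {sorted(orphans)}")
        for mid, sp, eff in self.de_mirnas:
            if species_of(mid) != sp:
                raise ValueError(f"id {mid!r} does not carry species tag {sp!r}")
            if abs(eff) > 8:
                raise ValueError(f"planted |log2 effect| > 8 for {mid}")

    @property
    def effects(self) -> dict[str, float]:
        return {m: e for m, _, e in self.de_mirnas}

    def targets_of_direction(self, direction: str) -> frozenset[str]:
        """Union of planted target genes of miRNAs with the given direction."""
        sign = 1 if direction == "up" else -1
        out: set[str] = set()
        for mid, _, eff in self.de_mirnas:
            if np.sign(eff) == sign:
                out |= self.target_map.get(mid, frozenset())
        return frozenset(out)

    @property
    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.target_map.values():
            out |= genes
        return frozenset(out)

    def to_json(self) -> str:
        payload = {
            "de_mirnas": [list(t) for t in self.de_mirnas],
            "target_map": {m: sorted(g) for m, g in self.target_map.items()},
            "enriched_terms": [list(t) for t in self.enriched_terms],
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            de_mirnas=tuple((m, s, float(e)) for m, s, e in d["de_mirnas"]),
            target_map={m: frozenset(g) for m, g in d["target_map"].items()},
            enriched_terms=tuple((t, dom, int(k)) for t, dom, k in d["enriched_terms"]),
            seed=int(d["seed"]),
        )


def make_planted_truth(
    seed: int = 0,
    effect: float = 2.0,
    targets_per_mirna: int = 8,
    term_overlap: int = 5,
) -> PlantedTruth:
    """Default study design: 9 down / 3 up planted miRNAs (two of them
    cross-species), disjoint anti-correlated target sets, and one planted
    enriched term per annotation domain."""
    de = tuple(
        [(m, species_of(m), -abs(effect)) for m in DOWN_MIRNAS]
        + [(m, species_of(m), abs(effect)) for m in UP_MIRNAS]
    )
    target_map: dict[str, frozenset[str]] = {}
    nxt = 1
    for mid, _, _ in de:
        target_map[mid] = frozenset(_gene_id(i) for i in range(nxt, nxt + targets_per_mirna))
        nxt += targets_per_mirna
    terms = tuple(
        (f"TERM_{dom}{i:02d}", dom, term_overlap)
        for dom in ("BP", "MF", "CC", "pathway")
        for i in (1, 2)
    )
    return PlantedTruth(de_mirnas=de, target_map=target_map, enriched_terms=terms, seed=seed)


# ---------------------------------------------------------------------------
# reference and reads
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_ALPHABET), size=length))


def generate_mirna_reference(
    n_per_species: int,
    length_range: tuple[int, int] = (20, 24),
    seed: int = 0,
    species_order: tuple[str, ...] = DEFAULT_SPECIES_ORDER,
    named: list[tuple[str, str]] | None = None,
) -> list[SeqRecord]:
    """Species-ordered mature miRNA reference with unambiguous sequences.

    Generates ``n_per_species`` anonymous mature sequences per species tag,
    plus optional ``named`` ``(mirna_id, species)`` entries, such that no
    two sequences in the whole reference share a 17-nt substring.  That
    guarantees every sufficiently long read maps to at most one miRNA.
    """
    lo, hi = length_range
    if lo < 18 or hi > 26 or lo > hi:
        raise ValueError("length_range must lie within [18, 26]")
    if n_per_species < 0:
        raise ValueError("n_per_species must be >= 0")
    rng = np.random.default_rng(seed)
    named = list(named or [])
    for mid, sp in named:
        if sp not in species_order:
            raise ValueError(f"unknown species tag {sp!r} for {mid!r}")
        if species_of(mid) != sp:
            raise ValueError(f"id {mid!r} must be prefixed by its species tag {sp!r}")

    seen: set[str] = set()
    records: list[SeqRecord] = []

    def _draw(mirna_id: str, description: str) -> None:
        for _ in range(_REJECTION_CAP):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_rna(rng, length)
            ks = kmers(seq, UNIQUE_KMER)
            if ks and not (ks & seen):
                seen.update(ks)
                records.append(SeqRecord(Seq(seq), id=mirna_id, description=description))
                return
        raise RuntimeError(
            f"could not draw a sequence with unique {UNIQUE_KMER}-mers for "
            f"{mirna_id} after {_REJECTION_CAP} attempts"
        )

    for sp in species_order:
        for mid, msp in named:
            if msp == sp:
                _draw(mid, f"{sp} mature miRNA (planted)")
        for j in range(n_per_species):
            _draw(f"{sp}-miR-s{j + 1:03d}", f"{sp} mature miRNA")
    return records


@dataclass(frozen=True)
class QualityProfile:
    """Per-base Phred model: a good-read mode plus a degraded-read mode that
    exercises the quality filter."""

    mean: float = 36.0
    sd: float = 2.0
    degraded_fraction: float = 0.02
    degraded_mean: float = 12.0
    degraded_sd: float = 3.0


def generate_reads(
    reference: list[SeqRecord],
    abundance: dict[str, float],
    adapter: str = "TGGAATTCTCGGGTGCCAAGG",
    qual_profile: QualityProfile | None = None,
    contaminant_fraction: float = 0.0,
    read_length: int = 36,
    seed: int = 0,
) -> list[SeqRecord]:
    """Simulate a Truseq-style small-RNA library (single-end, Phred+33).

    Per-feature read counts are Poisson with the given expected
    ``abundance``; each read is the mature sequence (with occasional 1-nt
    3' trimming or extension) followed by the 3' adapter, truncated to the
    machine read length.  Contaminant reads are uniform random sequence.
    The source feature is recorded in the read id after the last ``|``.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    if any(v < 0 for v in abundance.values()):
        raise ValueError("abundances must be nonnegative")
    if not 0 <= contaminant_fraction < 1:
        raise ValueError("contaminant_fraction must be in [0, 1)")
    if abundance and sum(abundance.values()) > 0 and not reference:
        raise ValueError("nonzero abundance requires a nonempty reference")
    qual = qual_profile or QualityProfile()
    rng = np.random.default_rng(seed)
    seqs = {r.id: to_dna(str(r.seq)) for r in reference}
    missing = set(abundance) - set(seqs)
    if missing:
        raise ValueError(f"abundance refers to unknown features: {sorted(missing)}")
    adapter = to_dna(adapter)

    total = float(sum(abundance.values()))
    plan: list[str] = []
    for fid in sorted(abundance):
        plan.extend([fid] * int(rng.poisson(abundance[fid])))
    if contaminant_fraction > 0 and total > 0:
        lam = contaminant_fraction / (1.0 - contaminant_fraction) * total
        plan.extend(["*contaminant*"] * int(rng.poisson(lam)))
    rng.shuffle(plan)

    reads: list[SeqRecord] = []
    for i, fid in enumerate(plan):
        if fid == "*contaminant*":
            insert = "".join(rng.choice(list("ACGT"), size=read_length))
            seq = insert[:read_length]
        else:
            insert = seqs[fid]
            u = rng.random()
            if u < 0.10:  # 3' trimming by one base
                insert = insert[:-1]
            elif u < 0.15:  # 3' non-templated addition
                insert = insert + str(rng.choice(list("ACGT")))
            seq = (insert + adapter)[:read_length]
        if rng.random() < qual.degraded_fraction:
            q = rng.normal(qual.degraded_mean, qual.degraded_sd, size=len(seq))
        else:
            q = rng.normal(qual.mean, qual.sd, size=len(seq))
        phred = np.clip(np.rint(q), 2, 40).astype(int).tolist()
        rec = SeqRecord(Seq(seq), id=f"r{i:07d}|{fid.strip('*')}", description="")
        rec.letter_annotations["phred_quality"] = phred
        reads.append(rec)
    return reads


# ---------------------------------------------------------------------------
# fast count path
# ---------------------------------------------------------------------------

def generate_count_matrix(
    truth: PlantedTruth,
    n_features: int = 300,
    depth: int = 1_000_000,
    dispersion: float = 0.0,
    seed: int = 0,
    base_cpm_range: tuple[float, float] = (50.0, 2000.0),
    sample_names: tuple[str, str] = ("control", "treated"),
) -> pd.DataFrame:
    """Two-column (control, treated) count matrix, bypassing read simulation.

    Null features share the same expected CPM in both libraries; planted
    features have expected treated/control ratio ``2**effect``.  Baseline
    expression is log-uniform over ``base_cpm_range``, reflecting the
    strongly skewed abundance of real small-RNA libraries.  Counts are
    multinomial per library, so each column sums to ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    planted = [m for m, _, _ in truth.de_mirnas]
    if n_features < len(planted):
        raise ValueError("n_features smaller than the number of planted miRNAs")
    rng = np.random.default_rng(seed)
    features = planted + [f"dre-miR-n{i + 1:04d}" for i in range(n_features - len(planted))]
    lo, hi = base_cpm_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))
    eff = np.array([truth.effects.get(f, 0.0) for f in features])
    expected = np.column_stack([base, base * 2.0 ** eff])
    if dispersion > 0:
        expected = expected * rng.lognormal(0.0, dispersion, size=expected.shape)
    counts = np.column_stack(
        [rng.multinomial(depth, expected[:, j] / expected[:, j].sum()) for j in range(2)]
    )
    return pd.DataFrame(counts, index=pd.Index(features, name="feature_id"), columns=list(sample_names))


# ---------------------------------------------------------------------------
# mRNA side: DE table and UTRs
# ---------------------------------------------------------------------------

def _seed_patterns(mirna_rna: str) -> dict[str, str]:
    core6 = revcomp_rna(mirna_rna[1:7])  # seed positions 2-7
    core7 = revcomp_rna(mirna_rna[1:8])  # seed positions 2-8
    return {"6mer": core6, "7mer-A1": core6 + "A", "7mer-m8": core7, "8mer": core7 + "A"}


def generate_mrna_side(
    truth: PlantedTruth,
    reference: list[SeqRecord],
    n_genes: int = 2000,
    utr_length: int = 500,
    seed: int = 0,
    decoys_per_mirna: int = 0,
) -> tuple[pd.DataFrame, list[SeqRecord], dict[str, frozenset[str]]]:
    """mRNA DE table plus 3'UTR records hosting the planted seed sites.

    Planted target genes receive one exact 7mer-m8 or 8mer site of their
    regulator and a significant DE record of the opposite sign; optional
    decoy genes receive a site but a *same*-sign significant DE record
    (false positives the anti-correlation filter must remove).  All other
    UTRs are rejection-sampled to contain no seed match of any planted DE
    miRNA.  Returns ``(de_table, utr_records, decoy_map)``.
    """
    from .de import bh_fdr  # local import avoids a cycle at module load

    rng = np.random.default_rng(seed)
    seqmap = {r.id: to_rna(str(r.seq)) for r in reference}
    missing = set(truth.target_map) - set(seqmap)
    if missing:
        raise ValueError(f"reference lacks planted miRNAs: {sorted(missing)}")
    if utr_length < 8:
        raise ValueError("utr_length too short to host a seed site")

    effects = truth.effects
    patterns = {m: _seed_patterns(seqmap[m]) for m in effects if m in seqmap}
    forbidden = [p["6mer"] for p in patterns.values()]

    hosts: dict[str, list[str]] = {}  # gene -> miRNAs whose site it hosts
    for m, genes in truth.target_map.items():
        for g in genes:
            hosts.setdefault(g, []).append(m)
    n_planted = len(hosts)
    genes = [_gene_id(i) for i in range(1, n_genes + 1)]
    if set(hosts) - set(genes):
        raise ValueError("n_genes too small for the planted target genes")

    free = [g for g in genes if g not in hosts]
    decoy_map: dict[str, frozenset[str]] = {}
    if decoys_per_mirna > 0:
        if decoys_per_mirna * len(effects) > len(free):
            raise ValueError("n_genes too small for the requested decoys")
        pool = list(free)
        for m in effects:
            picked = [pool.pop() for _ in range(decoys_per_mirna)]
            decoy_map[m] = frozenset(picked)
            for g in picked:
                hosts.setdefault(g, []).append(m)
        free = pool

    def _clean_utr() -> str:
        for _ in range(_REJECTION_CAP):
            u = _random_rna(rng, utr_length)
            if not any(f in u for f in forbidden):
                return u
        raise RuntimeError("rejection sampling failed to produce a site-free UTR")

    utrs: list[SeqRecord] = []
    for g in genes:
        owners = hosts.get(g, [])
        for _ in range(_REJECTION_CAP):
            u = _clean_utr()
            windows: list[tuple[int, int]] = []
            for m in owners:
                cls = str(rng.choice(["7mer-m8", "8mer"]))
                site = patterns[m][cls]
                pos = int(rng.integers(0, utr_length - len(site) + 1))
                u = u[:pos] + site + u[pos + len(site):]
                windows.append((pos, pos + len(site)))
            # overwriting may create a junction match for a non-owner; scan
            # with the planted windows masked (a non-owner 6mer *inside* a
            # planted site is unavoidable when patterns overlap)
            masked = list(u)
            for a, b in windows:
                masked[a:b] = "N" * (b - a)
            masked_u = "".join(masked)
            clean = not any(
                f in masked_u for m2, f in zip(patterns, forbidden) if m2 not in owners
            )
            if clean and all(patterns[m]["6mer"] in u for m in owners):
                break
        else:  # pragma: no cover - rejection cap
            raise RuntimeError(f"could not build UTR for {g}")
        utrs.append(SeqRecord(Seq(u), id=g, description="3'UTR"))

    # DE table: targets anti-correlated, decoys co-directional, rest null
    target_of: dict[str, str] = {}
    for m, gs in truth.target_map.items():
        for g in gs:
            target_of[g] = m
    decoy_of: dict[str, str] = {}
    for m, gs in decoy_map.items():
        for g in gs:
            decoy_of[g] = m

    log2fc = np.empty(n_genes)
    pval = np.empty(n_genes)
    for i, g in enumerate(genes):
        if g in target_of:
            sgn = -np.sign(effects[target_of[g]])
        elif g in decoy_of:
            sgn = np.sign(effects[decoy_of[g]])
        else:
            sgn = 0.0
        if sgn != 0.0:
            log2fc[i] = sgn * rng.uniform(1.0, 3.0)
            pval[i] = 10.0 ** (-rng.uniform(3.0, 8.0))
        else:
            log2fc[i] = rng.normal(0.0, 0.4)
            pval[i] = rng.uniform()
    table = pd.DataFrame(
        {"gene_id": genes, "log2fc": log2fc, "pvalue": pval, "fdr": bh_fdr(pval)}
    )
    return table, utrs, decoy_map


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_DOMAINS = ("BP", "MF", "CC", "pathway")


def generate_annotation(
    truth: PlantedTruth,
    background_genes: list[str],
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> list[TermAnnotation]:
    """Annotation with planted enriched terms over a declared background.

    Each planted term intersects the planted target genes of one expression
    direction in exactly its stated overlap; the remaining members, and all
    filler terms, are drawn uniformly from the background."""
    rng = np.random.default_rng(seed)
    background = list(dict.fromkeys(background_genes))
    lo, hi = term_size_range
    if lo < 1 or lo > hi or hi > len(background):
        raise ValueError("invalid term_size_range for this background")
    all_planted = truth.all_targets
    neutral = [g for g in background if g not in all_planted]

    terms: list[TermAnnotation] = []
    for j, (term_id, dom, overlap) in enumerate(truth.enriched_terms):
        direction = "down" if j % 2 == 0 else "up"
        pool = sorted(truth.targets_of_direction(direction))
        if overlap > len(pool):
            raise ValueError(f"planted overlap {overlap} exceeds {direction} target pool")
        core = list(rng.choice(pool, size=overlap, replace=False))
        # planted terms stay small and specific so the planted overlap
        # dominates the term, as in a genuinely perturbed category
        size = int(rng.integers(max(lo, overlap), max(lo, min(2 * overlap, hi)) + 1))
        fill = list(rng.choice(neutral, size=size - overlap, replace=False))
        terms.append(
            TermAnnotation(
                term_id=term_id,
                label=f"planted {dom} term ({direction})",
                domain=dom,
                genes=frozenset(core + fill),
            )
        )
    for j in range(n_terms - len(terms)):
        dom = _DOMAINS[j % len(_DOMAINS)]
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(background, size=size, replace=False))
        terms.append(
            TermAnnotation(
                term_id=f"T{j + 1:04d}",
                label=f"background {dom} term {j + 1}",
                domain=dom,
                genes=frozenset(members),
            )
        )
    return terms
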