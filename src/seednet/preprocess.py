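"""Raw small-RNA read filtering and hierarchical species mapping.

Clean reads are obtained by three criteria applied in order: (i) discard a
read when more than 30% of its bases fall below Q20, (ii) trim the 3'
adapter, (iii) discard reads shorter than 17 nt after trimming.  Clean
reads are then mapped against species-ordered mature-miRNA references
(focal species first, then rat, mouse, human): a read is assigned to the
first species with a hit, and assignments to a non-first species are
tagged as cross-species "predicted" features — the rescue route for a
focal species whose miRNA database is incomplete.

Matching is exact substring containment in either direction with a minimum
overlap (default 17 nt), which is deterministic and unambiguous on
references whose sequences share no 17-mer; a mismatch-tolerance knob
exists for degraded data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqRecord import SeqRecord

from .seq import to_dna

DEFAULT_SPECIES_ORDER = ("dre", "rno", "mmu", "hsa")


@dataclass(frozen=True)
class SmallRNARead:
    """One single-end read with Phred+33-decoded qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 or q > 93 for q in self.qualities):
            raise ValueError(f"read {self.id}: Phred scores must lie in [0, 93]")

    @classmethod
    def from_seqrecord(cls, rec: SeqRecord) -> "SmallRNARead":
        return cls(
            id=rec.id,
            sequence=to_dna(str(rec.seq)),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcReport:
    """Read accounting for one sample; every raw read lands in exactly one
    of kept / discarded_quality / discarded_length / discarded_adapter_only.
    Mapping-category counts (over kept reads) are filled by the mapping
    stage."""

    sample: str = ""
    total_raw: int = 0
    discarded_quality: int = 0
    discarded_length: int = 0
    discarded_adapter_only: int = 0
    kept: int = 0
    mapped_focal: int = 0
    mapped_cross: int = 0
    unmapped: int = 0

    def check(self) -> None:
        if self.total_raw != (
            self.kept
            + self.discarded_quality
            + self.discarded_length
            + self.discarded_adapter_only
        ):
            raise AssertionError("QcReport does not account for every read exactly once")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    mirna_id: str
    species: str
    overlap: int
    mismatches: int
    cross_species: bool


def trim_adapter(read: SmallRNARead, adapter: str) -> SmallRNARead:
    """Truncate at the leftmost exact occurrence of the adapter's first 8 nt;
    qualities are cut in lockstep.  No occurrence leaves the read unchanged."""
    if not adapter:
        raise ValueError("adapter must be nonempty")
    probe = to_dna(adapter)[:8]
    pos = read.sequence.find(probe)
    if pos < 0:
        return read
    return SmallRNARead(read.id, read.sequence[:pos], read.qualities[:pos])


def filter_reads(
    reads: Iterable[SmallRNARead],
    adapter: str,
    q_threshold: int = 20,
    q_fraction: float = 0.30,
    min_len: int = 17,
) -> tuple[list[SmallRNARead], QcReport]:
    """Apply the clean-read criteria in order quality -> adapter -> length.

    Quality is judged on the full untrimmed read: discard when the fraction
    of bases below ``q_threshold`` strictly exceeds ``q_fraction``.  Reads
    empty after adapter trimming count as adapter-only; shorter than
    ``min_len`` count as length discards.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    if q_threshold <= 0 or min_len <= 0 or not 0 <= q_fraction <= 1:
        raise ValueError("thresholds must be positive and q_fraction in [0, 1]")
    qc = QcReport()
    kept: list[SmallRNARead] = []
    for read in reads:
        qc.total_raw += 1
        n_low = sum(1 for q in read.qualities if q < q_threshold)
        if len(read) > 0 and n_low / len(read) > q_fraction:
            qc.discarded_quality += 1
            continue
        trimmed = trim_adapter(read, adapter)
        if len(trimmed) == 0:
            qc.discarded_adapter_only += 1
            continue
        if len(trimmed) < min_len:
            qc.discarded_length += 1
            continue
        qc.kept += 1
        kept.append(trimmed)
    qc.check()
    return kept, qc


class _SpeciesIndex:
    """k-mer prefilter over one species' mature sequences for exact
    containment queries."""

    def __init__(self, records: Sequence[SeqRecord], k: int):
        self.k = k
        self.seqs = {r.id: to_dna(str(r.seq)) for r in records}
        self.index: dict[str, set[str]] = {}
        for rid, s in self.seqs.items():
            for i in range(len(s) - k + 1):
                self.index.setdefault(s[i : i + k], set()).add(rid)

    def candidates(self, seq: str) -> set[str]:
        out: set[str] = set()
        for i in range(len(seq) - self.k + 1):
            out |= self.index.get(seq[i : i + self.k], set())
        return out


def _best_hit(
    seq: str, idx: _SpeciesIndex, min_overlap: int, max_mismatches: int
) -> tuple[str, int, int] | None:
    """Best (mirna_id, overlap, mismatches) within one species, or None.

    A hit is end-to-end containment of the shorter sequence in the longer
    one; ties break by longest overlap, then lexicographically smallest id.
    """
    hits: list[tuple[int, int, str]] = []
    if max_mismatches == 0:
        for rid in idx.candidates(seq):
            ref = idx.seqs[rid]
            short, long_ = (seq, ref) if len(seq) <= len(ref) else (ref, seq)
            if len(short) >= min_overlap and short in long_:
                hits.append((len(short), 0, rid))
    else:
        for rid, ref in idx.seqs.items():
            short, long_ = (seq, ref) if len(seq) <= len(ref) else (ref, seq)
            if len(short) < min_overlap:
                continue
            best_mm = None
            for off in range(len(long_) - len(short) + 1):
                mm = sum(1 for a, b in zip(short, long_[off:]) if a != b)
                if mm <= max_mismatches and (best_mm is None or mm < best_mm):
                    best_mm = mm
            if best_mm is not None:
                hits.append((len(short), best_mm, rid))
    if not hits:
        return None
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    overlap, mm, rid = hits[0]
    return rid, overlap, mm


def map_reads_hierarchical(
    reads: Iterable[SmallRNARead],
    references: Sequence[tuple[str, Sequence[SeqRecord]]],
    min_overlap: int = 17,
    max_mismatches: int = 0,
) -> tuple[list[ReadAssignment], list[SmallRNARead]]:
    """Assign each read to the first species (in reference order) with a hit.

    ``references`` is an ordered list of ``(species_tag, records)``; the
    first species is the focal one, later species yield cross-species
    ("predicted") assignments.  Each read receives at most one assignment.
    """
    references = list(references)
    if not references:
        raise ValueError("empty reference list")
    k = min(min_overlap, 17)
    indexes = [(sp, _SpeciesIndex(recs, k)) for sp, recs in references]
    focal = references[0][0]

    assignments: list[ReadAssignment] = []
    unmapped: list[SmallRNARead] = []
    for read in reads:
        hit = None
        for sp, idx in indexes:
            found = _best_hit(read.sequence, idx, min_overlap, max_mismatches)
            if found is not None:
                rid, overlap, mm = found
                hit = ReadAssignment(
                    read_id=read.id,
                    mirna_id=rid,
                    species=sp,
                    overlap=overlap,
                    mismatches=mm,
                    cross_species=(sp != focal),
                )
                break
        if hit is None:
            unmapped.append(read)
        else:
            assignments.append(hit)
    return assignments, unmapped


def count_features(assignments: Iterable[ReadAssignment], sample: str) -> pd.Series:
    """Tally assigned reads per miRNA; the column sum equals the number of
    assignments."""
    tally = Counter(a.mirna_id for a in assignments)
    s = pd.Series(dict(tally), dtype=int, name=sample)
    s.index.name = "feature_id"
    return s.sort_index()


def composition_report(qc_reports: dict[str, QcReport]) -> pd.DataFrame:
    """Per-sample mapping composition over kept reads.

    Fractions of focal-species-mapped, cross-species-mapped and unmapped
    reads; they sum to 1 except for samples with zero kept reads, which are
    reported as all-zero with ``degenerate=True``.
    """
    rows = []
    for sample, qc in qc_reports.items():
        qc.check()
        if qc.kept == 0:
            rows.append((sample, 0, 0.0, 0.0, 0.0, True))
            continue
        if qc.mapped_focal + qc.mapped_cross + qc.unmapped != qc.kept:
            raise AssertionError(f"sample {sample}: mapping categories do not cover kept reads")
        rows.append(
            (
                sample,
                qc.kept,
                qc.mapped_focal / qc.kept,
                qc.mapped_cross / qc.kept,
                qc.unmapped / qc.kept,
                False,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "kept", "frac_focal", "frac_cross_species", "frac_unmapped", "degenerate"],
    ).set_index("sample")
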