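"""Alphabet normalization and small sequence helpers.

miRNA references and UTRs circulate both as DNA (FASTA downloads) and RNA
(mature miRNA convention).  Every public entry point normalizes to a single
alphabet at ingest so that T/U never causes a silent mismatch.
"""

from __future__ import annotations

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"


def to_rna(seq: str) -> str:
    """Uppercase and transcribe T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and back-transcribe U->T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return to_dna(seq).translate(_DNA_COMPLEMENT)[::-1]


def species_of(feature_id: str) -> str:
    """Species tag of a miRBase-style id (``dre-miR-735-3p`` -> ``dre``)."""
    return feature_id.split("-", 1)[0]


def kmers(seq: str, k: int) -> set[str]:
    """All k-length substrings of ``seq`` (empty set if too short)."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
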