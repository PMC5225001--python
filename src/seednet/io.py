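"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA/FASTQ via Biopython; counts, DE tables, predictions and enrichment
results as TSV via pandas; annotation as two-column TSV or GMT."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .enrichment import TermAnnotation
from .preprocess import SmallRNARead


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write(records, path, "fasta")
    return path


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write(records, path, "fastq")
    return path


def read_fastq_reads(path: str | Path) -> list[SmallRNARead]:
    """Parse a Phred+33 FASTQ file into reads, naming the offender on a
    malformed record."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    reads = []
    with open(path) as handle:
        title = "<unknown>"
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0]
                if len(seq) != len(qual):
                    raise ValueError("sequence and quality lengths differ")
                reads.append(
                    SmallRNARead(read_id, seq.upper().replace("U", "T"),
                                 tuple(ord(c) - 33 for c in qual))
                )
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record {title.split()[0]!r} in {path}: {exc}"
            ) from exc
    return reads


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# --- annotation -------------------------------------------------------------

def write_annotation_tsv(terms: Iterable[TermAnnotation], path: str | Path) -> Path:
    """Two-column gene_id/term_id table plus a term metadata block is not
    needed: domain and label travel in the GMT; the TSV holds memberships."""
    rows = [
        {"gene_id": g, "term_id": t.term_id}
        for t in terms
        for g in sorted(t.genes)
    ]
    return write_table(pd.DataFrame(rows, columns=["gene_id", "term_id"]), path, index=False)


def write_gmt(terms: Iterable[TermAnnotation], path: str | Path) -> Path:
    """GMT: term_id <tab> domain|label <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    lines = [
        "\t".join([t.term_id, f"{t.domain}|{t.label}"] + sorted(t.genes))
        for t in terms
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_gmt(path: str | Path) -> list[TermAnnotation]:
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        term_id, desc, genes = fields[0], fields[1], fields[2:]
        domain, _, label = desc.partition("|")
        terms.append(
            TermAnnotation(term_id=term_id, label=label or term_id, domain=domain,
                           genes=frozenset(genes))
        )
    return terms


def read_annotation_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    """term_id -> gene set from a two-column table (no domain information)."""
    df = read_table(path)
    return {
        t: frozenset(sub["gene_id"]) for t, sub in df.groupby("term_id", sort=True)
    }
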