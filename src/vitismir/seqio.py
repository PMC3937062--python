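"""Sequence I/O and coordinate primitives shared by every pipeline stage.

All sequences are held internally in the DNA alphabet ``{A, C, G, T, N}``;
RNA input (mature miRNA references are conventionally printed with U) is
normalized on ingest and converted back to RNA only in reports. Genomic
coordinates are 0-based half-open internally and 1-based inclusive in GFF3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_RNA = str.maketrans("T", "U")
_TO_DNA = str.maketrans("Uu", "Tt")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input, naming the offending position."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named sequence in the canonical DNA alphabet."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.identifier!r}")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.identifier!r}: residues outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def normalize_residues(residues: str) -> str:
    """Upper-case and map U -> T so every comparison runs in one alphabet."""
    return residues.translate(_TO_DNA).upper()


def to_rna(residues: str) -> str:
    """DNA -> RNA alphabet, used only when writing reports."""
    return residues.translate(_TO_RNA)


def reverse_complement(residues: str) -> str:
    """Reverse complement over ACGTN. N complements to N.

    Applying the function twice returns the input (involution).
    """
    bad = set(residues) - DNA_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement residues {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_sequences(path, format: str | None = None) -> list[NucleotideSequence]:
    """Read FASTA/FASTQ into normalized :class:`NucleotideSequence` records.

    Residues are upper-cased with U normalized to T; record order is
    preserved; an empty file yields an empty list. FASTQ qualities are read
    for syntax but otherwise ignored (small-RNA pipelines filter by length
    and identity, not quality).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    records: list[NucleotideSequence] = []
    lines_per_record = 4 if fmt == "fastq" else 2
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            residues = normalize_residues(str(rec.seq))
            try:
                records.append(NucleotideSequence(rec.id, residues))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: record {i + 1} (near line {i * lines_per_record + 1}): {exc}"
                ) from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(
            f"{path}: malformed {fmt} near line "
            f"{len(records) * lines_per_record + 1}: {exc}"
        ) from exc
    return records


def write_fasta(records: Iterable[NucleotideSequence], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n{rec.residues}\n")


def write_fastq(reads: Iterable[str], path, prefix: str = "read") -> None:
    """Write raw read strings as Sanger FASTQ with uniform dummy qualities."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{prefix}{i + 1}\n{read}\n+\n{'I' * len(read)}\n")


def write_gff3(hairpins, path) -> None:
    """Write hairpin candidates as GFF3: a miRNA_primary_transcript feature
    per precursor with child miRNA features for the mature (and star, when
    detected) arms. Internal 0-based half-open coordinates become the GFF3
    1-based inclusive convention (column 4 = start + 1, column 5 = end).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for hp in hairpins:
            loc = hp.precursor_interval
            pid = hp.name
            fh.write(
                "\t".join(
                    [
                        loc.contig,
                        "vitismir",
                        "miRNA_primary_transcript",
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        f"ID={pid}",
                    ]
                )
                + "\n"
            )
            children = [("mature", hp.mature_interval)]
            if hp.star_interval is not None:
                children.append(("star", hp.star_interval))
            for kind, iv in children:
                fh.write(
                    "\t".join(
                        [
                            iv.contig,
                            "vitismir",
                            "miRNA",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            f"ID={pid}.{kind};Parent={pid}",
                        ]
                    )
                    + "\n"
                )


def read_gff3_intervals(path) -> list[tuple[str, str, GenomicInterval]]:
    """Minimal GFF3 reader returning (feature_id, type, interval) triples,
    converting back to the internal 0-based half-open convention."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            out.append(
                (
                    attrs.get("ID", "."),
                    cols[2],
                    GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]),
                )
            )
    return out
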