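"""Tag annotation: classify collapsed tags into the standard small-RNA
categories (miRNA, rRNA, tRNA, snRNA, snoRNA, repeat, exon/intron
sense/antisense, unannotated) and tabulate the per-category breakdown.

Contaminant classes are matched by exact substring membership against the
class reference sequences — the conservative "removal" semantics of sRNA
cleanup — with structural RNAs (rRNA/tRNA/sn(o)RNA/repeat) matched on either
strand and exon/intron features matched strand-aware. Classification is by a
fixed priority so categories stay mutually exclusive and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import DEFAULT_MAX_LEN, DEFAULT_MIN_LEN, TagLibrary
from .seqio import read_sequences, reverse_complement

STRUCTURAL_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")
STRANDED_CLASSES = ("exon", "intron")

#: Classification priority, highest first. Known-miRNA hits outrank
#: everything; structural RNA outranks genic context; sense before antisense.
CATEGORY_PRIORITY = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unann",
)


def _substring_index(
    sequences: list[str], min_len: int, max_len: int
) -> set[str]:
    """All substrings with lengths in [min_len, max_len] of the given
    sequences, for O(1) membership tests against tags."""
    index: set[str] = set()
    for seq in sequences:
        n = len(seq)
        for length in range(min_len, min(max_len, n) + 1):
            for i in range(n - length + 1):
                index.add(seq[i : i + length])
    return index


@dataclass
class AnnotationIndex:
    """Per-class substring sets (sequence mode) and/or per-class genomic
    intervals (interval mode), plus an optional genome for mapping tallies.

    Interval mode serves classes supplied as coordinates on the genome
    (BED6) rather than as sequences: a tag belongs to a class when one of
    its exact genomic loci overlaps a class interval, strand-insensitively
    for structural classes and strand-aware for exon/intron.
    """

    sense: dict[str, set[str]] = field(default_factory=dict)
    antisense: dict[str, set[str]] = field(default_factory=dict)
    intervals: dict[str, list] = field(default_factory=dict)
    genome: dict[str, str] | None = None

    @classmethod
    def build(
        cls,
        class_sequences: dict[str, list[str]],
        genome: dict[str, str] | None = None,
        min_len: int = DEFAULT_MIN_LEN,
        max_len: int = DEFAULT_MAX_LEN,
    ) -> "AnnotationIndex":
        """Build from a mapping of class label -> reference sequences.

        Valid labels are the structural classes plus ``exon``/``intron``.
        """
        sense: dict[str, set[str]] = {}
        antisense: dict[str, set[str]] = {}
        for label, seqs in class_sequences.items():
            if label not in STRUCTURAL_CLASSES + STRANDED_CLASSES:
                raise ValueError(f"unknown annotation class {label!r}")
            sense[label] = _substring_index(seqs, min_len, max_len)
            antisense[label] = _substring_index(
                [reverse_complement(s) for s in seqs], min_len, max_len
            )
        return cls(sense=sense, antisense=antisense, genome=genome)

    @classmethod
    def from_fasta(
        cls,
        class_paths: dict[str, str],
        genome: dict[str, str] | None = None,
        min_len: int = DEFAULT_MIN_LEN,
        max_len: int = DEFAULT_MAX_LEN,
    ) -> "AnnotationIndex":
        class_sequences = {
            label: [rec.residues for rec in read_sequences(path)]
            for label, path in class_paths.items()
        }
        return cls.build(class_sequences, genome, min_len, max_len)

    @classmethod
    def from_bed(
        cls,
        class_paths: dict[str, str],
        genome: dict[str, str],
    ) -> "AnnotationIndex":
        """Interval mode: class references as BED6 tracks on the genome."""
        from .seqio import GenomicInterval

        intervals: dict[str, list] = {}
        for label, path in class_paths.items():
            if label not in STRUCTURAL_CLASSES + STRANDED_CLASSES:
                raise ValueError(f"unknown annotation class {label!r}")
            ivs = []
            with open(path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    cols = line.rstrip("\n").split("\t")
                    strand = cols[5] if len(cols) > 5 else "+"
                    ivs.append(
                        GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand)
                    )
            intervals[label] = ivs
        return cls(intervals=intervals, genome=genome)

    def maps_to_genome(self, tag: str) -> bool:
        """Exact occurrence on either strand of the genome (non-exclusive
        tally reported alongside the category breakdown)."""
        if self.genome is None:
            return False
        rc = reverse_complement(tag)
        for contig in self.genome.values():
            if tag in contig or rc in contig:
                return True
        return False


def classify_tag(
    tag: str, index: AnnotationIndex, known_mirna_hit: bool = False
) -> str:
    """Assign exactly one category to a tag by fixed priority.

    Structural classes match on either strand; exon/intron distinguish the
    tag strand relative to the feature (sense = tag matches the feature
    sequence, antisense = the tag's reverse complement does).
    """
    if known_mirna_hit:
        return "miRNA"
    rc = reverse_complement(tag)
    loci = None
    if index.intervals:
        from .novel import map_exact

        loci = map_exact(tag, index.genome or {})
    for label in STRUCTURAL_CLASSES:
        if tag in index.sense.get(label, ()) or tag in index.antisense.get(
            label, ()
        ):
            return label
        if loci and any(
            locus.overlaps(iv)
            for iv in index.intervals.get(label, ())
            for locus in loci
        ):
            return label
    for label in STRANDED_CLASSES:
        if tag in index.sense.get(label, ()):
            return f"{label}_sense"
        if rc in index.sense.get(label, ()):
            return f"{label}_antisense"
        if loci:
            hits = [
                locus.strand == iv.strand
                for iv in index.intervals.get(label, ())
                for locus in loci
                if locus.overlaps(iv)
            ]
            if any(hits):
                return f"{label}_sense"
            if hits:
                return f"{label}_antisense"
    return "unann"


def classify_library(
    lib: TagLibrary, index: AnnotationIndex, known_hits: set[str] | None = None
) -> dict[str, str]:
    """Category per tag for a whole library."""
    known_hits = known_hits or set()
    return {
        tag: classify_tag(tag, index, known_mirna_hit=tag in known_hits)
        for tag in lib.tags
    }


def category_breakdown(
    lib: TagLibrary,
    index: AnnotationIndex,
    known_hits: set[str] | None = None,
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate unique/redundant counts and percents per category.

    Returns a DataFrame indexed by category with columns ``unique``,
    ``unique_pct``, ``redundant``, ``redundant_pct``; a ``Total`` row; and a
    separate non-exclusive ``mapping_to_genome`` row (a tag can both map to
    the genome and belong to any category, so it is not part of the
    partition and is excluded from the Total).
    """
    if categories is None:
        categories = classify_library(lib, index, known_hits)
    rows = {cat: [0, 0] for cat in CATEGORY_PRIORITY}
    mapped = [0, 0]
    for tag, count in lib.tags.items():
        cat = categories[tag]
        rows[cat][0] += 1
        rows[cat][1] += count
        if index.maps_to_genome(tag):
            mapped[0] += 1
            mapped[1] += count
    total_u = lib.total_unique
    total_r = lib.total_redundant
    records = []
    for cat in CATEGORY_PRIORITY:
        u, r = rows[cat]
        records.append(
            (
                cat,
                u,
                100.0 * u / total_u if total_u else 0.0,
                r,
                100.0 * r / total_r if total_r else 0.0,
            )
        )
    records.append(
        (
            "mapping_to_genome",
            mapped[0],
            100.0 * mapped[0] / total_u if total_u else 0.0,
            mapped[1],
            100.0 * mapped[1] / total_r if total_r else 0.0,
        )
    )
    records.append(("Total", total_u, 100.0, total_r, 100.0))
    df = pd.DataFrame(
        records,
        columns=["category", "unique", "unique_pct", "redundant", "redundant_pct"],
    ).set_index("category")
    return df
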