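"""Raw-read preprocessing: adapter trimming, length/poly-A filtering,
collapsing into unique tags, and library profiling (size distribution and
5' first-nucleotide bias).

A "tag" is a unique insert sequence; its count is the number of reads that
collapsed onto it ("redundant" abundance), while the number of distinct tags
is the "unique" abundance. Both weightings matter downstream: category
breakdowns and size profiles are conventionally reported in both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .seqio import to_rna

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_POLYA_FRAC = 0.8
DEFAULT_MIN_SEED = 8
DEFAULT_MAX_MISMATCH = 1


@dataclass
class TagLibrary:
    """Collapsed unique tags with counts for one sequencing library."""

    label: str
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def total_redundant(self) -> int:
        return sum(self.tags.values())

    @property
    def total_unique(self) -> int:
        return len(self.tags)

    def count(self, tag: str) -> int:
        return self.tags.get(tag, 0)


def trim_adapter(
    read: str,
    adapter3: str,
    min_seed: int = DEFAULT_MIN_SEED,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> str | None:
    """Trim the 3' adapter from a read.

    Scans left to right for the left-most position where a prefix of
    ``adapter3`` of length >= ``min_seed`` matches with at most
    ``max_mismatch`` mismatches, and returns the insert preceding it.
    Returns the read unchanged when no adapter is found, and ``None``
    (rejected) for adapter-only reads, i.e. a hit at position 0.
    """
    if len(adapter3) < min_seed:
        raise ValueError("adapter shorter than min_seed")
    n = len(read)
    for i in range(0, n - min_seed + 1):
        overlap = min(len(adapter3), n - i)
        mismatches = 0
        for a, b in zip(read[i : i + overlap], adapter3):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            if i == 0:
                return None
            return read[:i]
    return read


def filter_and_collapse(
    reads: Iterable[str | None],
    label: str = "library",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    polya_frac: float = DEFAULT_POLYA_FRAC,
) -> TagLibrary:
    """Length/poly-A filter surviving reads and collapse identical sequences.

    Drops rejected (``None``) reads, reads containing N (exact collapsing
    and mismatch counting both need a clean alphabet), reads outside
    [min_len, max_len], and reads whose A fraction is >= ``polya_frac``
    (poly-A tail carry-over). ``total_redundant`` of the result equals the
    number of surviving reads by construction.
    """
    counter: Counter[str] = Counter()
    for read in reads:
        if read is None:
            continue
        if "N" in read:
            continue
        n = len(read)
        if n < min_len or n > max_len:
            continue
        if read.count("A") / n >= polya_frac:
            continue
        counter[read] += 1
    return TagLibrary(label, dict(sorted(counter.items())))


def preprocess_reads(
    reads: Iterable[str],
    adapter3: str,
    label: str = "library",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    polya_frac: float = DEFAULT_POLYA_FRAC,
    min_seed: int = DEFAULT_MIN_SEED,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> TagLibrary:
    """Convenience composition: trim every read, then filter and collapse."""
    trimmed = (trim_adapter(r, adapter3, min_seed, max_mismatch) for r in reads)
    return filter_and_collapse(trimmed, label, min_len, max_len, polya_frac)


def _weights(lib: TagLibrary, weighting: str) -> Mapping[str, int]:
    if weighting == "redundant":
        return lib.tags
    if weighting == "unique":
        return {t: 1 for t in lib.tags}
    raise ValueError(f"weighting must be 'unique' or 'redundant', got {weighting!r}")


def size_distribution(
    lib: TagLibrary,
    weighting: str = "redundant",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[int, float]:
    """Fraction of tags (or reads, for redundant weighting) at each length.

    Fractions over lengths [min_len, max_len] sum to 1.
    """
    if not lib.tags:
        raise ValueError(f"library {lib.label!r} is empty")
    weights = _weights(lib, weighting)
    by_len = Counter()
    for tag, w in weights.items():
        by_len[len(tag)] += w
    total = sum(by_len.values())
    return {n: by_len.get(n, 0) / total for n in range(min_len, max_len + 1)}


def first_nt_bias(
    lib: TagLibrary, weighting: str = "redundant"
) -> dict[tuple[int, str], float]:
    """Per-length distribution of the 5' first nucleotide, in the RNA
    alphabet (mature plant miRNAs are strongly biased toward a 5' U).

    For each tag length present, the fractions over {A, C, G, U} sum to 1.
    """
    if not lib.tags:
        raise ValueError(f"library {lib.label!r} is empty")
    weights = _weights(lib, weighting)
    by_len_nt: Counter[tuple[int, str]] = Counter()
    len_totals: Counter[int] = Counter()
    for tag, w in weights.items():
        key = (len(tag), to_rna(tag[0]))
        by_len_nt[key] += w
        len_totals[len(tag)] += w
    return {
        (n, nt): count / len_totals[n] for (n, nt), count in sorted(by_len_nt.items())
    }
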