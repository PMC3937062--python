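"""Novel miRNA discovery from unannotated tags.

The route is the classic one for plant sRNA data: map candidate tags exactly
to the genome, cut genomic windows with flanking sequence around each locus,
fold the windows into a secondary structure, and keep loci whose fold is a
genuine miRNA-like hairpin — mature on a single arm, almost fully paired to
a compact star region on the opposite arm, with small bulges — then look for
the predicted star among the sequenced tags (2-nt 3' overhang duplex
partner), which is the strongest evidence a locus is a real miRNA rather
than a fold-back repeat.

Folding maximizes the number of Watson-Crick + G:U base pairs under the
non-crossing (pseudoknot-free) constraint with a minimum hairpin loop — a
Nussinov-style dynamic program with a deterministic traceback. Maximum
pairing is a deliberate, dependency-free objective; an energy-based backend
can be plugged in behind the same ``fold`` contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median_low
from typing import Iterable, Mapping, Sequence

from .preprocess import TagLibrary
from .seqio import GenomicInterval, reverse_complement

#: Allowed base pairs in the canonical DNA alphabet (U is held as T).
PAIRABLE = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

DEFAULT_MIN_LOOP = 3


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure of one sequence."""

    dotbracket: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict[int, int]:
        """Position -> pairing partner, both directions."""
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds for accepting a candidate precursor hairpin.

    The defaults operationalize the community's annotation criteria for
    plant miRNAs: a mature almost fully paired in the mature/star duplex
    (>= ``min_paired_mature`` of its bases), few unpaired mature bases
    (``max_mismatches_in_duplex``), no bulge longer than ``max_bulge``, and a
    star with the canonical 2-nt 3' overhangs.
    """

    max_mismatches_in_duplex: int = 4
    max_bulge: int = 3
    min_paired_mature: int = 16
    star_overhang: int = 2
    flank_window: int = 150
    min_precursor_len: int = 50
    max_precursor_len: int = 300

    def __post_init__(self) -> None:
        for name in (
            "max_mismatches_in_duplex",
            "max_bulge",
            "min_paired_mature",
            "flank_window",
            "min_precursor_len",
            "max_precursor_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.star_overhang != 2:
            raise ValueError("star_overhang is fixed at 2 nt")


@dataclass
class HairpinCandidate:
    """An accepted novel-miRNA locus."""

    name: str
    precursor: str
    precursor_interval: GenomicInterval
    structure: SecondaryStructure
    mature: str
    arm: str  # "5p" or "3p"
    star: str | None
    mature_interval: GenomicInterval
    star_interval: GenomicInterval | None
    five_prime_u: bool
    mature_counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)
    star_detected: bool = False


def map_exact(tag: str, genome: Mapping[str, str]) -> list[GenomicInterval]:
    """All exact occurrences of a tag on both genome strands.

    Minus-strand hits are found by locating the reverse complement on the
    forward sequence; intervals are always reported in forward coordinates.
    """
    hits: list[GenomicInterval] = []
    rc = reverse_complement(tag)
    n = len(tag)
    for contig in sorted(genome):
        seq = genome[contig]
        for query, strand in ((tag, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append(GenomicInterval(contig, start, start + n, strand))
                start = seq.find(query, start + 1)
    if tag == rc:  # palindromic tag: one interval per site, not two
        hits = sorted(set(replace(h, strand="+") for h in hits))
    return hits


@dataclass(frozen=True)
class Window:
    """An oriented candidate-precursor sequence cut from the genome."""

    seq: str
    interval: GenomicInterval

    def __len__(self) -> int:
        return len(self.seq)


def _cut(genome: Mapping[str, str], locus: GenomicInterval, lo: int, hi: int) -> Window:
    contig_seq = genome[locus.contig]
    lo = max(0, lo)
    hi = min(len(contig_seq), hi)
    seq = contig_seq[lo:hi]
    if locus.strand == "-":
        seq = reverse_complement(seq)
    return Window(seq, GenomicInterval(locus.contig, lo, hi, locus.strand))


def extract_windows(
    locus: GenomicInterval,
    genome: Mapping[str, str],
    flank: int = 150,
    pad: int = 20,
) -> tuple[Window, Window]:
    """Two candidate precursor windows around a mapped tag locus: one with
    the long flank upstream (plus a short downstream pad) and one with the
    long flank downstream. Windows are truncated at contig edges, and
    minus-strand loci are reverse-complemented so the tag always reads
    5'->3' within the returned sequence."""
    if locus.contig not in genome:
        raise ValueError(f"unknown contig {locus.contig!r}")
    contig_len = len(genome[locus.contig])
    if locus.end > contig_len:
        raise ValueError(
            f"locus [{locus.start}, {locus.end}) outside contig "
            f"{locus.contig!r} of length {contig_len}"
        )
    window_a = _cut(genome, locus, locus.start - flank, locus.end + pad)
    window_b = _cut(genome, locus, locus.start - pad, locus.end + flank)
    return window_a, window_b


def _pair_ok(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def fold(seq: str, min_loop: int = DEFAULT_MIN_LOOP) -> SecondaryStructure:
    """Maximum base-pair secondary structure (Nussinov dynamic program).

    Pairs are Watson-Crick plus G:U wobble, structures are non-crossing,
    and every hairpin loop spans at least ``min_loop`` unpaired bases.
    Traceback is deterministic: whenever pairing position i attains the
    optimum, i is paired with the largest admissible j. Maximum pairing is
    heavily degenerate, and among co-optimal structures the largest-j rule
    continues enclosing helices outside-in, which keeps clean stems intact
    instead of scattering ties into loop-internal pairs.
    """
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence of length {n} too short to fold")
    # M[i][j] = max pairs in seq[i..j]; padded so j = i-1 reads as 0.
    M = [[0] * (n + 1) for _ in range(n + 2)]
    pairable = [
        [_pair_ok(seq[i], seq[j]) for j in range(n)] for i in range(n)
    ]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            row_i1 = M[i + 1]
            best = row_i1[j]  # i unpaired
            p_i = pairable[i]
            for k in range(i + min_loop + 1, j + 1):
                if p_i[k]:
                    cand = 1 + row_i1[k - 1] + M[k + 1][j]
                    if cand > best:
                        best = cand
            M[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = M[i][j]
        if target == 0:
            continue
        chosen = None
        for k in range(j, i + min_loop, -1):
            if pairable[i][k] and 1 + M[i + 1][k - 1] + M[k + 1][j] == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return SecondaryStructure("".join(db), tuple(pairs))


def evaluate_hairpin(
    window: str,
    mature: str,
    structure: SecondaryStructure,
    criteria: HairpinCriteria = HairpinCriteria(),
    name: str = "hairpin",
    interval: GenomicInterval | None = None,
) -> HairpinCandidate | None:
    """Accept or reject a folded window as a miRNA precursor.

    Acceptance requires that the mature (a) lies on a single arm (all its
    pairing partners on one side, i.e. it does not span the terminal loop),
    (b) has at least ``min_paired_mature`` paired bases, and (c) has at most
    ``max_mismatches_in_duplex`` unpaired bases, none in a run longer than
    ``max_bulge``, against a compact star region. The star is the opposite
    strand of the duplex shifted to leave the canonical 2-nt 3' overhangs;
    ``five_prime_u`` flags a mature starting with U.
    """
    m0 = window.find(mature)
    if m0 == -1:
        raise ValueError("mature sequence does not occur in window")
    m1 = m0 + len(mature)
    partner = structure.partner()

    # Split the mature's pairs by which side of the mature the partner lies
    # on. A maximum-pairing fold can attach a few stray pairs (loop-internal
    # hairpins, partners just past the true star), so the duplex is taken as
    # the largest subset of same-side pairs sharing a near-constant
    # anti-diagonal i + partner(i) — the signature of one antiparallel stem
    # with bulge wiggle — and everything else counts as unpaired.
    right = [(i, partner[i]) for i in range(m0, m1) if partner.get(i, -1) >= m1]
    left = [(i, partner[i]) for i in range(m0, m1) if 0 <= partner.get(i, -1) < m0]
    if len(right) >= len(left):
        arm, side_pairs, minority = "5p", right, len(left)
    else:
        arm, side_pairs, minority = "3p", left, len(right)
    # (a) single arm: more than a couple of partners across the terminal
    # loop means the mature spans it
    if minority > 2 or not side_pairs:
        return None
    wiggle = 2 * criteria.max_bulge
    diags = sorted(i + j for i, j in side_pairs)
    best_d0, best_n = diags[0], 0
    for d0 in diags:
        n = sum(1 for d in diags if d0 <= d <= d0 + wiggle)
        if n > best_n:
            best_d0, best_n = d0, n
    consistent = [
        (i, j) for i, j in side_pairs if best_d0 <= i + j <= best_d0 + wiggle
    ]
    # (b) duplex pairing depth
    if len(consistent) < criteria.min_paired_mature:
        return None
    # (c) unpaired budget and bulge length, stray pairs counting as unpaired
    if len(mature) - len(consistent) > criteria.max_mismatches_in_duplex:
        return None
    # bulges are internal: unpaired runs between duplex pairs, not the
    # unpaired mature termini (those are overhangs, budgeted above)
    in_duplex = {i for i, _ in consistent}
    run = 0
    for i in range(min(in_duplex), max(in_duplex) + 1):
        if i in in_duplex:
            run = 0
        else:
            run += 1
            if run > criteria.max_bulge:
                return None
    # (d) star: the duplex partner of the mature, shifted for the canonical
    # 2-nt 3' overhangs and held at the mature's length. The duplex
    # anti-diagonal is estimated by the median over consistent pairs —
    # robust against edge slippage in homopolymer runs, where co-optimal
    # folds shift the outermost pair along an A/T run.
    shift = criteria.star_overhang
    d_hat = median_low(i + j for i, j in consistent)
    if arm == "5p":
        s1 = d_hat - m0 + 1 + shift
        s0 = s1 - len(mature)
    else:
        s0 = d_hat - (m1 - 1) - shift
        s1 = s0 + len(mature)
    star = window[max(0, s0) : min(len(window), s1)] or None
    five_prime_u = mature[0] == "T"

    def _sub_interval(lo: int, hi: int) -> GenomicInterval | None:
        if interval is None:
            return None
        if interval.strand == "+":
            return GenomicInterval(
                interval.contig, interval.start + lo, interval.start + hi, "+"
            )
        return GenomicInterval(
            interval.contig, interval.end - hi, interval.end - lo, "-"
        )

    return HairpinCandidate(
        name=name,
        precursor=window,
        precursor_interval=interval
        or GenomicInterval("window", 0, len(window), "+"),
        structure=structure,
        mature=mature,
        arm=arm,
        star=star,
        mature_interval=_sub_interval(m0, m1)
        or GenomicInterval("window", m0, m1, "+"),
        star_interval=(
            _sub_interval(max(0, s0), min(len(window), s1))
            or GenomicInterval("window", max(0, s0), min(len(window), s1), "+")
        )
        if star
        else None,
        five_prime_u=five_prime_u,
    )


def detect_star(
    candidate: HairpinCandidate,
    lib: TagLibrary,
    tolerance: int = 2,
) -> int | None:
    """Look for the predicted star among sequenced tags.

    Accepts tags equal to the predicted star allowing end shifts of up to
    ``tolerance`` nt on either end (Dicer processing is not base-precise).
    Returns the summed count of matching tags, or None when absent.
    """
    if candidate.star is None:
        return None
    window = candidate.precursor
    s0 = window.find(candidate.star)
    if s0 == -1:
        return None
    s1 = s0 + len(candidate.star)
    total = 0
    seen: set[str] = set()
    for ds in range(-tolerance, tolerance + 1):
        for de in range(-tolerance, tolerance + 1):
            a, b = s0 + ds, s1 + de
            if a < 0 or b > len(window) or b - a < len(candidate.star) - tolerance:
                continue
            variant = window[a:b]
            if variant in seen:
                continue
            seen.add(variant)
            total += lib.count(variant)
    return total if total > 0 else None


def _precursor_windows(
    locus: GenomicInterval,
    genome: Mapping[str, str],
    criteria: HairpinCriteria,
    pad: int = 15,
    extents: Sequence[int] = (40, 60, 90, 130, 150),
) -> list[Window]:
    """Graduated candidate-precursor windows around a locus, smallest first.

    Both orientations (star downstream of the mature, then upstream) are
    tried; extents are capped by the criteria's flank and precursor-length
    bounds. Folding small windows first keeps the duplex local: a global
    max-pairing fold of a very long window can absorb mature bases into
    spurious distal pairs even when a clean local stem exists.
    """
    windows: list[Window] = []
    for ext in extents:
        ext = min(ext, criteria.flank_window)
        for lo, hi in (
            (locus.start - pad, locus.end + ext),
            (locus.start - ext, locus.end + pad),
        ):
            w = _cut(genome, locus, lo, hi)
            if (
                criteria.min_precursor_len
                <= len(w)
                <= criteria.max_precursor_len
            ):
                windows.append(w)
    return windows


def discover_hairpins(
    tag_counts: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str],
    criteria: HairpinCriteria = HairpinCriteria(),
    libraries: Iterable[TagLibrary] = (),
    min_count: int = 5,
    mature_length: tuple[int, int] = (20, 24),
    star_tolerance: int = 2,
    max_loci: int = 20,
    name_prefix: str = "Vvi-miRC",
) -> list[HairpinCandidate]:
    """End-to-end novel discovery over unannotated tags.

    ``tag_counts`` maps tag -> {library label -> raw count}. Tags shorter or
    longer than a plausible mature, or seen fewer than ``min_count`` times in
    total, are not folded (singleton background fragments are never
    annotatable as miRNAs and folding them would dominate the runtime). Tags
    mapping to more than ``max_loci`` loci are skipped as repeats. Every
    distinct genomic locus of a surviving tag yields its own candidate;
    abundance is shared between such loci, never multiplied. Loci whose
    mature interval overlaps an already accepted precursor are folded into
    that candidate (isomiR end-variants), processing tags in decreasing
    abundance so the dominant variant names the locus.
    """
    libraries = list(libraries)
    merged = TagLibrary(
        "merged",
        {
            t: sum(lib.count(t) for lib in libraries)
            for lib in libraries
            for t in lib.tags
        },
    )
    order = sorted(
        tag_counts, key=lambda t: (-sum(tag_counts[t].values()), t)
    )
    accepted: list[HairpinCandidate] = []
    counter = 0
    for tag in order:
        counts = tag_counts[tag]
        if sum(counts.values()) < min_count:
            continue
        if not mature_length[0] <= len(tag) <= mature_length[1]:
            continue
        loci = map_exact(tag, genome)
        if not loci or len(loci) > max_loci:
            continue
        for locus in loci:
            if any(locus.overlaps(c.precursor_interval) for c in accepted):
                # isomiR, star, or opposite-strand read-through of an
                # already-called locus (an inverted repeat folds as a
                # hairpin from either strand): one locus, one candidate
                continue
            candidate = None
            for window in _precursor_windows(locus, genome, criteria):
                structure = fold(window.seq)
                candidate = evaluate_hairpin(
                    window.seq,
                    tag,
                    structure,
                    criteria,
                    interval=window.interval,
                )
                if candidate is not None:
                    break
            if candidate is None:
                continue
            counter += 1
            candidate.name = f"{name_prefix}{counter:02d}"
            candidate.mature_counts = {
                lib.label: lib.count(tag) for lib in libraries
            }
            if detect_star(candidate, merged, star_tolerance) is not None:
                candidate.star_detected = True
                star_variants = _star_variants(candidate, star_tolerance)
                candidate.star_counts = {
                    lib.label: sum(lib.count(v) for v in star_variants)
                    for lib in libraries
                }
            accepted.append(candidate)
    return accepted


def _star_variants(candidate: HairpinCandidate, tolerance: int) -> list[str]:
    window = candidate.precursor
    s0 = window.find(candidate.star)
    s1 = s0 + len(candidate.star)
    variants = set()
    for ds in range(-tolerance, tolerance + 1):
        for de in range(-tolerance, tolerance + 1):
            a, b = s0 + ds, s1 + de
            if a < 0 or b > len(window) or b - a < len(candidate.star) - tolerance:
                continue
            variants.add(window[a:b])
    return sorted(variants)
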