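"""Synthetic genomes and paired two-condition small-RNA libraries with
planted ground truth.

The generator emulates the study design every pipeline stage expects: a
random genome with planted perfect-stem miRNA precursors, contaminant
reference classes (rRNA/tRNA/snRNA/snoRNA/repeat), and one sequencing
library per condition (control vs. hormone treatment) whose per-miRNA read
counts are Poisson with planted condition means — including eight-fold
changes and zero-in-one-condition extremes, the presence/absence cases the
response classifier must recover exactly. Reads carry the 3' adapter, a
21/24-nt-dominated background length profile, a 5'U bias on planted
matures, optional ±1-nt end jitter and substitution errors, so trimming,
collapsing, isomiR-tolerant matching and star detection are all exercised.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GenomicInterval, reverse_complement, write_fasta, write_fastq, NucleotideSequence

BASES = np.array(list("ACGT"))

#: Default per-condition response plan for n_hairpins = 20: the class of
#: each planted hairpin in order. Eight-fold changes for up/down.
DEFAULT_PLAN = (
    ["up"] * 4 + ["down"] * 4 + ["treatment_only"] * 3 + ["control_only"] * 3 + ["unchanged"] * 6
)

DEFAULT_CONTAMINANTS = {
    "rRNA": (3, 500),
    "tRNA": (3, 80),
    "snRNA": (2, 150),
    "snoRNA": (2, 130),
    "repeat": (2, 300),
}

DEFAULT_LENGTH_DIST = {21: 0.38, 24: 0.32}
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study."""

    seed: int
    genome_length: int = 100_000
    n_hairpins: int = 20
    response_plan: tuple[str, ...] | None = None
    fold_change: float = 8.0
    mature_length: int = 21
    contaminants: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANTS)
    )
    contaminant_mean_reads: int = 300
    background_reads: int = 44_000
    length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    five_prime_u_prob: float = 0.6
    star_expressed_fraction: float = 0.5
    star_mean_fraction: float = 0.15
    error_rate: float = 0.005
    jitter_prob: float = 0.1
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 48

    def __post_init__(self) -> None:
        for p in (
            self.five_prime_u_prob,
            self.star_expressed_fraction,
            self.error_rate,
            self.jitter_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.genome_length < (self.n_hairpins + 1) * 400:
            raise ValueError("genome too short to host the requested hairpins")

    def plan(self) -> list[str]:
        if self.response_plan is not None:
            plan = list(self.response_plan)
            if len(plan) != self.n_hairpins:
                raise ValueError("response_plan length must equal n_hairpins")
            return plan
        # cycle the default proportions for other hairpin counts
        return [DEFAULT_PLAN[i % len(DEFAULT_PLAN)] for i in range(self.n_hairpins)]

    def length_probabilities(self) -> tuple[list[int], list[float]]:
        lengths = list(range(18, 31))
        named = dict(self.length_dist)
        rest = [n for n in lengths if n not in named]
        remainder = 1.0 - sum(named.values())
        probs = [named.get(n, remainder / len(rest)) for n in lengths]
        return lengths, probs


@dataclass
class PlantedHairpin:
    """Ground truth for one planted precursor locus."""

    name: str
    precursor_interval: GenomicInterval
    mature: str
    mature_interval: GenomicInterval
    star: str
    loop_length: int
    control_mean: float
    treatment_mean: float
    star_expressed: bool
    response: str


@dataclass
class PlantedSequence:
    name: str
    label: str
    sequence: str
    interval: GenomicInterval


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    hairpins: list[PlantedHairpin]
    contaminants: list[PlantedSequence]

    def contaminant_sequences(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c in self.contaminants:
            out.setdefault(c.label, []).append(c.sequence)
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _condition_means(
    spec: SimulationSpec, rng: np.random.Generator
) -> list[tuple[float, float]]:
    means = []
    for cls in spec.plan():
        if cls == "up":
            low = float(rng.integers(20, 26))
            means.append((low, low * spec.fold_change))
        elif cls == "down":
            low = float(rng.integers(20, 26))
            means.append((low * spec.fold_change, low))
        elif cls == "treatment_only":
            means.append((0.0, float(rng.integers(50, 201))))
        elif cls == "control_only":
            means.append((float(rng.integers(50, 201)), 0.0))
        elif cls == "unchanged":
            m = float(rng.integers(20, 201))
            means.append((m, m))
        else:
            raise ValueError(f"unknown response class {cls!r}")
    return means


def generate_genome(spec: SimulationSpec) -> tuple[dict[str, str], GroundTruth]:
    """Random background genome with planted hairpin precursors and
    contaminant class sequences at recorded, non-overlapping loci.

    A planted precursor is mature + loop + reverse-complement(mature), a
    perfect inverted repeat whose duplex the folding stage must recover.
    The recorded star is read off the final genome with the canonical 2-nt
    3' overhang shift, so library star reads are exactly what discovery
    predicts.
    """
    rng = np.random.default_rng(spec.seed)
    genome = list(_random_seq(rng, spec.genome_length))
    contig = "chr1"
    margin = 300
    spacing = (spec.genome_length - 2 * margin) // max(
        1, spec.n_hairpins + len(spec.contaminants) * max((n for n, _ in spec.contaminants.values()), default=0)
    )
    cursor = margin
    means = _condition_means(spec, rng)
    plan = spec.plan()

    hairpins: list[PlantedHairpin] = []
    for i in range(spec.n_hairpins):
        mature = _random_seq(rng, spec.mature_length)
        if rng.random() < spec.five_prime_u_prob:
            mature = "T" + mature[1:]
        loop = int(rng.integers(6, 13))
        precursor = mature + _random_seq(rng, loop) + reverse_complement(mature)
        pos = cursor + int(rng.integers(0, max(1, spacing - len(precursor) - 50)))
        genome[pos : pos + len(precursor)] = list(precursor)
        cursor = pos + len(precursor) + 60
        hairpins.append(
            PlantedHairpin(
                name=f"hp{i + 1:02d}",
                precursor_interval=GenomicInterval(
                    contig, pos, pos + len(precursor), "+"
                ),
                mature=mature,
                mature_interval=GenomicInterval(
                    contig, pos, pos + spec.mature_length, "+"
                ),
                star="",  # filled in after planting below
                loop_length=loop,
                control_mean=means[i][0],
                treatment_mean=means[i][1],
                star_expressed=i < round(spec.star_expressed_fraction * spec.n_hairpins),
                response=plan[i],
            )
        )

    contaminants: list[PlantedSequence] = []
    for label in sorted(spec.contaminants):
        n_seqs, length = spec.contaminants[label]
        for k in range(n_seqs):
            seq = _random_seq(rng, length)
            pos = cursor + int(rng.integers(0, 50))
            genome[pos : pos + length] = list(seq)
            cursor = pos + length + 60
            contaminants.append(
                PlantedSequence(
                    f"{label}{k + 1}",
                    label,
                    seq,
                    GenomicInterval(contig, pos, pos + length, "+"),
                )
            )
    if cursor >= spec.genome_length - margin:
        raise ValueError("infeasible packing: genome too short for the spec")

    genome_str = "".join(genome)
    # star = duplex partner region of the mature, shifted 2 nt (3' overhangs)
    for hp in hairpins:
        a = hp.precursor_interval.start
        s0 = a + spec.mature_length + hp.loop_length + 2
        s1 = s0 + spec.mature_length
        hp.star = genome_str[s0:s1]
    return {contig: genome_str}, GroundTruth(hairpins, contaminants)


def _apply_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    chars = list(read)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def _jitter(
    genome: str, start: int, end: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Shift one end of [start, end) by one base, staying in bounds."""
    moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    ds, de = moves[int(rng.integers(0, 4))]
    s, e = start + ds, end + de
    if s < 0 or e > len(genome) or e - s < 18:
        return start, end
    return s, e


def _emit_read(insert: str, spec: SimulationSpec) -> str:
    return (insert + spec.adapter + "A" * spec.read_length)[: spec.read_length]


def simulate_libraries(
    spec: SimulationSpec,
    genome: dict[str, str],
    truth: GroundTruth,
) -> dict[str, list[str]]:
    """Draw the two condition libraries as raw (adapter-carrying) reads.

    Per-miRNA and per-contaminant read counts are Poisson with the planted
    means (one library per condition: no replicate dispersion to model).
    Background reads are genomic fragments drawn outside all planted loci
    with the 21/24-peaked length profile, so they collapse to unannotated
    tags rather than colliding with planted sequences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    contig = next(iter(genome))
    gseq = genome[contig]
    blocked = np.zeros(len(gseq), dtype=bool)
    for hp in truth.hairpins:
        iv = hp.precursor_interval
        blocked[max(0, iv.start - 35) : iv.end + 35] = True
    for c in truth.contaminants:
        blocked[c.interval.start : c.interval.end] = True
    free_positions = np.flatnonzero(~blocked[: len(gseq) - 31])

    lengths, length_probs = spec.length_probabilities()
    libraries: dict[str, list[str]] = {}
    for cond_idx, condition in enumerate(("control", "treatment")):
        reads: list[str] = []
        for hp in truth.hairpins:
            mean = hp.control_mean if condition == "control" else hp.treatment_mean
            count = int(rng.poisson(mean)) if mean > 0 else 0
            m0, m1 = hp.mature_interval.start, hp.mature_interval.end
            for _ in range(count):
                s, e = m0, m1
                if rng.random() < spec.jitter_prob:
                    s, e = _jitter(gseq, s, e, rng)
                insert = _apply_errors(gseq[s:e], rng, spec.error_rate)
                reads.append(_emit_read(insert, spec))
            if hp.star_expressed and mean > 0:
                star_mean = max(8.0, spec.star_mean_fraction * mean)
                a = (
                    hp.precursor_interval.start
                    + spec.mature_length
                    + hp.loop_length
                    + 2
                )
                for _ in range(int(rng.poisson(star_mean))):
                    s, e = a, a + len(hp.star)
                    if rng.random() < spec.jitter_prob:
                        s, e = _jitter(gseq, s, e, rng)
                    insert = _apply_errors(gseq[s:e], rng, spec.error_rate)
                    reads.append(_emit_read(insert, spec))
        for c in truth.contaminants:
            for _ in range(int(rng.poisson(spec.contaminant_mean_reads))):
                length = int(rng.choice(lengths, p=length_probs))
                length = min(length, len(c.sequence))
                start = int(rng.integers(0, len(c.sequence) - length + 1))
                insert = _apply_errors(
                    c.sequence[start : start + length], rng, spec.error_rate
                )
                reads.append(_emit_read(insert, spec))
        if len(free_positions):
            starts = rng.choice(free_positions, size=spec.background_reads)
            frag_lengths = rng.choice(lengths, p=length_probs, size=spec.background_reads)
            strands = rng.random(spec.background_reads) < 0.5
            for start, length, fwd in zip(starts, frag_lengths, strands):
                insert = gseq[int(start) : int(start) + int(length)]
                if not fwd:
                    insert = reverse_complement(insert)
                reads.append(_emit_read(insert, spec))
        libraries[condition] = reads
    return libraries


def true_response(hp: PlantedHairpin) -> str:
    """Planted response class implied by the condition means."""
    if hp.control_mean == 0 and hp.treatment_mean > 0:
        return "treatment_only"
    if hp.treatment_mean == 0 and hp.control_mean > 0:
        return "control_only"
    if hp.control_mean == 0 and hp.treatment_mean == 0:
        return "unchanged"
    ratio = hp.treatment_mean / hp.control_mean
    if ratio >= 1.5:
        return "up"
    if ratio <= 1 / 1.5:
        return "down"
    return "unchanged"


def shuffle_genome(genome: dict[str, str], seed: int) -> dict[str, str]:
    """Per-contig base shuffle: same composition, no planted structure —
    the negative control for hairpin discovery."""
    rng = np.random.default_rng(seed)
    return {
        contig: "".join(rng.permutation(list(seq))) for contig, seq in genome.items()
    }


def write_bundle(
    spec: SimulationSpec,
    genome: dict[str, str],
    truth: GroundTruth,
    libraries: dict[str, list[str]],
    outdir,
) -> dict[str, Path]:
    """Write genome/contaminant FASTA, per-condition FASTQ and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fasta"
    write_fasta(
        [NucleotideSequence(c, s) for c, s in genome.items()], paths["genome"]
    )
    by_class = truth.contaminant_sequences()
    for label, seqs in sorted(by_class.items()):
        p = outdir / f"{label}.fasta"
        write_fasta(
            [NucleotideSequence(f"{label}{i + 1}", s) for i, s in enumerate(seqs)], p
        )
        paths[label] = p
    for condition, reads in libraries.items():
        p = outdir / f"{condition}.fastq"
        write_fastq(reads, p, prefix=f"{condition}_")
        paths[condition] = p
    truth_path = outdir / "truth_hairpins.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "name\tcontig\tstart\tend\tmature\tstar\tstar_expressed\t"
            "control_mean\ttreatment_mean\tresponse\n"
        )
        for hp in truth.hairpins:
            iv = hp.precursor_interval
            fh.write(
                f"{hp.name}\t{iv.contig}\t{iv.start}\t{iv.end}\t{hp.mature}\t"
                f"{hp.star}\t{int(hp.star_expressed)}\t{hp.control_mean:g}\t"
                f"{hp.treatment_mean:g}\t{hp.response}\n"
            )
    paths["truth"] = truth_path
    return paths
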