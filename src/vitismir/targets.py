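"""miRNA target prediction on a transcript set and cleavage-site validation.

Plant miRNAs direct cleavage of near-perfectly complementary sites, so
prediction is an exhaustive ungapped scan: every transcript window of the
miRNA's length is scored against the reverse complement of the miRNA with a
mismatch budget (default <= 3), optionally tightened by the classic
positional rules for functional plant targets — perfect pairing opposite
miRNA positions 10-11 (the cleavage site), at most one mismatch within
positions 2-12, and G:U wobble pairs charged half a mismatch.

Cleavage validation implements the RLM-5'-RACE reading: the observed
coordinate is the 5' end of the downstream cleavage fragment, and the site
is supported when that nucleotide pairs with the 9th, 10th or 11th
nucleotide of the miRNA (counting from its 5' end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqio import NucleotideSequence

DEFAULT_MAX_MISMATCH = 3.0
SUPPORTED_POSITIONS = (9, 10, 11)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TargetSite:
    """An ungapped complementary site of one miRNA on one transcript."""

    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    mismatches: float  # G:U wobbles count 0.5
    alignment: str  # miRNA 5'->3' over the reverse-complemented site


@dataclass(frozen=True)
class CleavageObservation:
    """A mapped transcript cleavage terminus with clone support."""

    transcript_id: str
    coordinate: int  # 0-based: first nucleotide of the downstream fragment
    clones: int = 1


@dataclass(frozen=True)
class PairingRules:
    """Positional stringency for functional plant target sites. Each rule
    can be switched off independently."""

    require_perfect_10_11: bool = True
    max_mismatch_2_12: float = 1.0
    gu_wobble_cost: float = 0.5


def _position_cost(mirna_base: str, transcript_base: str, gu_cost: float) -> float:
    """Cost of one miRNA:target pairing: 0 for Watson-Crick, ``gu_cost``
    for a G:U wobble, 1 otherwise. N never pairs."""
    if mirna_base not in _COMP or transcript_base not in _COMP:
        return 1.0
    if _COMP[mirna_base] == transcript_base:
        return 0.0
    if (mirna_base, transcript_base) in (("G", "T"), ("T", "G")):
        return gu_cost
    return 1.0


def score_site(
    mirna: str,
    site: str,
    rules: PairingRules | None = PairingRules(),
) -> float | None:
    """Mismatch score of an ungapped miRNA/site duplex, or None when a
    positional rule disqualifies the site.

    ``site`` is the transcript window 5'->3'; the miRNA binds antiparallel,
    so miRNA position p (1-based from the miRNA 5' end) pairs the site base
    at index ``len(site) - p``.
    """
    if len(site) != len(mirna):
        raise ValueError("site and miRNA lengths differ")
    gu = rules.gu_wobble_cost if rules is not None else 0.5
    total = 0.0
    seed_mismatch = 0.0
    for p in range(1, len(mirna) + 1):
        cost = _position_cost(mirna[p - 1], site[len(site) - p], gu)
        total += cost
        if rules is not None:
            if rules.require_perfect_10_11 and p in (10, 11) and cost > 0:
                return None
            if 2 <= p <= 12:
                seed_mismatch += cost
    if rules is not None and seed_mismatch > rules.max_mismatch_2_12:
        return None
    return total


def predict_targets(
    mirna: str,
    transcripts: Iterable[NucleotideSequence],
    max_mismatch: float = DEFAULT_MAX_MISMATCH,
    rules: PairingRules | None = PairingRules(),
    mirna_id: str = "miRNA",
) -> list[TargetSite]:
    """All candidate target sites of one miRNA across a transcript set.

    Scans every ungapped window; a window is a site when its score is
    within ``max_mismatch`` (and passes the positional rules unless
    ``rules`` is None).
    """
    n = len(mirna)
    sites: list[TargetSite] = []
    for tx in transcripts:
        seq = tx.residues
        for start in range(0, len(seq) - n + 1):
            window = seq[start : start + n]
            score = score_site(mirna, window, rules)
            if score is None or score > max_mismatch:
                continue
            sites.append(
                TargetSite(
                    mirna_id=mirna_id,
                    transcript_id=tx.identifier,
                    start=start,
                    end=start + n,
                    mismatches=score,
                    alignment=mirna,
                )
            )
    return sites


def validate_cleavage(
    site: TargetSite, obs: CleavageObservation
) -> tuple[str, int | None]:
    """Check a RACE-mapped cleavage terminus against a predicted site.

    Returns ("supported"|"unsupported", miRNA position index). The index is
    the miRNA position (1-based from its 5' end) pairing the transcript
    nucleotide at the observed coordinate; cleavage between the bases
    opposite miRNA positions 9-11 is the hallmark of miRNA-guided slicing.
    A coordinate outside the site is unsupported with an undefined index.
    """
    if obs.transcript_id != site.transcript_id:
        raise ValueError("cleavage observation is on a different transcript")
    if not site.start <= obs.coordinate < site.end:
        return "unsupported", None
    position = site.end - obs.coordinate
    status = "supported" if position in SUPPORTED_POSITIONS else "unsupported"
    return status, position
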