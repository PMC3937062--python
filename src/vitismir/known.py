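"""Known-miRNA identification: mismatch-tolerant ungapped matching of tags
against a mature-miRNA reference, identifier/family parsing, and family
summaries.

Matching is ungapped with a signed offset (shift of the tag start relative
to the reference start) to absorb isomiR end-variants: the cost of an
alignment is the number of internal mismatches within the overlap plus the
unaligned overhang bases of the shorter sequence, and a tag is accepted when
the best cost is within the mismatch budget (default 0-3). N never matches
anything.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_MAX_MISMATCH = 3
DEFAULT_MAX_SHIFT = 4


@dataclass(frozen=True)
class MatchResult:
    """Best ungapped hit of a tag against a reference set.

    ``mismatches`` is the full cost (internal mismatches + overhang of the
    shorter sequence); ``offset`` is the signed shift of the tag start
    relative to the reference start.
    """

    tag: str
    reference_id: str
    mismatches: int
    offset: int


def ungapped_cost(tag: str, reference: str, offset: int) -> int:
    """Cost of aligning ``tag`` with its start at ``offset`` relative to the
    reference start: internal mismatches in the overlap plus the overhang of
    the shorter sequence (its bases left out of the overlap)."""
    lo = max(0, offset)
    hi = min(len(reference), offset + len(tag))
    overlap = max(0, hi - lo)
    mismatches = 0
    for k in range(lo, hi):
        a = tag[k - offset]
        b = reference[k]
        if a != b or a == "N":
            mismatches += 1
    return mismatches + min(len(tag), len(reference)) - overlap


def match_known(
    tag: str,
    reference: Mapping[str, str] | Sequence,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> MatchResult | None:
    """Best reference hit for one tag, or None when nothing is within budget.

    Evaluates every reference at every offset with ``|offset| <= max_shift``.
    Ties break by lower cost, then smaller ``|offset|`` (positive before
    negative), then lexicographically smallest reference identifier.
    """
    if hasattr(reference, "items"):
        refs = sorted(reference.items())
    else:
        refs = sorted(
            (r.identifier, r.residues) if hasattr(r, "identifier") else tuple(r)
            for r in reference
        )
    offsets = sorted(range(-max_shift, max_shift + 1), key=lambda o: (abs(o), -o))
    best: MatchResult | None = None
    for ref_id, ref_seq in refs:
        for offset in offsets:
            cost = ungapped_cost(tag, ref_seq, offset)
            if cost > max_mismatch:
                continue
            if best is None or (cost, abs(offset)) < (
                best.mismatches,
                abs(best.offset),
            ):
                best = MatchResult(tag, ref_id, cost, offset)
    return best


def match_known_bulk(
    tags: Iterable[str],
    reference: Mapping[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> dict[str, MatchResult]:
    """Vectorized equivalent of :func:`match_known` over many tags.

    Groups tags by length, encodes them as byte matrices, and scores each
    (reference, offset) pair with one array comparison, so whole-library
    matching stays fast. Returns only tags with a hit within budget; agrees
    with the per-tag scorer (including tie-breaks) by construction of the
    iteration order.
    """
    tags = sorted(set(tags))
    by_len: dict[int, list[str]] = defaultdict(list)
    for t in tags:
        by_len[len(t)].append(t)
    encoded = {
        n: np.frombuffer("".join(group).encode(), dtype=np.uint8).reshape(
            len(group), n
        )
        for n, group in by_len.items()
    }
    n_mask = {n: (arr == ord("N")) for n, arr in encoded.items()}
    best_cost = {n: np.full(len(g), max_mismatch + 1, dtype=np.int32) for n, g in by_len.items()}
    best_absoff = {n: np.full(len(g), 2 * max_shift + 1, dtype=np.int32) for n, g in by_len.items()}
    best_ref = {n: np.full(len(g), -1, dtype=np.int32) for n, g in by_len.items()}
    best_off = {n: np.zeros(len(g), dtype=np.int32) for n, g in by_len.items()}

    ref_items = sorted(reference.items())
    offsets = sorted(range(-max_shift, max_shift + 1), key=lambda o: (abs(o), -o))
    for ref_idx, (ref_id, ref_seq) in enumerate(ref_items):
        ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        rlen = len(ref_seq)
        for offset in offsets:
            for n, arr in encoded.items():
                lo = max(0, offset)
                hi = min(rlen, offset + n)
                overlap = hi - lo
                if overlap <= 0:
                    continue
                sub = arr[:, lo - offset : hi - offset]
                # mismatch iff bases differ or the tag base is N (N never matches)
                mism = (
                    (sub != ref_arr[lo:hi]) | n_mask[n][:, lo - offset : hi - offset]
                ).sum(axis=1)
                cost = mism + (min(n, rlen) - overlap)
                better = (cost < best_cost[n]) | (
                    (cost == best_cost[n]) & (abs(offset) < best_absoff[n])
                )
                better &= cost <= max_mismatch
                if better.any():
                    best_cost[n][better] = cost[better]
                    best_absoff[n][better] = abs(offset)
                    best_off[n][better] = offset
                    best_ref[n][better] = ref_idx

    results: dict[str, MatchResult] = {}
    for n, group in by_len.items():
        for i, tag in enumerate(group):
            if best_ref[n][i] >= 0:
                results[tag] = MatchResult(
                    tag,
                    ref_items[best_ref[n][i]][0],
                    int(best_cost[n][i]),
                    int(best_off[n][i]),
                )
    return results


class ParsedMiRNAId(NamedTuple):
    identifier: str
    family: str
    star: bool
    origin: str  # "known" or "novel"


_ID_PATTERN = re.compile(
    r"^[Vv]vi?-miR(?:C(?P<cnum>\d+)|(?P<num>\d+)(?P<suffix>[a-z]?))(?P<star>\*)?$"
)


def parse_mirna_id(identifier: str) -> ParsedMiRNAId:
    """Parse a grapevine miRNA identifier into family, star flag and origin.

    Known identifiers look like ``Vvi-miR156a`` (family miR156; the letter
    suffix distinguishes members); novel candidates carry a C-number like
    ``Vvi-miRC20`` (family C20). A trailing ``*`` marks the star (passenger)
    strand and is stripped from the family but recorded.
    """
    m = _ID_PATTERN.match(identifier.strip())
    if m is None:
        raise ValueError(f"unparsable miRNA identifier {identifier!r}")
    if m.group("cnum") is not None:
        return ParsedMiRNAId(
            identifier, f"C{int(m.group('cnum')):02d}", m.group("star") is not None, "novel"
        )
    return ParsedMiRNAId(
        identifier, f"miR{m.group('num')}", m.group("star") is not None, "known"
    )


def assign_family(identifier: str) -> str:
    """Family label for an identifier (e.g. Vvi-miR395a -> miR395)."""
    return parse_mirna_id(identifier).family


def family_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-family member counts and per-library normalized-count sums.

    ``records`` needs columns ``identifier``, ``nc_control``,
    ``nc_treatment``. Star records contribute to NC sums but not to the
    member count (members are distinct non-star identifiers).
    """
    df = records.copy()
    if df.empty:
        return pd.DataFrame(
            columns=["members", "nc_control", "nc_treatment"],
            index=pd.Index([], name="family"),
        )
    parsed = df["identifier"].map(parse_mirna_id)
    df["family"] = [p.family for p in parsed]
    df["star"] = [p.star for p in parsed]
    grouped = df.groupby("family")
    out = pd.DataFrame(
        {
            "members": grouped.apply(
                lambda g: g.loc[~g["star"], "identifier"].nunique(),
                include_groups=False,
            ),
            "nc_control": grouped["nc_control"].sum(),
            "nc_treatment": grouped["nc_treatment"].sum(),
        }
    )
    return out.sort_index()


def aggregate_tag_counts(
    matches: Mapping[str, MatchResult],
    control: Mapping[str, int],
    treatment: Mapping[str, int],
) -> pd.DataFrame:
    """Attribute each matched tag's raw counts to its single best reference.

    Returns a DataFrame indexed by reference identifier with raw
    ``control``/``treatment`` count sums; abundance is never double-counted
    because every tag has exactly one best hit.
    """
    sums: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for tag, match in matches.items():
        sums[match.reference_id][0] += control.get(tag, 0)
        sums[match.reference_id][1] += treatment.get(tag, 0)
    df = pd.DataFrame.from_dict(
        sums, orient="index", columns=["control", "treatment"]
    )
    df.index.name = "identifier"
    return df.sort_index()
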