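"""Two-library differential classification of miRNA abundance.

Counts are normalized to reads-per-million within each library (NC,
"normalized counts") and every miRNA is placed in one of five response
classes by comparing its control and treatment NC values:

    up              NC ratio treatment/control >= fold threshold   (↑)
    down            NC ratio <= 1/fold threshold                   (↓)
    treatment_only  zero in control, positive in treatment         (▲)
    control_only    positive in control, zero in treatment         (▼)
    unchanged       everything else, including zero in both        (●)

The study design is one library per condition, so no replicate dispersion
model is available or pretended: the presence/absence classes are exact
statements about the observed libraries, and the fold classes are
descriptive with a configurable threshold (default 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_FOLD_THRESHOLD = 1.5

GLYPHS = {
    "up": "↑",
    "down": "↓",
    "treatment_only": "▲",
    "control_only": "▼",
    "unchanged": "●",
}
CLASS_FROM_GLYPH = {v: k for k, v in GLYPHS.items()}

RESPONSE_CLASSES = tuple(GLYPHS)


@dataclass(frozen=True)
class ResponseCall:
    """Five-way response class with the fold change when defined."""

    response: str
    fold_change: float | None

    @property
    def glyph(self) -> str:
        return GLYPHS[self.response]


def normalize_counts(raw: int, library_total: int) -> float:
    """Reads-per-million normalization: NC = raw / total x 1e6.

    Carried at full precision; round to 2 decimals only in reports.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if raw < 0:
        raise ValueError("raw count must be non-negative")
    return raw / library_total * 1_000_000


def classify_response(
    nc_control: float,
    nc_treatment: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> ResponseCall:
    """Classify one miRNA's response from its two NC values.

    Presence/absence outranks the ratio and is independent of the fold
    threshold; the fold change is undefined whenever either NC is zero.
    """
    if nc_control < 0 or nc_treatment < 0:
        raise ValueError("NC values must be non-negative")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if nc_control == 0 and nc_treatment == 0:
        return ResponseCall("unchanged", None)
    if nc_control == 0:
        return ResponseCall("treatment_only", None)
    if nc_treatment == 0:
        return ResponseCall("control_only", None)
    ratio = nc_treatment / nc_control
    if ratio >= fold_threshold:
        return ResponseCall("up", ratio)
    if ratio <= 1 / fold_threshold:
        return ResponseCall("down", ratio)
    return ResponseCall("unchanged", ratio)


def call_responses(
    table: pd.DataFrame, fold_threshold: float = DEFAULT_FOLD_THRESHOLD
) -> pd.DataFrame:
    """Add ``response``/``glyph``/``fold_change`` columns to an NC table
    (columns ``nc_control`` and ``nc_treatment`` required)."""
    calls = [
        classify_response(c, t, fold_threshold)
        for c, t in zip(table["nc_control"], table["nc_treatment"])
    ]
    out = table.copy()
    out["response"] = [c.response for c in calls]
    out["glyph"] = [c.glyph for c in calls]
    out["fold_change"] = [c.fold_change for c in calls]
    return out


def summarize_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts partitioned by origin and star status.

    ``table`` needs a ``response`` column; optional boolean ``star`` and
    categorical ``origin`` ({known, novel}) columns refine the partition
    (star records are tallied separately from mature ones). Returns a
    DataFrame indexed by (origin, star) with one column per response class.
    """
    df = table.copy()
    if "origin" not in df:
        df["origin"] = "all"
    if "star" not in df:
        df["star"] = False
    counts = (
        df.groupby(["origin", "star", "response"], observed=True)
        .size()
        .unstack("response", fill_value=0)
    )
    for cls in RESPONSE_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    return counts[list(RESPONSE_CLASSES)].sort_index()


def read_nc_table(path) -> pd.DataFrame:
    """Read a normalized-count table (TSV with columns ``identifier``,
    ``sequence``, ``nc_control``, ``nc_treatment`` and optionally a printed
    ``mark`` glyph column)."""
    df = pd.read_csv(path, sep="\t", dtype={"identifier": str, "sequence": str})
    required = {"identifier", "sequence", "nc_control", "nc_treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_nc_table(table: pd.DataFrame, path) -> None:
    """Write an NC table with the 2-decimal report formatting."""
    out = table.copy()
    for col in ("nc_control", "nc_treatment"):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    if "fold_change" in out:
        out["fold_change"] = out["fold_change"].map(
            lambda v: "" if v is None else f"{v:.3f}"
        )
    out.to_csv(path, sep="\t", index=False)
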