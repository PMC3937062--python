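"""Bundled normalized-count reference tables.

Two TSVs ship with the package: the published normalized counts (control
vs. GA3-treated grapevine berry libraries) for the 122 known grapevine
miRNAs and for the 90 novel candidates with their 28 detected star strands.
They are the desk-scale inputs for the differential-classification stage
and for the package's self-checks; response classes are always recomputed
from the NC columns, never read off the printed glyph column.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .differential import read_nc_table
from .known import parse_mirna_id

_DATA = files("vitismir.data")


def _load(name: str, origin: str) -> pd.DataFrame:
    df = read_nc_table(_DATA / name)
    parsed = df["identifier"].map(parse_mirna_id)
    df["family"] = [p.family for p in parsed]
    df["star"] = [p.star for p in parsed]
    df["origin"] = origin
    return df


def load_known_table() -> pd.DataFrame:
    """NC table of the 122 known miRNAs (columns: identifier, sequence,
    nc_control, nc_treatment, mark, family, star, origin)."""
    return _load("known_mirna_counts.tsv", "known")


def load_novel_table() -> pd.DataFrame:
    """NC table of the 90 novel candidate miRNAs plus their 28 star rows."""
    return _load("novel_mirna_counts.tsv", "novel")


def load_all() -> pd.DataFrame:
    return pd.concat(
        [load_known_table(), load_novel_table()], ignore_index=True
    )
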