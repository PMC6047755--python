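"""Contact-list input.

The text format is tab-separated ``chr1 pos1 chr2 pos2 [count]`` with
1-based positions; ``#`` lines are comments. Contacts may also be supplied
programmatically as an iterable of tuples or a pandas DataFrame with the
same columns.
"""

from __future__ import annotations

import io
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import InputError
from .genome import ChromosomeTable

COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "count"]

ContactInput = Union[str, "io.TextIOBase", pd.DataFrame, Iterable[tuple]]


def read_contacts(source: ContactInput) -> pd.DataFrame:
    """Load contact records into a DataFrame (chrom1, pos1, chrom2, pos2, count).

    ``source`` may be a path, an open text stream, a DataFrame, or an
    iterable of (chr1, pos1, chr2, pos2[, count]) tuples. Missing counts
    default to 1. Positions stay 1-based here; binning converts.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if "count" not in df.columns:
            df["count"] = 1.0
        df = df[COLUMNS]
    elif isinstance(source, (str,)) or hasattr(source, "read"):
        df = _read_text(source)
    else:
        rows = []
        for rec in source:
            rec = tuple(rec)
            if len(rec) == 4:
                rec = rec + (1.0,)
            elif len(rec) != 5:
                raise InputError(f"contact record needs 4 or 5 fields, got {rec!r}")
            rows.append(rec)
        df = pd.DataFrame(rows, columns=COLUMNS) if rows else _empty()
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    df["count"] = df["count"].astype(np.float64)
    return df


def _empty() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom1": pd.Series(dtype=str),
            "pos1": pd.Series(dtype=np.int64),
            "chrom2": pd.Series(dtype=str),
            "pos2": pd.Series(dtype=np.int64),
            "count": pd.Series(dtype=np.float64),
        }
    )


def _read_text(source) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            source,
            sep="\t",
            comment="#",
            header=None,
            names=COLUMNS,
            dtype={"chrom1": str, "chrom2": str},
        )
    except pd.errors.EmptyDataError:
        return _empty()
    except ValueError as exc:
        raise InputError(f"cannot parse contact list: {exc}") from None
    if df["count"].isna().all():
        df["count"] = 1.0
    elif df["count"].isna().any():
        raise InputError("contact list mixes 4- and 5-column rows")
    bad = df["pos1"].isna() | df["pos2"].isna()
    if bad.any():
        raise InputError(f"contact record line {bad.idxmax() + 1}: missing position")
    return df


def validate_contacts(df: pd.DataFrame, chrom_sizes: ChromosomeTable) -> None:
    """Check every record against the chromosome table.

    Raises :class:`InputError` naming the first offending record line
    (1-based over data rows).
    """
    known = set(chrom_sizes.names())
    for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
        unknown = ~df[col_c].isin(known)
        if unknown.any():
            i = int(np.argmax(unknown.to_numpy()))
            raise InputError(
                f"contact record {i + 1}: unknown chromosome {df[col_c].iloc[i]!r}"
            )
        lengths = df[col_c].map(lambda n: chrom_sizes[n].length).to_numpy()
        pos = df[col_p].to_numpy()
        bad = (pos < 1) | (pos > lengths)
        if bad.any():
            i = int(np.argmax(bad))
            raise InputError(
                f"contact record {i + 1}: position {pos[i]} outside "
                f"{df[col_c].iloc[i]} (length {lengths[i]})"
            )
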