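"""Tabular output writers/parsers.

Coordinate conventions: bedGraph intervals are 0-based half-open with beta in
percent; the per-cytosine report is 1-based with raw counts and context, one
row per strand-resolved cytosine.  Both are emitted in coordinate order so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from ..methylquant import SITE_COLUMNS, HotspotRecord

_CYT_HEADER = ["reference", "pos_1based", "strand", "meth", "unmeth", "context"]


def write_bedgraph(sites: pd.DataFrame, path: str | Path) -> None:
    """Per-site beta (percent) as ``ref  start  end  percent`` lines."""
    ordered = sites.sort_values(["reference", "pos", "strand"])
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="methylation"\n')
        for row in ordered.itertuples():
            fh.write(f"{row.reference}\t{row.pos}\t{row.pos + 1}\t{100.0 * row.beta:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("track"):
            continue
        ref, start, end, pct = line.split("\t")
        rows.append((ref, int(start), int(end), float(pct) / 100.0))
    return pd.DataFrame(rows, columns=["reference", "start", "end", "beta"])


def write_cytosine_report(sites: pd.DataFrame, path: str | Path) -> None:
    ordered = sites.sort_values(["reference", "pos", "strand"])
    with open(path, "w") as fh:
        fh.write("\t".join(_CYT_HEADER) + "\n")
        for row in ordered.itertuples():
            fh.write(
                f"{row.reference}\t{row.pos + 1}\t{row.strand}\t"
                f"{row.meth}\t{row.unmeth}\t{row.context}\n"
            )


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Parse a cytosine report back into the internal 0-based site table."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos_1based"] - 1
    df["beta"] = df["meth"] / (df["meth"] + df["unmeth"])
    return df[SITE_COLUMNS]


def write_hotspots(records: Iterable[HotspotRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reference\tpos\tstrand\tbeta\twindow\tsupporting_ch\n")
        for rec in records:
            support = ",".join(f"{p}:{b:.6g}" for p, b in rec.supporting_ch)
            fh.write(f"{rec.reference}\t{rec.pos}\t{rec.strand}\t{rec.beta:.6g}\t{rec.window}\t{support}\n")


def write_beta_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Samples x markers TSV (index column = sample id)."""
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(value):
    if hasattr(value, "tolist"):
        return value.tolist()
    if hasattr(value, "item"):
        return value.item()
    raise TypeError(f"not JSON serializable: {type(value)}")
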