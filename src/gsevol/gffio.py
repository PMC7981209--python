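"""GFF3 / BED writers and a minimal GFF3 reader for the pipeline's own files.

Internally all coordinates are 0-based half-open; GFF3 output is 1-based
inclusive with a ``##gff-version 3`` pragma, BED output is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _fmt_attrs(attrs: Mapping[str, object]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def write_gff3(
    rows: Iterable[tuple[str, str, str, int, int, object, str, Mapping[str, object]]],
    path: str | Path,
) -> None:
    """Write features given as (seqid, source, type, start0, end0, score, strand, attrs)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start0, end0, score, strand, attrs in rows:
            score_s = "." if score is None else f"{score:g}"
            fh.write(
                "\t".join(
                    [
                        seqid, source, ftype,
                        str(start0 + 1), str(end0),
                        score_s, strand, ".", _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a frame with 0-based half-open start/end.

    Attribute key=value pairs are expanded into columns.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str},
    )
    if df.empty:
        return df
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    attr_frame = df["attributes"].map(_parse_attrs).apply(pd.Series)
    return pd.concat([df.drop(columns=["attributes"]), attr_frame], axis=1)


def _parse_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for field in str(text).split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k] = v
    return out


def write_bed(
    rows: Iterable[tuple[str, int, int, str, object, str]], path: str | Path
) -> None:
    """Write (chrom, start0, end0, name, score, strand) records as BED6."""
    with open(path, "w") as fh:
        for chrom, start0, end0, name, score, strand in rows:
            score_s = "0" if score is None else f"{score:g}"
            fh.write(f"{chrom}\t{start0}\t{end0}\t{name}\t{score_s}\t{strand}\n")
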