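"""Binned depth tracks (bedGraph) for nuclear and mitochondrial contigs.

The in-memory container is a pandas DataFrame with columns
``chrom, start, end, depth`` (0-based half-open intervals, mean read depth
per bin) plus a derived ``subgenome`` column.  Mitochondrial contigs are
part of the same track and are separated out by name.
"""

from __future__ import annotations

import pandas as pd

from .references import is_mito, subgenome_of

COLUMNS = ["chrom", "start", "end", "depth"]


def as_track(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a depth DataFrame and attach the subgenome column."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"depth track lacks columns {missing}")
    df = df.copy()
    if (df["start"] >= df["end"]).any():
        raise ValueError("depth track has empty or inverted bins")
    if (df["depth"] < 0).any():
        raise ValueError("depth track has negative depths")
    df["subgenome"] = df["chrom"].map(subgenome_of)
    if df["subgenome"].isna().any():
        bad = df.loc[df["subgenome"].isna(), "chrom"].unique()
        raise ValueError(f"depth track has contigs from no known subgenome: {list(bad)}")
    return df


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=COLUMNS, dtype=str)
    # tolerate UCSC "track ..." header lines and comments
    df = df[~df["chrom"].str.startswith(("track", "#"))]
    df = df.astype({"start": int, "end": int, "depth": float}).reset_index(drop=True)
    return as_track(df)


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[COLUMNS].to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


def nuclear(track: pd.DataFrame) -> pd.DataFrame:
    return track[~track["chrom"].map(is_mito)]


def mitochondrial(track: pd.DataFrame) -> pd.DataFrame:
    return track[track["chrom"].map(is_mito)]


def chromosome_depths(track: pd.DataFrame, chrom: str) -> pd.Series:
    sub = track[track["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no depth bins for contig {chrom!r}")
    return sub["depth"].reset_index(drop=True)
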