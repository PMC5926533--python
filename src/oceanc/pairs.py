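"""Read-pair classification and valid-pair filtering.

A sequenced ligation product maps as two 5' coordinates with strands.  Pairs
with both ends in the same restriction fragment are artifacts: inward-facing
pairs are dangling ends (unligated fragments), outward-facing pairs are
self-circles (fragments ligated to themselves), and same-strand pairs are
dumped.  Pairs whose fragments lie closer than ``min_separation`` (1 kb by
default) are discarded as uninformative short-range products.  Everything
else is a valid cis or trans contact and feeds every downstream stage.

Bulk classification is vectorised over a pandas DataFrame with columns
``chrom1 pos1 strand1 chrom2 pos2 strand2 mapq1 mapq2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genome import FragmentMap

__all__ = [
    "PairClass",
    "ReadPair",
    "classify_pair",
    "classify_pairs_frame",
    "filter_pairs",
    "read_bedpe",
    "write_pairs",
    "read_pairs",
]

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "mapq1", "mapq2"]


class PairClass(str, Enum):
    VALID_CIS = "VALID_CIS"
    VALID_TRANS = "VALID_TRANS"
    DANGLING_END = "DANGLING_END"
    SELF_CIRCLE = "SELF_CIRCLE"
    SAME_STRAND_DUMPED = "SAME_STRAND_DUMPED"
    TOO_CLOSE = "TOO_CLOSE"
    LOW_MAPQ = "LOW_MAPQ"


VALID_CLASSES = (PairClass.VALID_CIS, PairClass.VALID_TRANS)


@dataclass(frozen=True)
class ReadPair:
    """One mapped ligation product: two 5' coordinates with strands and MAPQ."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapq1: int = 30
    mapq2: int = 30
    pair_id: str = "."


def classify_pair(
    pair: ReadPair,
    fragmap: FragmentMap,
    mapq_min: int = 1,
    min_separation: int = 1000,
    distance_mode: str = "midpoint",
) -> PairClass:
    """Classify a single read pair (see :func:`classify_pairs_frame` for bulk).

    Decision order: low MAPQ -> trans -> same-fragment artifact (inward =
    dangling end, outward = self-circle, same strand = dumped) -> fragments
    closer than ``min_separation`` -> valid cis.  Orientation is judged after
    canonically ordering the two mates by coordinate, so the result is
    invariant under mate swap.
    """
    df = pd.DataFrame([{
        "chrom1": pair.chrom1, "pos1": pair.pos1, "strand1": pair.strand1,
        "chrom2": pair.chrom2, "pos2": pair.pos2, "strand2": pair.strand2,
        "mapq1": pair.mapq1, "mapq2": pair.mapq2,
    }])
    out = classify_pairs_frame(df, fragmap, mapq_min, min_separation, distance_mode)
    return PairClass(out["pair_class"].iloc[0])


def classify_pairs_frame(
    pairs: pd.DataFrame,
    fragmap: FragmentMap,
    mapq_min: int = 1,
    min_separation: int = 1000,
    distance_mode: str = "midpoint",
) -> pd.DataFrame:
    """Vectorised classification; returns a copy with added columns.

    Added columns: ``frag1``/``frag2`` (genome-wide fragment ids),
    ``pair_class``, and ``cis_distance`` (absolute 5'-coordinate difference
    for cis pairs, NaN for trans).
    """
    if distance_mode not in ("midpoint", "nearest-edge"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    df = pairs.copy()
    n = len(df)
    if n == 0:
        df["frag1"] = np.array([], dtype=np.int64)
        df["frag2"] = np.array([], dtype=np.int64)
        df["pair_class"] = pd.Series([], dtype=object)
        df["cis_distance"] = np.array([], dtype=float)
        return df

    # canonical mate order: sort the two ends by (chrom, pos)
    swap = (df["chrom2"].to_numpy() < df["chrom1"].to_numpy()) | (
        (df["chrom2"].to_numpy() == df["chrom1"].to_numpy())
        & (df["pos2"].to_numpy() < df["pos1"].to_numpy())
    )
    for a, b in [("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2"),
                 ("mapq1", "mapq2")]:
        va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
        df[a] = np.where(swap, vb, va)
        df[b] = np.where(swap, va, vb)

    frag1 = np.empty(n, dtype=np.int64)
    frag2 = np.empty(n, dtype=np.int64)
    mid1 = np.empty(n, dtype=float)
    mid2 = np.empty(n, dtype=float)
    edge_gap = np.full(n, np.inf)
    for col_chrom, col_pos, frag, mid in [("chrom1", "pos1", frag1, mid1),
                                          ("chrom2", "pos2", frag2, mid2)]:
        for chrom, sub in df.groupby(col_chrom, sort=False):
            idx = sub.index.to_numpy()
            loc = df.index.get_indexer(idx)
            ids = fragmap.assign(chrom, sub[col_pos].to_numpy())
            frag[loc] = ids
            mid[loc] = fragmap.midpoint(chrom, ids)
    # nearest-edge gap between the two fragments (cis, frag1 < frag2)
    if distance_mode == "nearest-edge":
        for chrom, sub in df[df["chrom1"] == df["chrom2"]].groupby("chrom1", sort=False):
            loc = df.index.get_indexer(sub.index.to_numpy())
            starts, ends = fragmap.fragments(chrom)
            off = fragmap._id_offset[chrom]
            lo = np.minimum(frag1[loc], frag2[loc]) - off
            hi = np.maximum(frag1[loc], frag2[loc]) - off
            edge_gap[loc] = np.maximum(starts[hi] - ends[lo], 0)

    cis = df["chrom1"].to_numpy() == df["chrom2"].to_numpy()
    same_frag = cis & (frag1 == frag2)
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    if distance_mode == "midpoint":
        frag_dist = np.abs(mid2 - mid1)
    else:
        frag_dist = edge_gap

    cls = np.full(n, PairClass.VALID_CIS.value, dtype=object)
    cls[cis & ~same_frag & (frag_dist < min_separation)] = PairClass.TOO_CLOSE.value
    cls[same_frag & (s1 == s2)] = PairClass.SAME_STRAND_DUMPED.value
    cls[same_frag & (s1 == "+") & (s2 == "-")] = PairClass.DANGLING_END.value
    cls[same_frag & (s1 == "-") & (s2 == "+")] = PairClass.SELF_CIRCLE.value
    cls[~cis] = PairClass.VALID_TRANS.value
    low = (df["mapq1"].to_numpy() < mapq_min) | (df["mapq2"].to_numpy() < mapq_min)
    cls[low] = PairClass.LOW_MAPQ.value

    df["frag1"] = frag1
    df["frag2"] = frag2
    df["pair_class"] = cls
    dist = np.abs(df["pos2"].to_numpy() - df["pos1"].to_numpy()).astype(float)
    dist[~cis] = np.nan
    df["cis_distance"] = dist
    return df


def filter_pairs(
    pairs: pd.DataFrame,
    fragmap: FragmentMap,
    mapq_min: int = 1,
    min_separation: int = 1000,
    distance_mode: str = "midpoint",
    deduplicate: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify pairs in bulk and return (valid pairs, class counts).

    PCR duplicates (identical coordinates and strands on both ends) are
    collapsed to one copy by default; the number removed is reported under
    ``duplicates_removed``.  Class counts partition the post-deduplication
    input exactly.
    """
    n_in = len(pairs)
    work = pairs
    n_dup = 0
    if deduplicate and n_in:
        keys = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
        work = pairs.drop_duplicates(subset=keys, keep="first")
        n_dup = n_in - len(work)
    classified = classify_pairs_frame(work, fragmap, mapq_min, min_separation, distance_mode)
    counts = {c.value: 0 for c in PairClass}
    vc = classified["pair_class"].value_counts()
    for k, v in vc.items():
        counts[k] = int(v)
    counts["duplicates_removed"] = n_dup
    counts["input_pairs"] = n_in
    valid = classified[
        classified["pair_class"].isin([c.value for c in VALID_CLASSES])
    ].reset_index(drop=True)
    return valid, counts


# ---------------------------------------------------------------------------
# I/O: BEDPE in, annotated .pairs-style text out
# ---------------------------------------------------------------------------

_BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score", "strand1", "strand2", "mapq1", "mapq2"]


def read_bedpe(path) -> pd.DataFrame:
    """Read a BEDPE-like pair table; the 5' coordinate is taken per strand.

    For a '+' end the 5' position is ``start``; for a '-' end it is
    ``end - 1`` (half-open).  Missing MAPQ columns default to 30.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BEDPE_COLS[: df.shape[1]]
    for col in ("mapq1", "mapq2"):
        if col not in df.columns:
            df[col] = 30
    out = pd.DataFrame({
        "chrom1": df["chrom1"],
        "pos1": np.where(df["strand1"] == "-", df["end1"] - 1, df["start1"]),
        "strand1": df["strand1"],
        "chrom2": df["chrom2"],
        "pos2": np.where(df["strand2"] == "-", df["end2"] - 1, df["start2"]),
        "strand2": df["strand2"],
        "mapq1": df["mapq1"],
        "mapq2": df["mapq2"],
    })
    if "name" in df.columns:
        out["name"] = df["name"]
    return out


def write_pairs(path, pairs: pd.DataFrame) -> None:
    """Write pairs as tab-separated text (.pairs-style, with extra columns)."""
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
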