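"""Super-enhancer calling (ROSE-style) and broad H3K4me3 domains.

Super-enhancers: constituent enhancers (H3K27ac-enriched regions) within
12.5 kb of one another are stitched after removing those falling inside
TSS +/- 2 kb promoter zones; stitched regions are ranked by their total
background-subtracted ChIP signal (rpm*bp, negative values floored at 0),
ranks and signals are scaled to [0,1], and the cutoff is the point where a
slope-1 line is tangent to the ascending curve — found exactly on the
empirical curve as argmax(x - y).  Entries strictly right of the cutoff are
super-enhancers.

Broad domains: peaks ranked by width; the widest ceil(5% * N) are flagged
broad (a fixed minimum-width mode, e.g. 4 kb, is also available).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .annotate import overlap_report

__all__ = [
    "stitch_enhancers",
    "region_signal",
    "rank_and_cut",
    "call_broad_domains",
    "domain_hoci_overlap",
]


def stitch_enhancers(
    enhancers: pd.DataFrame,
    tss_positions: pd.DataFrame,
    stitch_gap: int = 12500,
    tss_exclusion: int = 2000,
    exclusion_mode: str = "contained",
) -> pd.DataFrame:
    """Merge enhancers within ``stitch_gap`` after promoter exclusion.

    ``tss_positions`` needs ``chrom`` and ``tss`` columns.  In the default
    ``contained`` mode an enhancer is removed only when fully inside some
    TSS +/- ``tss_exclusion`` window; ``overlap`` mode removes on any
    overlap.  Returns stitched regions with ``n_constituents`` and the
    constituent row indices.
    """
    if exclusion_mode not in ("contained", "overlap"):
        raise ValueError(f"unknown exclusion_mode {exclusion_mode!r}")
    enh = enhancers.sort_values(["chrom", "start"]).reset_index(drop=True)
    keep = np.ones(len(enh), dtype=bool)
    for chrom, sub in enh.groupby("chrom", sort=False):
        tss = np.sort(tss_positions.loc[tss_positions["chrom"] == chrom, "tss"].to_numpy())
        if len(tss) == 0:
            continue
        loc = enh.index.get_indexer(sub.index)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if exclusion_mode == "contained":
            # fully inside some window: exists tss with tss-excl <= s and e <= tss+excl,
            # i.e. tss in [e-excl, s+excl]
            lo = np.searchsorted(tss, e - tss_exclusion, side="left")
            hi = np.searchsorted(tss, s + tss_exclusion, side="right")
            keep[loc[hi > lo]] = False
        else:
            # any overlap with some window [tss-excl, tss+excl): tss in (s-excl, e+excl)
            lo = np.searchsorted(tss, s - tss_exclusion, side="right")
            hi = np.searchsorted(tss, e + tss_exclusion, side="left")
            keep[loc[hi > lo]] = False
    enh = enh[keep].reset_index(drop=False).rename(columns={"index": "constituent_row"})

    rows = []
    for chrom, sub in enh.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        members = sub["constituent_row"].to_numpy()
        cur_s, cur_e, cur_m = s[0], e[0], [int(members[0])]
        for i in range(1, len(s)):
            if s[i] - cur_e < stitch_gap:
                cur_e = max(cur_e, e[i])
                cur_m.append(int(members[i]))
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e),
                             "n_constituents": len(cur_m), "constituents": cur_m})
                cur_s, cur_e, cur_m = s[i], e[i], [int(members[i])]
        rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e),
                     "n_constituents": len(cur_m), "constituents": cur_m})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_constituents",
                                       "constituents"])


def region_signal(
    regions: pd.DataFrame,
    chip: pd.DataFrame,
    control: pd.DataFrame | None = None,
) -> np.ndarray:
    """Total background-subtracted signal per region from bedGraph tables.

    bedGraph columns: ``chrom start end value`` (value in rpm/bp).  The
    per-region score is the summed (chip - control) * covered-bp over the
    region, floored at 0.
    """

    def _sum_over(track, chrom, start, end):
        sub = track[(track["chrom"] == chrom) & (track["end"] > start) & (track["start"] < end)]
        if len(sub) == 0:
            return 0.0
        ov = np.minimum(sub["end"].to_numpy(), end) - np.maximum(sub["start"].to_numpy(), start)
        return float((ov * sub["value"].to_numpy()).sum())

    out = np.zeros(len(regions))
    for i, (_, r) in enumerate(regions.iterrows()):
        s = _sum_over(chip, r["chrom"], r["start"], r["end"])
        if control is not None:
            s -= _sum_over(control, r["chrom"], r["start"], r["end"])
        out[i] = max(s, 0.0)
    return out


def rank_and_cut(signals: np.ndarray) -> pd.DataFrame:
    """Slope-1 tangent cutoff on the scaled rank-signal curve.

    Signals are sorted ascending; rank is scaled to x in [0,1] and signal to
    y in [0,1].  The cutoff index is argmax(x - y) (the tangent point of a
    slope-1 line on a convex ascending curve), ties broken toward the
    rightmost index; entries strictly to the right are super-enhancers.
    Returns one row per input entry (original order preserved in
    ``input_index``).
    """
    signals = np.asarray(signals, dtype=float)
    if len(signals) < 3:
        raise ValueError("need at least 3 stitched enhancers to place a cutoff")
    if np.any(signals < 0):
        raise ValueError("signals must be >= 0 (floor background-subtracted values)")
    order = np.argsort(signals, kind="stable")
    s = signals[order]
    n = len(s)
    x = np.arange(n) / (n - 1)
    span = s[-1] - s[0]
    if span == 0:
        warnings.warn("all ranking signals equal; no super-enhancers called")
        y = np.zeros(n)
    else:
        y = (s - s[0]) / span
    diff = x - y
    cutoff_idx = int(n - 1 - np.argmax(diff[::-1]))  # rightmost argmax
    is_super = np.zeros(n, dtype=bool)
    is_super[cutoff_idx + 1 :] = span > 0
    df = pd.DataFrame({
        "input_index": order,
        "rank": np.arange(n),
        "signal": s,
        "scaled_x": x,
        "scaled_y": y,
        "is_super": is_super,
    })
    df.attrs["cutoff_index"] = cutoff_idx
    df.attrs["cutoff_signal"] = float(s[cutoff_idx])
    df.attrs["n_super"] = int(is_super.sum())
    return df


def call_broad_domains(
    peaks: pd.DataFrame,
    top_fraction: float = 0.05,
    min_width: int | None = None,
) -> pd.DataFrame:
    """Flag the widest peaks as broad domains.

    Default: rank by width descending (ties broken by genomic order) and
    flag the top ceil(``top_fraction`` * N).  If ``min_width`` is given the
    fixed-width definition (width > min_width) is used instead.
    """
    if len(peaks) == 0:
        raise ValueError("need at least one peak")
    out = peaks.copy().reset_index(drop=True)
    width = (out["end"] - out["start"]).to_numpy()
    out["width"] = width
    if min_width is not None:
        out["is_broad"] = width > min_width
        return out
    n_broad = math.ceil(top_fraction * len(out))
    order = sorted(
        range(len(out)),
        key=lambda i: (-width[i], out["chrom"].iloc[i], out["start"].iloc[i]),
    )
    flag = np.zeros(len(out), dtype=bool)
    flag[order[:n_broad]] = True
    out["is_broad"] = flag
    return out


def domain_hoci_overlap(domains: pd.DataFrame, hocis: pd.DataFrame, **kwargs) -> dict:
    """Overlap statistics between regulatory domains and HOCIs."""
    return overlap_report(domains, hocis, **kwargs)
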