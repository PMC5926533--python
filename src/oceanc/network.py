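"""HOCI-HOCI interaction networks and pair-category statistics.

A valid-pair end maps to a HOCI when its 5' coordinate lies inside the HOCI
interval.  Pairs bridging two different HOCIs become weighted edges of an
undirected network; pairs with both ends inside one HOCI count toward that
node's interaction total but form no edge.  Pairs are also categorised by
the regulatory classes of the HOCIs they touch (promoter-promoter,
enhancer-enhancer, promoter-enhancer, single-ended "related" categories,
and other), each with its cis-distance distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .genome import IntervalIndex

__all__ = [
    "assign_ends_to_hocis",
    "build_network",
    "categorize_pairs",
    "distance_summary",
    "interactions_per_peak",
    "exact_median",
]

PAIR_CATEGORIES = (
    "PROMOTER_HOCI",
    "ENHANCER_HOCI",
    "PROMOTER_ENHANCER_HOCI",
    "PROMOTER_HOCI_RELATED",
    "ENHANCER_HOCI_RELATED",
    "OTHER",
)


def _check_non_overlapping(hocis: pd.DataFrame) -> None:
    for chrom, sub in hocis.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
            raise ValueError(f"HOCIs overlap on {chrom}; end assignment ambiguous")


def assign_ends_to_hocis(valid: pd.DataFrame, hocis: pd.DataFrame) -> pd.DataFrame:
    """Add ``hoci1``/``hoci2`` columns: row index of the containing HOCI, -1 if none."""
    _check_non_overlapping(hocis)
    idx = IntervalIndex(hocis.reset_index(drop=True))
    out = valid.copy()
    for chrom_col, pos_col, dest in [("chrom1", "pos1", "hoci1"), ("chrom2", "pos2", "hoci2")]:
        assigned = np.full(len(out), -1, dtype=np.int64)
        for chrom, sub in out.groupby(chrom_col, sort=False):
            loc = out.index.get_indexer(sub.index)
            assigned[loc] = idx.assign_points(chrom, sub[pos_col].to_numpy())
        out[dest] = assigned
    return out


def build_network(
    valid: pd.DataFrame, hocis: pd.DataFrame, min_weight: int = 1
) -> nx.Graph:
    """Weighted undirected HOCI-HOCI contact graph.

    Nodes are HOCI row indices with interval and class attributes; edge
    weight is the number of valid pairs with one end in each HOCI.  Node
    attribute ``interaction_count`` is the number of valid pairs with at
    least one end in the node (same-HOCI pairs included).  Edges with weight
    below ``min_weight`` are dropped.
    """
    ends = assign_ends_to_hocis(valid, hocis)
    g = nx.Graph()
    hocis = hocis.reset_index(drop=True)
    for i, row in hocis.iterrows():
        g.add_node(
            int(i),
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            hoci_class=row.get("hoci_class", "NA"),
            interaction_count=0,
        )
    h1 = ends["hoci1"].to_numpy()
    h2 = ends["hoci2"].to_numpy()
    per_node = np.bincount(h1[h1 >= 0], minlength=len(hocis))
    per_node += np.bincount(h2[(h2 >= 0) & (h2 != h1)], minlength=len(hocis))
    for i, n in enumerate(per_node):
        g.nodes[int(i)]["interaction_count"] = int(n)
    bridging = (h1 >= 0) & (h2 >= 0) & (h1 != h2)
    if bridging.any():
        lo = np.minimum(h1[bridging], h2[bridging])
        hi = np.maximum(h1[bridging], h2[bridging])
        edges, weights = np.unique(np.stack([lo, hi]), axis=1, return_counts=True)
        for (a, b), w in zip(edges.T, weights):
            if w >= min_weight:
                g.add_edge(int(a), int(b), weight=int(w))
    return g


def categorize_pairs(valid: pd.DataFrame, hocis: pd.DataFrame) -> pd.DataFrame:
    """Per-pair regulatory category from the classes of touched HOCIs.

    Precedence: both ends in promoter HOCIs -> PROMOTER_HOCI; both in
    enhancer HOCIs -> ENHANCER_HOCI; one of each -> PROMOTER_ENHANCER_HOCI;
    else any promoter end -> PROMOTER_HOCI_RELATED; else any enhancer end ->
    ENHANCER_HOCI_RELATED; else OTHER.
    """
    if "hoci_class" not in hocis.columns:
        raise ValueError("hocis must carry a hoci_class column (run classify_hoci)")
    ends = assign_ends_to_hocis(valid, hocis)
    cls = hocis.reset_index(drop=True)["hoci_class"].to_numpy()
    lut = np.concatenate((cls, ["NONE"]))  # -1 wraps to the sentinel
    c1 = lut[ends["hoci1"].to_numpy()]
    c2 = lut[ends["hoci2"].to_numpy()]
    cat = np.full(len(ends), "OTHER", dtype=object)
    prom = (c1 == "PROMOTER") | (c2 == "PROMOTER")
    enh = (c1 == "ENHANCER") | (c2 == "ENHANCER")
    cat[prom] = "PROMOTER_HOCI_RELATED"
    cat[~prom & enh] = "ENHANCER_HOCI_RELATED"
    cat[(c1 == "PROMOTER") & (c2 == "PROMOTER")] = "PROMOTER_HOCI"
    cat[(c1 == "ENHANCER") & (c2 == "ENHANCER")] = "ENHANCER_HOCI"
    cat[prom & enh] = "PROMOTER_ENHANCER_HOCI"
    ends["pair_category"] = cat
    return ends


def exact_median(values: np.ndarray) -> float:
    """Median as the lower of the two middle values for even n."""
    v = np.sort(np.asarray(values))
    if len(v) == 0:
        raise ValueError("median of empty sample")
    return float(v[(len(v) - 1) // 2])


def distance_summary(categorized: pd.DataFrame) -> pd.DataFrame:
    """Per-category cis-distance medians and quartiles.

    Trans pairs (NaN distance) are excluded; categories without any cis
    pair are absent from the output rather than reported as zero.
    """
    rows = []
    for cat in PAIR_CATEGORIES:
        d = categorized.loc[
            (categorized["pair_category"] == cat) & categorized["cis_distance"].notna(),
            "cis_distance",
        ].to_numpy()
        if len(d) == 0:
            continue
        rows.append({
            "category": cat,
            "n": len(d),
            "median": exact_median(d),
            "q25": float(np.percentile(d, 25)),
            "q75": float(np.percentile(d, 75)),
        })
    return pd.DataFrame(rows, columns=["category", "n", "median", "q25", "q75"])


def interactions_per_peak(
    valid: pd.DataFrame,
    intervals: pd.DataFrame,
    other_valid: pd.DataFrame | None = None,
    test: str = "mannwhitney",
) -> dict:
    """Valid pairs touching each interval (>=1 end), with an optional
    two-sample comparison of per-interval counts against a second pair set
    over the same intervals."""
    if len(intervals) == 0:
        raise ValueError("empty interval set")

    def _counts(pairs):
        ends = assign_ends_to_hocis(pairs, intervals)
        h1 = ends["hoci1"].to_numpy()
        h2 = ends["hoci2"].to_numpy()
        counts = np.bincount(h1[h1 >= 0], minlength=len(intervals))
        counts += np.bincount(h2[(h2 >= 0) & (h2 != h1)], minlength=len(intervals))
        return counts

    counts = _counts(valid)
    out = {"counts": counts, "mean": float(counts.mean())}
    if other_valid is not None:
        other = _counts(other_valid)
        out["other_counts"] = other
        out["other_mean"] = float(other.mean())
        if test == "mannwhitney":
            res = stats.mannwhitneyu(counts, other, alternative="two-sided")
        elif test == "welch":
            res = stats.ttest_ind(counts, other, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        out["pvalue"] = float(res.pvalue)
    return out


def network_to_edgelist(g: nx.Graph) -> pd.DataFrame:
    """Deterministic edge-list export, nodes ordered by genomic coordinate."""
    rows = []
    for a, b, data in g.edges(data=True):
        na, nb = g.nodes[a], g.nodes[b]
        key_a = (na["chrom"], na["start"])
        key_b = (nb["chrom"], nb["start"])
        if key_b < key_a:
            a, b, na, nb = b, a, nb, na
        rows.append({
            "chrom1": na["chrom"], "start1": na["start"], "end1": na["end"],
            "chrom2": nb["chrom"], "start2": nb["start"], "end2": nb["end"],
            "node1": a, "node2": b, "weight": data["weight"],
        })
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                                     "end2", "node1", "node2", "weight"])
    return df.sort_values(["chrom1", "start1", "chrom2", "start2"]).reset_index(drop=True)
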