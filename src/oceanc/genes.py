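"""Gene typing against HOCIs and association with expression.

Genes fall in three types per condition: *hub* genes, whose promoter window
overlaps a HOCI; *interacting* genes, whose promoter is linked to a HOCI by
at least one valid ligation pair; and *dissociative* genes, whose promoter
does neither.  Typing is compared with RPKM expression within a condition
and across two conditions, where "promoter HOCI changed" genes (promoter
overlaps a HOCI in exactly one condition) are tested for larger expression
changes than unchanged genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, IntervalIndex
from .annotate import promoter_windows
from .network import assign_ends_to_hocis

__all__ = [
    "type_genes",
    "expression_by_type",
    "compare_conditions",
    "read_genes_bed",
    "read_expression",
]

GENE_TYPES = ("HUB", "INTERACTING", "DISSOCIATIVE")
EXPRESSED_RPKM = 0.5  # strictly greater than


def type_genes(
    genes: pd.DataFrame,
    hocis: pd.DataFrame,
    valid: pd.DataFrame,
    assembly: GenomeAssembly | None = None,
    promoter_up: int = 2000,
    promoter_mode: str = "upstream",
    min_link_pairs: int = 1,
) -> pd.Series:
    """Assign HUB / INTERACTING / DISSOCIATIVE per gene.

    HUB when the promoter window overlaps any HOCI; else INTERACTING when at
    least ``min_link_pairs`` valid pairs have one end in the promoter window
    and the other end inside any HOCI; else DISSOCIATIVE.
    """
    proms = promoter_windows(genes, assembly, promoter_up, promoter_mode)
    types = pd.Series("DISSOCIATIVE", index=genes["gene_id"].to_numpy(), name="gene_type")
    if len(hocis) == 0:
        return types
    idx_hoci = IntervalIndex(hocis.reset_index(drop=True))
    hub = np.zeros(len(proms), dtype=bool)
    for chrom, sub in proms.groupby("chrom", sort=False):
        loc = proms.index.get_indexer(sub.index)
        hub[loc] = idx_hoci.any_bulk(chrom, sub["start"].to_numpy(), sub["end"].to_numpy())
    types.iloc[np.nonzero(hub)[0]] = "HUB"

    # promoter<->HOCI link pairs: one end inside a promoter window, other in a HOCI
    ends = assign_ends_to_hocis(valid, hocis)
    link_counts = np.zeros(len(proms), dtype=np.int64)
    h1 = ends["hoci1"].to_numpy()
    h2 = ends["hoci2"].to_numpy()
    for pos_col, chrom_col, other_in_hoci in [
        ("pos1", "chrom1", h2 >= 0),
        ("pos2", "chrom2", h1 >= 0),
    ]:
        cand = ends[other_in_hoci]
        for chrom, sub in cand.groupby(chrom_col, sort=False):
            positions = np.sort(sub[pos_col].to_numpy())
            win = proms[proms["chrom"] == chrom]
            loc = proms.index.get_indexer(win.index)
            n_in = np.searchsorted(positions, win["end"].to_numpy()) - np.searchsorted(
                positions, win["start"].to_numpy()
            )
            link_counts[loc] += n_in
    linked = (link_counts >= min_link_pairs) & ~hub
    types.iloc[np.nonzero(linked)[0]] = "INTERACTING"
    return types


def expression_by_type(
    genes: pd.DataFrame,
    gene_types: pd.Series,
    expression: pd.Series,
    expressed_cutoff: float = EXPRESSED_RPKM,
) -> dict:
    """Expression distributions, proportions and one-sided tests per type.

    Returns medians and proportions per type (among all genes and among
    expressed genes, RPKM strictly above the cutoff), plus one-sided
    Mann-Whitney p-values for the expected ordering hub > interacting >
    dissociative.  Comparisons with a type below two genes are skipped.
    """
    rpkm = genes["gene_id"].map(expression).to_numpy(dtype=float)
    types = genes["gene_id"].map(gene_types).to_numpy()
    out = {"per_type": {}, "tests": {}, "n_genes": len(genes)}
    expressed = rpkm > expressed_cutoff
    out["n_expressed"] = int(expressed.sum())
    samples = {}
    for t in GENE_TYPES:
        mask = types == t
        samples[t] = rpkm[mask]
        out["per_type"][t] = {
            "n": int(mask.sum()),
            "median_rpkm": float(np.median(rpkm[mask])) if mask.any() else float("nan"),
            "prop_all": float(mask.mean()) if len(genes) else float("nan"),
            "prop_expressed": float(mask[expressed].mean()) if expressed.any() else float("nan"),
        }
    for hi, lo in [("HUB", "INTERACTING"), ("INTERACTING", "DISSOCIATIVE"),
                   ("HUB", "DISSOCIATIVE")]:
        if len(samples[hi]) < 2 or len(samples[lo]) < 2:
            out["tests"][f"{hi}>{lo}"] = None
            continue
        res = stats.mannwhitneyu(samples[hi], samples[lo], alternative="greater")
        out["tests"][f"{hi}>{lo}"] = float(res.pvalue)
    return out


def compare_conditions(
    genes: pd.DataFrame,
    types_a: pd.Series,
    types_b: pd.Series,
    expr_a: pd.Series,
    expr_b: pd.Series,
    hub_a: pd.Series | None = None,
    hub_b: pd.Series | None = None,
    epsilon: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Cross-condition type changes vs. expression changes.

    Per-gene output: type in each condition, change category (``same-type``,
    ``hub-dissociative`` for the extreme switch in either direction,
    ``other-change``), ``promoter_hoci_changed`` (promoter overlaps a HOCI
    in exactly one condition — by default inferred from HUB type, or from
    explicit boolean Series), and ``log2fc`` = log2((A+eps)/(B+eps)).
    The summary tests whether changed genes move more than unchanged ones
    among down- and up-regulated genes separately (one-sided Mann-Whitney).
    Genes missing a type or expression value in either condition are
    excluded and counted in the summary.
    """
    gid = genes["gene_id"]
    df = pd.DataFrame({"gene_id": gid.to_numpy()})
    df["type_a"] = gid.map(types_a).to_numpy()
    df["type_b"] = gid.map(types_b).to_numpy()
    df["rpkm_a"] = gid.map(expr_a).to_numpy(dtype=float)
    df["rpkm_b"] = gid.map(expr_b).to_numpy(dtype=float)
    complete = df[["type_a", "type_b", "rpkm_a", "rpkm_b"]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df[complete].reset_index(drop=True)

    same = df["type_a"] == df["type_b"]
    extreme = ((df["type_a"] == "HUB") & (df["type_b"] == "DISSOCIATIVE")) | (
        (df["type_a"] == "DISSOCIATIVE") & (df["type_b"] == "HUB")
    )
    cat = np.where(same, "same-type", np.where(extreme, "hub-dissociative", "other-change"))
    df["change_category"] = cat

    if hub_a is None:
        hub_a = types_a == "HUB"
    if hub_b is None:
        hub_b = types_b == "HUB"
    pa = df["gene_id"].map(hub_a).astype(bool)
    pb = df["gene_id"].map(hub_b).astype(bool)
    df["promoter_hoci_changed"] = (pa ^ pb).to_numpy()

    df["log2fc"] = np.log2((df["rpkm_a"] + epsilon) / (df["rpkm_b"] + epsilon))

    summary = {"n_genes": len(df), "n_dropped": n_dropped,
               "category_counts": df["change_category"].value_counts().to_dict(),
               "n_promoter_hoci_changed": int(df["promoter_hoci_changed"].sum())}
    changed = df[df["promoter_hoci_changed"]]
    unchanged = df[~df["promoter_hoci_changed"]]
    for direction, mask_c, mask_u in [
        ("down", changed["log2fc"] > 0, unchanged["log2fc"] > 0),
        ("up", changed["log2fc"] < 0, unchanged["log2fc"] < 0),
    ]:
        c = changed.loc[mask_c, "log2fc"].abs().to_numpy()
        u = unchanged.loc[mask_u, "log2fc"].abs().to_numpy()
        if len(c) >= 2 and len(u) >= 2:
            p = float(stats.mannwhitneyu(c, u, alternative="greater").pvalue)
        else:
            p = None
        summary[f"{direction}_changed_vs_unchanged_p"] = p
        summary[f"{direction}_changed_median_abs_log2fc"] = (
            float(np.median(c)) if len(c) else None
        )
        summary[f"{direction}_unchanged_median_abs_log2fc"] = (
            float(np.median(u)) if len(u) else None
        )
    return df, summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> pd.DataFrame:
    """Read genes from BED6; the TSS is the strand-dependent 5' end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return pd.DataFrame({
        "gene_id": df["name"], "chrom": df["chrom"], "strand": df["strand"],
        "tss": tss.astype(np.int64), "start": df["start"], "end": df["end"],
    })


def read_expression(path) -> pd.Series:
    """Read a two-column TSV (gene_id, RPKM) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("expression table needs gene_id and RPKM columns")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0], name="rpkm")
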