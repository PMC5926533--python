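"""Regulatory classification of HOCIs and overlap/occupancy statistics.

A HOCI is a *promoter* HOCI when it overlaps both an H3K4me3 ChIP-seq peak
and a gene promoter window (2 kb upstream of the TSS through the TSS,
strand-aware); otherwise it is an *enhancer* HOCI when it overlaps both
H3K4me1 and H3K27ac peaks; everything else is *other*.  Promoter takes
precedence over enhancer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, IntervalIndex

__all__ = [
    "promoter_windows",
    "classify_hoci",
    "count_binding_proteins",
    "overlap_report",
]

HOCI_CLASSES = ("PROMOTER", "ENHANCER", "OTHER")


def promoter_windows(
    genes: pd.DataFrame,
    assembly: GenomeAssembly | None = None,
    upstream: int = 2000,
    mode: str = "upstream",
) -> pd.DataFrame:
    """Strand-aware promoter windows around each gene's TSS.

    ``mode='upstream'`` (default): 2 kb upstream of the TSS through the TSS
    itself; ``mode='symmetric'``: TSS +/- ``upstream``.  Windows are clipped
    to the chromosome.  Requires ``gene_id``, ``chrom``, ``strand``, ``tss``
    columns; genes without strand are an error (the window is undefined).
    """
    if genes["strand"].isin(["+", "-"]).sum() != len(genes):
        raise ValueError("all genes need strand '+' or '-' to define promoters")
    tss = genes["tss"].to_numpy()
    plus = genes["strand"].to_numpy() == "+"
    if mode == "upstream":
        start = np.where(plus, tss - upstream, tss)
        end = np.where(plus, tss + 1, tss + upstream + 1)
    elif mode == "symmetric":
        start, end = tss - upstream, tss + upstream + 1
    else:
        raise ValueError(f"unknown promoter mode {mode!r}")
    start = np.maximum(start, 0)
    if assembly is not None:
        lens = genes["chrom"].map(assembly.lengths).to_numpy()
        end = np.minimum(end, lens)
    return pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": start.astype(np.int64),
        "end": end.astype(np.int64),
        "gene_id": genes["gene_id"].to_numpy(),
    })


def classify_hoci(
    hocis: pd.DataFrame,
    h3k4me3: pd.DataFrame,
    h3k4me1: pd.DataFrame,
    h3k27ac: pd.DataFrame,
    genes: pd.DataFrame,
    assembly: GenomeAssembly | None = None,
    promoter_up: int = 2000,
    promoter_mode: str = "upstream",
) -> pd.DataFrame:
    """Attach a ``hoci_class`` column (PROMOTER / ENHANCER / OTHER)."""
    proms = promoter_windows(genes, assembly, promoter_up, promoter_mode)
    idx_me3 = IntervalIndex(h3k4me3)
    idx_me1 = IntervalIndex(h3k4me1)
    idx_ac = IntervalIndex(h3k27ac)
    idx_prom = IntervalIndex(proms)
    out = hocis.copy()
    classes = np.full(len(out), "OTHER", dtype=object)
    for i, (_, row) in enumerate(out.iterrows()):
        c, s, e = row["chrom"], row["start"], row["end"]
        if idx_me3.any(c, s, e) and idx_prom.any(c, s, e):
            classes[i] = "PROMOTER"
        elif idx_me1.any(c, s, e) and idx_ac.any(c, s, e):
            classes[i] = "ENHANCER"
    out["hoci_class"] = classes
    return out


def count_binding_proteins(
    hocis: pd.DataFrame, factor_peaks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Distinct DNA-binding factors (>=1 bp peak overlap) per HOCI.

    Returns the HOCI table with one boolean column per factor plus an
    ``n_factors`` count; the mean of ``n_factors`` is the headline
    "proteins per hub" statistic.
    """
    if len(factor_peaks) == 0:
        raise ValueError("need at least one factor peak set")
    out = hocis.copy()
    total = np.zeros(len(out), dtype=np.int64)
    for name, peaks in factor_peaks.items():
        idx = IntervalIndex(peaks)
        hit = np.zeros(len(out), dtype=bool)
        for chrom, sub in out.groupby("chrom", sort=False):
            loc = out.index.get_indexer(sub.index)
            hit[loc] = idx.any_bulk(chrom, sub["start"].to_numpy(), sub["end"].to_numpy())
        out[f"factor_{name}"] = hit
        total += hit
    out["n_factors"] = total
    return out


def overlap_report(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    assembly: GenomeAssembly | None = None,
    bin_bp: int = 1000,
) -> dict:
    """Element-level overlap between two interval sets, with a Fisher test.

    An element of A "overlaps" if it shares >=1 bp with any element of B
    (and vice versa).  When an assembly is supplied, a 2x2 Fisher exact test
    is computed over genome bins labeled by membership in A and in B,
    testing association against a genome-background null.
    """
    idx_a = IntervalIndex(set_a)
    idx_b = IntervalIndex(set_b)

    def _hits(df, idx):
        hit = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            loc = df.index.get_indexer(sub.index)
            hit[loc] = idx.any_bulk(chrom, sub["start"].to_numpy(), sub["end"].to_numpy())
        return hit

    a_hit = _hits(set_a, idx_b)
    b_hit = _hits(set_b, idx_a)
    report = {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_a_overlap": int(a_hit.sum()),
        "n_b_overlap": int(b_hit.sum()),
        "frac_a_overlap": float(a_hit.mean()) if len(set_a) else float("nan"),
        "frac_b_overlap": float(b_hit.mean()) if len(set_b) else float("nan"),
    }
    if assembly is not None:
        in_a = in_b = 0
        both = 0
        n_bins = 0
        for chrom in assembly.chrom_names:
            nb = -(-assembly.length(chrom) // bin_bp)
            starts = np.arange(nb, dtype=np.int64) * bin_bp
            ends = np.minimum(starts + bin_bp, assembly.length(chrom))
            ha = idx_a.any_bulk(chrom, starts, ends)
            hb = idx_b.any_bulk(chrom, starts, ends)
            in_a += int(ha.sum())
            in_b += int(hb.sum())
            both += int((ha & hb).sum())
            n_bins += nb
        table = [
            [both, in_a - both],
            [in_b - both, n_bins - in_a - in_b + both],
        ]
        report["fisher_table"] = table
        report["fisher_p"] = float(stats.fisher_exact(table, alternative="greater")[1])
    return report
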