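"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the data model the hub analysis assumes: a random
MboI-digestible genome; ligation read pairs with a power-law distance-decay
background; planted open-chromatin hubs wired into promoter-promoter,
enhancer-enhancer and promoter-enhancer links with configured distance
scales; ligation artifacts (dangling ends, self-circles, same-strand
pairs, short-range products, low-MAPQ pairs) at configured fractions;
histone peaks co-located with hubs; genes of three planted interaction
types with log-normal expression ordered by type; and alternating A/B
compartment blocks that bias background contacts.

Hubs are laid out in four-hub modules (two promoter hubs, two enhancer
hubs) carrying exactly one link of each category, whose genomic separations
are stratified quantiles of a log-normal around the configured median — so
the realized per-category distance median sits at the configured value by
construction.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, digest, write_fasta
from .matrix import ContactMatrix

__all__ = [
    "SimulationConfig",
    "SimBundle",
    "simulate",
    "two_condition_bundle",
    "write_bundle",
    "planted_bias_matrix",
    "checkerboard_matrix",
    "tad_block_matrix",
]


@dataclass
class SimulationConfig:
    seed: int
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    # hubs: modules of 2 promoter + 2 enhancer hubs, plus standalone "other" hubs
    n_modules_per_chrom: int = 4
    n_other_hubs_per_chrom: int = 4
    hub_width_median: float = 1000.0
    hub_width_sigma: float = 0.3
    # pairs
    n_pairs: int = 200_000
    frac_dangling: float = 0.10
    frac_self_circle: float = 0.10
    frac_same_strand: float = 0.10
    frac_too_close: float = 0.05
    frac_low_mapq: float = 0.05
    # allocation of non-artifact pairs
    frac_background: float = 0.55
    frac_hub_hub: float = 0.30
    frac_hub_background: float = 0.12
    frac_promoter_link: float = 0.03
    trans_fraction: float = 0.05  # of background pairs
    # distance decay P(d) ~ d^-alpha on [d_min, d_max]
    decay_alpha: float = 1.0
    d_min: int = 2000
    d_max: int = 2_000_000
    # planted link distance medians (log-normal, stratified per category)
    pp_median: float = 44_000.0
    ee_median: float = 13_000.0
    pe_median: float = 117_000.0
    link_distance_sigma: float = 0.15
    # genes
    n_genes: int = 500
    frac_hub_genes: float = 0.18
    frac_interacting_genes: float = 0.32
    promoter_up: int = 2000
    # expression (log-normal medians per planted type, RPKM)
    rpkm_median_hub: float = 20.0
    rpkm_median_interacting: float = 5.0
    rpkm_median_dissociative: float = 0.2
    rpkm_sigma: float = 1.0
    # histone peaks
    peak_margin: int = 200
    n_noise_peaks_per_mark: int = 25
    noise_peak_width: int = 800
    # compartments
    compartment_block: int = 500_000
    hub_in_A_prob: float = 0.8
    compartment_bias: float = 0.8  # preference for same-label background ends
    # two-condition comparison
    n_hub_loss_genes: int = 50
    hub_loss_fold: float = 4.0
    expression_noise_sigma: float = 0.2

    def validate(self) -> None:
        fracs = [self.frac_dangling, self.frac_self_circle, self.frac_same_strand,
                 self.frac_too_close, self.frac_low_mapq]
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("artifact fractions must lie in [0,1] and sum below 1")
        alloc = [self.frac_background, self.frac_hub_hub, self.frac_hub_background,
                 self.frac_promoter_link]
        if abs(sum(alloc) - 1) > 1e-9:
            raise ValueError("non-artifact allocation fractions must sum to 1")
        if self.frac_hub_genes + self.frac_interacting_genes > 1:
            raise ValueError("gene type fractions exceed 1")
        if not self.d_min < self.d_max <= self.chrom_length:
            raise ValueError("need d_min < d_max <= chrom_length")


@dataclass
class SimBundle:
    config: SimulationConfig
    assembly: GenomeAssembly
    pairs: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.Series
    h3k4me3: pd.DataFrame
    h3k4me1: pd.DataFrame
    h3k27ac: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# layout: genome, hubs, links, genes, compartments
# ---------------------------------------------------------------------------

def _random_genome(cfg: SimulationConfig, rng) -> GenomeAssembly:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for i in range(cfg.n_chroms):
        draw = rng.integers(0, 4, size=cfg.chrom_length)
        seqs[f"chr{i + 1}"] = bases[draw].tobytes().decode("ascii")
    return GenomeAssembly({c: len(s) for c, s in seqs.items()}, seqs)


def _lognormal_quantiles(median: float, sigma: float, n: int) -> np.ndarray:
    """Stratified log-normal draws: quantiles (i+0.5)/n, shuffle-free."""
    from scipy.stats import norm

    q = (np.arange(n) + 0.5) / n
    return median * np.exp(sigma * norm.ppf(q))


def _compartment_labels(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Alternating A/B blocks per chromosome (A first)."""
    n_blocks = -(-cfg.chrom_length // cfg.compartment_block)
    labels = np.where(np.arange(n_blocks) % 2 == 0, "A", "B")
    return {f"chr{i + 1}": labels.copy() for i in range(cfg.n_chroms)}


def _block_of(pos: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return np.asarray(pos) // cfg.compartment_block


def _place_hubs(cfg: SimulationConfig, rng, comp: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out hub modules and standalone hubs; returns (hubs, links)."""
    n_modules = cfg.n_chroms * cfg.n_modules_per_chrom
    d_pp = _lognormal_quantiles(cfg.pp_median, cfg.link_distance_sigma, n_modules)
    d_ee = _lognormal_quantiles(cfg.ee_median, cfg.link_distance_sigma, n_modules)
    d_pe = _lognormal_quantiles(cfg.pe_median, cfg.link_distance_sigma, n_modules)
    for d in (d_pp, d_ee, d_pe):
        rng.shuffle(d)

    hubs, links = [], []
    occupied: dict[str, list[tuple[int, int]]] = {f"chr{i+1}": [] for i in range(cfg.n_chroms)}

    def _free(chrom, start, end, margin=10_000):
        return all(end + margin <= s or e + margin <= start for s, e in occupied[chrom])

    def _width():
        return int(cfg.hub_width_median * np.exp(cfg.hub_width_sigma * rng.standard_normal()))

    def _pick_base(chrom, span):
        lab = "A" if rng.random() < cfg.hub_in_A_prob else "B"
        blocks = np.nonzero(comp[chrom] == lab)[0]
        for _ in range(200):
            blk = int(rng.choice(blocks))
            lo = blk * cfg.compartment_block
            hi = min(lo + cfg.compartment_block, cfg.chrom_length) - span
            if hi <= lo:
                continue
            base = int(rng.integers(lo, hi))
            if _free(chrom, base, base + span):
                return base
        raise RuntimeError("could not place hub module; genome too crowded")

    mod_idx = 0
    hub_id = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        for _ in range(cfg.n_modules_per_chrom):
            dpp, dee, dpe = d_pp[mod_idx], d_ee[mod_idx], d_pe[mod_idx]
            mod_idx += 1
            # offsets: P1 at 0, P2 at dpp, E1 at dpe, E2 at dpe+dee
            span = int(dpe + dee + 4000)
            base = _pick_base(chrom, span)
            specs = [("PROMOTER", 0.0), ("PROMOTER", dpp), ("ENHANCER", dpe),
                     ("ENHANCER", dpe + dee)]
            ids = []
            for klass, off in specs:
                w = _width()
                start = base + int(off) - w // 2
                start = max(start, 0)
                hubs.append({"hub_id": hub_id, "chrom": chrom, "start": start,
                             "end": start + w, "hub_class": klass})
                ids.append(hub_id)
                hub_id += 1
            occupied[chrom].append((base - 2000, base + span + 2000))
            p1, p2, e1, e2 = ids
            links.append({"hub_a": p1, "hub_b": p2, "category": "PP", "distance": float(dpp)})
            links.append({"hub_a": e1, "hub_b": e2, "category": "EE", "distance": float(dee)})
            links.append({"hub_a": p1, "hub_b": e1, "category": "PE", "distance": float(dpe)})
        for _ in range(cfg.n_other_hubs_per_chrom):
            w = _width()
            base = _pick_base(chrom, w)
            hubs.append({"hub_id": hub_id, "chrom": chrom, "start": base,
                         "end": base + w, "hub_class": "OTHER"})
            hub_id += 1
            occupied[chrom].append((base - 2000, base + w + 2000))
    hubs_df = pd.DataFrame(hubs, columns=["hub_id", "chrom", "start", "end",
                                          "hub_class"])
    links_df = pd.DataFrame(links, columns=["hub_a", "hub_b", "category", "distance"])
    if len(links_df):
        # hub midpoints define realized link distances (ends jitter within hubs)
        mid = (hubs_df["start"] + hubs_df["end"]) // 2
        links_df["distance"] = np.abs(
            mid.to_numpy()[links_df["hub_a"]] - mid.to_numpy()[links_df["hub_b"]]
        ).astype(float)
    return hubs_df, links_df


def _place_genes(cfg: SimulationConfig, rng, hubs: pd.DataFrame) -> pd.DataFrame:
    n_hub = int(round(cfg.frac_hub_genes * cfg.n_genes))
    n_int = int(round(cfg.frac_interacting_genes * cfg.n_genes))
    n_dis = cfg.n_genes - n_hub - n_int
    genes = []

    prom_hubs = hubs[hubs["hub_class"] == "PROMOTER"].reset_index(drop=True)
    if len(prom_hubs) == 0 and n_hub > 0:
        raise ValueError("no promoter hubs available for hub genes")
    for k in range(n_hub):
        h = prom_hubs.iloc[k % len(prom_hubs)]
        slot = k // len(prom_hubs)
        tss = int(h["end"]) + 100 + 150 * slot  # promoter window reaches into the hub
        genes.append({"gene_id": f"gene_hub_{k}", "chrom": h["chrom"], "strand": "+",
                      "tss": tss, "planted_type": "HUB", "host_hub": int(h["hub_id"])})

    # quiet zones for interacting/dissociative genes: far from hubs and
    # from each other (promoter windows must not overlap)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for _, h in hubs.iterrows():
        occupied.setdefault(h["chrom"], []).append((h["start"] - 6000, h["end"] + 6000))
    for g in genes:
        occupied.setdefault(g["chrom"], []).append((g["tss"] - 2500, g["tss"] + 2500))

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    def _quiet_tss(chrom):
        for _ in range(500):
            tss = int(rng.integers(cfg.promoter_up + 10, cfg.chrom_length - 3000))
            lo, hi = tss - cfg.promoter_up - 500, tss + 2500
            if all(hi <= s or e <= lo for s, e in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((lo, hi))
                return tss
        raise RuntimeError("could not place gene promoter in a quiet zone")

    for k in range(n_int):
        chrom = chroms[k % len(chroms)]
        genes.append({"gene_id": f"gene_int_{k}", "chrom": chrom, "strand": "+",
                      "tss": _quiet_tss(chrom), "planted_type": "INTERACTING",
                      "host_hub": -1})
    for k in range(n_dis):
        chrom = chroms[k % len(chroms)]
        genes.append({"gene_id": f"gene_dis_{k}", "chrom": chrom, "strand": "+",
                      "tss": _quiet_tss(chrom), "planted_type": "DISSOCIATIVE",
                      "host_hub": -1})
    df = pd.DataFrame(genes)
    df["start"] = df["tss"]
    df["end"] = df["tss"] + 2000
    return df


def _histone_peaks(cfg: SimulationConfig, rng, hubs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    marks = {"h3k4me3": [], "h3k4me1": [], "h3k27ac": []}
    for _, h in hubs.iterrows():
        iv = {"chrom": h["chrom"], "start": max(0, h["start"] - cfg.peak_margin),
              "end": h["end"] + cfg.peak_margin}
        if h["hub_class"] == "PROMOTER":
            marks["h3k4me3"].append(iv)
        elif h["hub_class"] == "ENHANCER":
            marks["h3k4me1"].append(iv)
            marks["h3k27ac"].append(dict(iv))
    for name in marks:
        for _ in range(cfg.n_noise_peaks_per_mark):
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            start = int(rng.integers(0, cfg.chrom_length - cfg.noise_peak_width))
            marks[name].append({"chrom": chrom, "start": start,
                                "end": start + cfg.noise_peak_width})
    return {
        name: pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        for name, rows in marks.items()
    }


# ---------------------------------------------------------------------------
# pair generation
# ---------------------------------------------------------------------------

def _sample_decay(cfg: SimulationConfig, rng, n: int) -> np.ndarray:
    """Inverse-CDF draws from P(d) ~ d^-alpha truncated to [d_min, d_max]."""
    u = rng.random(n)
    a, lo, hi = cfg.decay_alpha, cfg.d_min, cfg.d_max
    if abs(a - 1.0) < 1e-12:
        return (lo * np.exp(u * np.log(hi / lo))).astype(np.int64)
    p = 1.0 - a
    return ((lo**p + u * (hi**p - lo**p)) ** (1 / p)).astype(np.int64)


class _Exclusion:
    """Per-chromosome forbidden windows with vectorised membership tests."""

    def __init__(self, windows: dict[str, np.ndarray]):
        self._bounds = {}
        for chrom, arr in windows.items():
            if len(arr) == 0:
                continue
            arr = arr[np.argsort(arr[:, 0])]
            self._bounds[chrom] = (arr[:, 0], arr[:, 1])

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        if chrom not in self._bounds:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = self._bounds[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] < ends[idx[ok]]
        return out


def _background_pairs(cfg, rng, chrom, n, excl, labels):
    """Distance-decay background pairs with compartment preference.

    The distance is drawn first and the left end placed uniformly in
    [0, L-d], so the distance law is exact; the left end is re-drawn (same
    distance) when an end hits an excluded window, and among candidate
    placements the one keeping both ends in the same compartment block
    label is preferred with probability ``compartment_bias``.
    """
    d = _sample_decay(cfg, rng, n)
    L = cfg.chrom_length
    pos1 = np.empty(n, dtype=np.int64)
    pos2 = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    lab = labels[chrom]
    prefer = rng.random(n) < cfg.compartment_bias
    for _ in range(50):
        if len(todo) == 0:
            break
        cand1 = rng.integers(0, L - d[todo])
        cand2 = cand1 + d[todo]
        bad = excl.contains(chrom, cand1) | excl.contains(chrom, cand2)
        same = lab[_block_of(cand1, cfg)] == lab[_block_of(cand2, cfg)]
        reject = bad | (prefer[todo] & ~same & (rng.random(len(todo)) < 0.7))
        pos1[todo[~reject]] = cand1[~reject]
        pos2[todo[~reject]] = cand2[~reject]
        todo = todo[reject]
    if len(todo):  # give up on preference, keep exclusion only
        for _ in range(200):
            if len(todo) == 0:
                break
            cand1 = rng.integers(0, L - d[todo])
            cand2 = cand1 + d[todo]
            bad = excl.contains(chrom, cand1) | excl.contains(chrom, cand2)
            pos1[todo[~bad]] = cand1[~bad]
            pos2[todo[~bad]] = cand2[~bad]
            todo = todo[bad]
    if len(todo):
        raise RuntimeError("background sampling failed; exclusion zones too dense")
    return pos1, pos2, d


def _generate_pairs(
    cfg: SimulationConfig,
    rng,
    assembly: GenomeAssembly,
    hubs: pd.DataFrame,
    links: pd.DataFrame,
    genes: pd.DataFrame,
    comp_labels: dict[str, np.ndarray],
    removed_hubs: set[int] = frozenset(),
    extra_excluded: list[tuple[str, int, int]] = (),
) -> pd.DataFrame:
    fragmap = digest(assembly, "GATC")
    live_hubs = hubs[~hubs["hub_id"].isin(removed_hubs)].reset_index(drop=True)
    live_links = links[
        ~links["hub_a"].isin(removed_hubs) & ~links["hub_b"].isin(removed_hubs)
    ].reset_index(drop=True)
    hub_by_id = hubs.set_index("hub_id")

    # exclusion zones: dissociative-gene promoters (and, across conditions,
    # the promoters of genes whose hub was removed) receive no stray ends
    windows: dict[str, list] = {}
    dis = genes[genes["planted_type"] == "DISSOCIATIVE"]
    for _, g in dis.iterrows():
        windows.setdefault(g["chrom"], []).append(
            (g["tss"] - cfg.promoter_up - 1, g["tss"] + 2)
        )
    for chrom, s, e in extra_excluded:
        windows.setdefault(chrom, []).append((s, e))
    excl = _Exclusion({c: np.array(w) for c, w in windows.items()})

    n_art = {
        "DANGLING_END": int(cfg.frac_dangling * cfg.n_pairs),
        "SELF_CIRCLE": int(cfg.frac_self_circle * cfg.n_pairs),
        "SAME_STRAND_DUMPED": int(cfg.frac_same_strand * cfg.n_pairs),
        "TOO_CLOSE": int(cfg.frac_too_close * cfg.n_pairs),
        "LOW_MAPQ": int(cfg.frac_low_mapq * cfg.n_pairs),
    }
    n_valid = cfg.n_pairs - sum(n_art.values())
    n_hh = int(cfg.frac_hub_hub * n_valid)
    n_hb = int(cfg.frac_hub_background * n_valid)
    n_pl = int(cfg.frac_promoter_link * n_valid)
    n_bg = n_valid - n_hh - n_hb - n_pl

    chroms = assembly.chrom_names
    frames = []

    def _rand_strands(n):
        return np.where(rng.random(n) < 0.5, "+", "-")

    def _frame(c1, p1, c2, p2, prov, n, mapq=30):
        return pd.DataFrame({
            "chrom1": c1, "pos1": p1, "strand1": _rand_strands(n),
            "chrom2": c2, "pos2": p2, "strand2": _rand_strands(n),
            "mapq1": mapq, "mapq2": mapq, "provenance": prov,
        })

    # --- background (cis + trans) ---
    n_trans = int(cfg.trans_fraction * n_bg) if len(chroms) > 1 else 0
    n_cis_bg = n_bg - n_trans
    per_chrom = np.full(len(chroms), n_cis_bg // len(chroms))
    per_chrom[: n_cis_bg % len(chroms)] += 1
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        p1, p2, _ = _background_pairs(cfg, rng, chrom, int(n_c), excl, comp_labels)
        frames.append(_frame(chrom, p1, chrom, p2, "background", int(n_c)))
    if n_trans:
        ci = rng.integers(0, len(chroms), size=(n_trans, 2))
        ci[:, 1] = (ci[:, 0] + 1 + ci[:, 1] % (len(chroms) - 1)) % len(chroms)
        p1 = rng.integers(0, cfg.chrom_length, n_trans)
        p2 = rng.integers(0, cfg.chrom_length, n_trans)
        frames.append(_frame(np.array(chroms)[ci[:, 0]], p1,
                             np.array(chroms)[ci[:, 1]], p2,
                             "background_trans", n_trans))

    # --- hub-hub link pairs (equal split across live links) ---
    if n_hh and len(live_links):
        alloc = np.full(len(live_links), n_hh // len(live_links))
        alloc[: n_hh % len(live_links)] += 1
        for (_, lk), n_l in zip(live_links.iterrows(), alloc):
            if n_l == 0:
                continue
            ha = hub_by_id.loc[lk["hub_a"]]
            hb = hub_by_id.loc[lk["hub_b"]]
            p1 = rng.integers(ha["start"], ha["end"], n_l)
            p2 = rng.integers(hb["start"], hb["end"], n_l)
            frames.append(_frame(ha["chrom"], p1, hb["chrom"], p2,
                                 f"hub_link_{lk['category']}", int(n_l)))

    # --- hub-background pairs ---
    if n_hb and len(live_hubs):
        pick = rng.integers(0, len(live_hubs), n_hb)
        for hi in np.unique(pick):
            h = live_hubs.iloc[hi]
            n_h = int((pick == hi).sum())
            p1 = rng.integers(h["start"], h["end"], n_h)
            d = _sample_decay(cfg, rng, n_h)
            sign = np.where(rng.random(n_h) < 0.5, 1, -1)
            p2 = p1 + sign * d
            flip = (p2 < 0) | (p2 >= cfg.chrom_length)
            p2[flip] = p1[flip] - sign[flip] * d[flip]
            p2 = np.clip(p2, 0, cfg.chrom_length - 1)
            bad = excl.contains(h["chrom"], p2)
            for _ in range(50):
                if not bad.any():
                    break
                p2[bad] = rng.integers(0, cfg.chrom_length, int(bad.sum()))
                bad = excl.contains(h["chrom"], p2)
            frames.append(_frame(h["chrom"], p1, h["chrom"], p2, "hub_background", n_h))

    # --- promoter->hub link pairs for interacting genes ---
    inter = genes[genes["planted_type"] == "INTERACTING"].reset_index(drop=True)
    if n_pl and len(inter) and len(live_hubs):
        alloc = np.full(len(inter), n_pl // len(inter))
        alloc[: n_pl % len(inter)] += 1
        for (_, g), n_g in zip(inter.iterrows(), alloc):
            if n_g == 0:
                continue
            cands = live_hubs[live_hubs["chrom"] == g["chrom"]]
            if len(cands) == 0:
                continue
            h = cands.iloc[int(rng.integers(0, len(cands)))]
            p1 = rng.integers(max(g["tss"] - cfg.promoter_up, 0), g["tss"] + 1, n_g)
            p2 = rng.integers(h["start"], h["end"], n_g)
            frames.append(_frame(g["chrom"], p1, g["chrom"], p2, "promoter_link", int(n_g)))

    # --- artifacts on real restriction fragments ---
    for prov, n_a in n_art.items():
        if n_a == 0:
            continue
        chrom_pick = np.array(chroms)[rng.integers(0, len(chroms), n_a)]
        rows = {"chrom1": [], "pos1": [], "strand1": [], "chrom2": [], "pos2": [],
                "strand2": [], "mapq1": [], "mapq2": []}
        for chrom in chroms:
            n_c = int((chrom_pick == chrom).sum())
            if n_c == 0:
                continue
            starts, ends = fragmap.fragments(chrom)
            widths = ends - starts
            eligible = np.nonzero(widths >= 40)[0]
            if prov == "LOW_MAPQ":
                p1 = rng.integers(0, cfg.chrom_length, n_c)
                p2 = rng.integers(0, cfg.chrom_length, n_c)
                s1, s2 = _rand_strands(n_c), _rand_strands(n_c)
                mq = 0
            elif prov == "TOO_CLOSE":
                fi = eligible[rng.integers(0, len(eligible) - 1, n_c)]
                fj = fi + 1
                # adjacent fragments; re-draw until midpoints are within 1 kb
                mid_i = (starts[fi] + ends[fi]) / 2
                mid_j = (starts[fj] + ends[fj]) / 2
                bad = np.abs(mid_j - mid_i) >= 1000
                for _ in range(100):
                    if not bad.any():
                        break
                    redraw = eligible[rng.integers(0, len(eligible) - 1, int(bad.sum()))]
                    fi[bad] = redraw
                    fj[bad] = redraw + 1
                    mid_i = (starts[fi] + ends[fi]) / 2
                    mid_j = (starts[fj] + ends[fj]) / 2
                    bad = np.abs(mid_j - mid_i) >= 1000
                fi, fj = fi[~bad], fj[~bad]
                n_c = len(fi)
                p1 = starts[fi] + rng.integers(0, 1_000_000, n_c) % (ends[fi] - starts[fi])
                p2 = starts[fj] + rng.integers(0, 1_000_000, n_c) % (ends[fj] - starts[fj])
                s1, s2 = _rand_strands(n_c), _rand_strands(n_c)
                mq = 30
            else:
                fi = eligible[rng.integers(0, len(eligible), n_c)]
                w = ends[fi] - starts[fi]
                off1 = rng.integers(0, 1_000_000, n_c) % w
                off2 = rng.integers(0, 1_000_000, n_c) % w
                lo = starts[fi] + np.minimum(off1, off2)
                hi = starts[fi] + np.maximum(off1, off2)
                hi = np.where(hi == lo, np.minimum(hi + 1, ends[fi] - 1), hi)
                p1, p2 = lo, hi
                if prov == "DANGLING_END":
                    s1, s2 = np.full(n_c, "+"), np.full(n_c, "-")
                elif prov == "SELF_CIRCLE":
                    s1, s2 = np.full(n_c, "-"), np.full(n_c, "+")
                else:  # SAME_STRAND_DUMPED
                    s = _rand_strands(n_c)
                    s1, s2 = s, s.copy()
                mq = 30
            rows["chrom1"].extend([chrom] * n_c)
            rows["pos1"].extend(p1.tolist())
            rows["strand1"].extend(np.asarray(s1).tolist())
            rows["chrom2"].extend([chrom] * n_c)
            rows["pos2"].extend(p2.tolist())
            rows["strand2"].extend(np.asarray(s2).tolist())
            rows["mapq1"].extend([mq] * n_c)
            rows["mapq2"].extend([30] * n_c)
        af = pd.DataFrame(rows)
        af["provenance"] = prov
        frames.append(af)

    pairs = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(pairs))
    pairs = pairs.iloc[order].reset_index(drop=True)
    pairs.insert(0, "pair_id", [f"p{i}" for i in range(len(pairs))])
    return pairs


def _expression(cfg: SimulationConfig, rng, genes: pd.DataFrame) -> pd.Series:
    medians = {"HUB": cfg.rpkm_median_hub, "INTERACTING": cfg.rpkm_median_interacting,
               "DISSOCIATIVE": cfg.rpkm_median_dissociative}
    mu = np.log(genes["planted_type"].map(medians).to_numpy(dtype=float))
    rpkm = np.exp(mu + cfg.rpkm_sigma * rng.standard_normal(len(genes)))
    return pd.Series(rpkm, index=genes["gene_id"].to_numpy(), name="rpkm")


def _make_truth(cfg, hubs, links, genes, expression, comp_labels, removed=frozenset(),
                changed_genes=()) -> dict:
    link_dist = {}
    for cat in ("PP", "EE", "PE"):
        d = links.loc[links["category"] == cat, "distance"].to_numpy()
        if len(d):
            link_dist[cat] = float(np.median(d))
    boundaries = {
        chrom: [int(b * cfg.compartment_block)
                for b in range(1, len(labels))]
        for chrom, labels in comp_labels.items()
    }
    return {
        "config": dataclasses.asdict(cfg),
        "hubs": hubs.to_dict(orient="records"),
        "links": links.to_dict(orient="records"),
        "genes": genes.to_dict(orient="records"),
        "expression": {k: float(v) for k, v in expression.items()},
        "link_distance_medians": link_dist,
        "compartment_labels": {c: list(map(str, v)) for c, v in comp_labels.items()},
        "compartment_block_boundaries": boundaries,
        "removed_hubs": sorted(int(h) for h in removed),
        "hub_loss_genes": list(changed_genes),
    }


def simulate(config: SimulationConfig) -> SimBundle:
    """Generate a full single-condition bundle with ground truth."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_layout, s_pairs, s_expr = root.spawn(3)
    rng_layout = np.random.default_rng(s_layout)
    assembly = _random_genome(config, rng_layout)
    comp = _compartment_labels(config)
    hubs, links = _place_hubs(config, rng_layout, comp)
    genes = _place_genes(config, rng_layout, hubs)
    peaks = _histone_peaks(config, rng_layout, hubs)
    pairs = _generate_pairs(config, np.random.default_rng(s_pairs), assembly, hubs,
                            links, genes, comp)
    expression = _expression(config, np.random.default_rng(s_expr), genes)
    truth = _make_truth(config, hubs, links, genes, expression, comp)
    return SimBundle(config, assembly, pairs, genes, expression,
                     peaks["h3k4me3"], peaks["h3k4me1"], peaks["h3k27ac"], truth)


def two_condition_bundle(config: SimulationConfig) -> tuple[SimBundle, SimBundle]:
    """Two conditions sharing genome and genes; some promoter hubs (and all
    pairs touching them) are removed in condition B, and the expression of
    the genes hosted there is scaled down by ``hub_loss_fold``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_layout, s_pairs_a, s_expr, s_pairs_b, s_noise = root.spawn(5)
    rng_layout = np.random.default_rng(s_layout)
    assembly = _random_genome(config, rng_layout)
    comp = _compartment_labels(config)
    hubs, links = _place_hubs(config, rng_layout, comp)
    genes = _place_genes(config, rng_layout, hubs)
    peaks = _histone_peaks(config, rng_layout, hubs)

    # pick promoter hubs to delete until enough hosted genes are affected
    hub_gene_counts = genes[genes["host_hub"] >= 0].groupby("host_hub").size()
    removed, affected = set(), []
    for hub_id, cnt in hub_gene_counts.items():
        if len(affected) >= config.n_hub_loss_genes:
            break
        removed.add(int(hub_id))
        affected.extend(genes.loc[genes["host_hub"] == hub_id, "gene_id"].tolist())

    pairs_a = _generate_pairs(config, np.random.default_rng(s_pairs_a), assembly,
                              hubs, links, genes, comp)
    # in B the lost promoters go quiet: no stray ends land there either
    lost_windows = [
        (g["chrom"], int(g["tss"]) - config.promoter_up - 1, int(g["tss"]) + 2)
        for _, g in genes[genes["gene_id"].isin(affected)].iterrows()
    ]
    hubs_b_peaks = _histone_peaks(config, np.random.default_rng(s_layout.spawn(1)[0]),
                                  hubs[~hubs["hub_id"].isin(removed)])
    pairs_b = _generate_pairs(config, np.random.default_rng(s_pairs_b), assembly,
                              hubs, links, genes, comp, removed_hubs=removed,
                              extra_excluded=lost_windows)

    expr_a = _expression(config, np.random.default_rng(s_expr), genes)
    rng_noise = np.random.default_rng(s_noise)
    noise = np.exp(config.expression_noise_sigma * rng_noise.standard_normal(len(expr_a)))
    scale = np.where(expr_a.index.isin(affected), 1.0 / config.hub_loss_fold, 1.0)
    expr_b = pd.Series(expr_a.to_numpy() * scale * noise, index=expr_a.index, name="rpkm")

    truth_a = _make_truth(config, hubs, links, genes, expr_a, comp)
    truth_b = _make_truth(config, hubs[~hubs["hub_id"].isin(removed)], links, genes,
                          expr_b, comp, removed=removed, changed_genes=affected)
    bundle_a = SimBundle(config, assembly, pairs_a, genes, expr_a,
                         peaks["h3k4me3"], peaks["h3k4me1"], peaks["h3k27ac"], truth_a)
    bundle_b = SimBundle(config, assembly, pairs_b, genes, expr_b,
                         hubs_b_peaks["h3k4me3"], hubs_b_peaks["h3k4me1"],
                         hubs_b_peaks["h3k27ac"], truth_b)
    return bundle_a, bundle_b


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Emit the bundle in standard text formats; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genome"] = out / "genome.fa"
    write_fasta(paths["genome"], bundle.assembly.sequence)

    p = bundle.pairs
    bedpe = pd.DataFrame({
        "chrom1": p["chrom1"], "start1": p["pos1"], "end1": p["pos1"] + 1,
        "chrom2": p["chrom2"], "start2": p["pos2"], "end2": p["pos2"] + 1,
        "name": p["provenance"], "score": 0,
        "strand1": p["strand1"], "strand2": p["strand2"],
        "mapq1": p["mapq1"], "mapq2": p["mapq2"],
    })
    paths["pairs"] = out / "pairs.bedpe"
    bedpe.to_csv(paths["pairs"], sep="\t", header=False, index=False)

    g = bundle.genes
    gene_bed = pd.DataFrame({
        "chrom": g["chrom"],
        "start": np.where(g["strand"] == "+", g["tss"], g["tss"] - 1999),
        "end": np.where(g["strand"] == "+", g["tss"] + 2000, g["tss"] + 1),
        "name": g["gene_id"], "score": 0, "strand": g["strand"],
    })
    paths["genes"] = out / "genes.bed"
    gene_bed.to_csv(paths["genes"], sep="\t", header=False, index=False)

    paths["expression"] = out / "expression.tsv"
    bundle.expression.rename_axis("gene_id").reset_index().to_csv(
        paths["expression"], sep="\t", index=False)

    for mark in ("h3k4me3", "h3k4me1", "h3k27ac"):
        paths[mark] = out / f"{mark}.bed"
        getattr(bundle, mark).to_csv(paths[mark], sep="\t", header=False, index=False,
                                     columns=["chrom", "start", "end"])

    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, default=_json_default)
    return paths


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# small planted matrices for balancing / compartment / insulation checks
# ---------------------------------------------------------------------------

def planted_bias_matrix(n_bins: int, seed: int, bias_range=(0.5, 2.0),
                        resolution: int = 40000) -> tuple[ContactMatrix, np.ndarray]:
    """``b_i * b_j * T`` with T (numerically) doubly balanced; returns (m, b)."""
    from .matrix import ice_balance

    rng = np.random.default_rng(seed)
    raw = rng.random((n_bins, n_bins)) + 0.5
    raw = (raw + raw.T) / 2
    t = ice_balance(ContactMatrix("synthetic", resolution, raw),
                    max_iter=500, tol=1e-12, mask_quantile=0.0).counts
    b = rng.uniform(*bias_range, n_bins)
    m = ContactMatrix("synthetic", resolution, np.outer(b, b) * t)
    return m, b


def checkerboard_matrix(n_bins: int = 100, block: int = 10, within: float = 5.0,
                        between: float = 1.0, mean_count: float = 50.0,
                        seed: int = 0, resolution: int = 40000
                        ) -> tuple[ContactMatrix, np.ndarray]:
    """Two interleaved bin classes with elevated within-class contact rate.

    Returns the Poisson-sampled matrix and the planted class of each bin
    (0/1, alternating blocks of ``block`` bins).
    """
    rng = np.random.default_rng(seed)
    classes = (np.arange(n_bins) // block) % 2
    same = classes[:, None] == classes[None, :]
    rate = np.where(same, within, between).astype(float)
    rate *= mean_count / rate.mean()
    m = rng.poisson(rate)
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMatrix("synthetic", resolution, m.astype(float)), classes


def tad_block_matrix(n_bins: int, boundaries: list[int], within: float = 10.0,
                     between: float = 1.0, mean_count: float = 40.0, seed: int = 0,
                     resolution: int = 40000) -> ContactMatrix:
    """Block-diagonal contact structure with boundaries at the given bins."""
    rng = np.random.default_rng(seed)
    edges = [0] + sorted(boundaries) + [n_bins]
    block_id = np.zeros(n_bins, dtype=int)
    for k in range(len(edges) - 1):
        block_id[edges[k]:edges[k + 1]] = k
    same = block_id[:, None] == block_id[None, :]
    rate = np.where(same, within, between).astype(float)
    rate *= mean_count / rate.mean()
    m = rng.poisson(rate)
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMatrix("synthetic", resolution, m.astype(float))
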