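"""Genome coordinate model, in-silico restriction digestion and interval overlap.

All coordinates are 0-based, half-open ``[start, end)`` internally; 1-based
conversion happens only when exporting browser text formats.  These types are
the plumbing every downstream stage rests on: a :class:`GenomeAssembly`
carries chromosome names, lengths and (optionally) sequence; a
:class:`FragmentMap` is the in-silico restriction digest used to classify
ligation read pairs; an :class:`IntervalIndex` answers every "does X overlap
Y" question in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "FragmentMap",
    "IntervalIndex",
    "digest",
    "overlap_any",
    "overlap_count",
    "overlap_list",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeAssembly:
    """Chromosome names, lengths, and optional nucleotide sequence.

    The assembly is always a parameter of the analysis, never hard-coded;
    any genome (or a synthetic one) can be supplied.
    """

    def __init__(
        self,
        lengths: dict[str, int],
        sequence: dict[str, str] | None = None,
    ):
        if len(lengths) == 0:
            raise ValueError("assembly needs at least one chromosome")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if sequence is not None:
            for name, seq in sequence.items():
                if name not in lengths:
                    raise ValueError(f"sequence for unknown chromosome {name}")
                if len(seq) != lengths[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{lengths[name]} for {name}"
                    )
        self.lengths: dict[str, int] = dict(lengths)
        self.sequence = sequence

    @property
    def chrom_names(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def subset(self, include: Sequence[str]) -> "GenomeAssembly":
        """Restrict to an include-list of chromosomes (order preserved)."""
        lengths = {c: self.lengths[c] for c in include}
        seq = None
        if self.sequence is not None:
            seq = {c: self.sequence[c] for c in include if c in self.sequence}
        return GenomeAssembly(lengths, seq)

    @classmethod
    def from_fasta(cls, path, include: Sequence[str] | None = None) -> "GenomeAssembly":
        seqs = read_fasta(path)
        if include is not None:
            seqs = {c: seqs[c] for c in include}
        return cls({c: len(s) for c, s in seqs.items()}, seqs)

    @classmethod
    def from_sizes(cls, path) -> "GenomeAssembly":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"], df["length"])))


class FragmentMap:
    """Restriction fragments tiling each chromosome, with genome-wide ids.

    Fragment ids are consecutive integers in genomic order (chromosomes in
    assembly order), so the distance between id-adjacent fragments is
    meaningful within a chromosome.
    """

    def __init__(self, assembly: GenomeAssembly, cut_positions: dict[str, np.ndarray]):
        self.assembly = assembly
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._id_offset: dict[str, int] = {}
        offset = 0
        for chrom in assembly.chrom_names:
            length = assembly.length(chrom)
            cuts = np.asarray(cut_positions.get(chrom, np.empty(0, dtype=np.int64)))
            # suppress zero-length fragments at 0 / chrom end and duplicates
            cuts = np.unique(cuts[(cuts > 0) & (cuts < length)])
            starts = np.concatenate(([0], cuts)).astype(np.int64)
            ends = np.concatenate((cuts, [length])).astype(np.int64)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._id_offset[chrom] = offset
            offset += len(starts)
        self.n_fragments = offset

    def fragments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._starts[chrom], self._ends[chrom]

    def assign(self, chrom: str, pos) -> np.ndarray | int:
        """Fragment id(s) containing position(s); O(log F) per query."""
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        length = self.assembly.length(chrom)
        if np.any((pos_arr < 0) | (pos_arr >= length)):
            bad = pos_arr[(pos_arr < 0) | (pos_arr >= length)]
            raise ValueError(f"position(s) {bad[:3]} outside [0,{length}) on {chrom}")
        idx = np.searchsorted(self._starts[chrom], pos_arr, side="right") - 1
        ids = idx + self._id_offset[chrom]
        if np.isscalar(pos) or np.ndim(pos) == 0:
            return int(ids[0])
        return ids

    def midpoint(self, chrom: str, frag_id) -> np.ndarray | float:
        """Fragment midpoint(s) from genome-wide id(s) on a chromosome."""
        local = np.atleast_1d(np.asarray(frag_id)) - self._id_offset[chrom]
        mids = (self._starts[chrom][local] + self._ends[chrom][local]) / 2.0
        if np.ndim(frag_id) == 0 and not isinstance(frag_id, np.ndarray):
            return float(mids[0])
        return mids

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in self.assembly.chrom_names:
            starts, ends = self.fragments(chrom)
            off = self._id_offset[chrom]
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "name": [f"frag_{off + i}" for i in range(len(starts))],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def digest(assembly: GenomeAssembly, recognition_site: str) -> FragmentMap:
    """In-silico restriction digest at every occurrence of ``recognition_site``.

    The cut is placed at the 5' end (match start) of each site, matching the
    blunt convention for 4-cutters such as MboI/GATC; zero-length fragments
    are never emitted.  ``N`` bases never match.
    """
    if assembly.sequence is None:
        raise ValueError("digestion requires an assembly with sequence")
    site = recognition_site.upper()
    if not site or any(b not in "ACGT" for b in site):
        raise ValueError(f"recognition site {recognition_site!r} must be non-empty ACGT")
    cuts: dict[str, np.ndarray] = {}
    for chrom in assembly.chrom_names:
        seq = assembly.sequence[chrom].upper()
        positions = []
        i = seq.find(site)
        while i != -1:
            positions.append(i)
            i = seq.find(site, i + 1)
        cuts[chrom] = np.asarray(positions, dtype=np.int64)
    return FragmentMap(assembly, cuts)


class IntervalIndex:
    """Overlap queries against a fixed set of intervals.

    Half-open convention: ``[a,b)`` and ``[c,d)`` overlap iff ``a < d and
    c < b`` (at least one shared base).  Queries on chromosomes absent from
    the index return no overlap rather than raising.
    """

    def __init__(self, intervals: pd.DataFrame | Iterable[GenomicInterval]):
        df = _as_interval_frame(intervals)
        self.df = df
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        self._rows: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            order = np.argsort(sub["start"].to_numpy(), kind="stable")
            starts = sub["start"].to_numpy()[order]
            ends = sub["end"].to_numpy()[order]
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._maxend[chrom] = np.maximum.accumulate(ends)
            self._rows[chrom] = sub.index.to_numpy()[order]

    def __len__(self) -> int:
        return len(self.df)

    def any(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._starts:
            return False
        hi = np.searchsorted(self._starts[chrom], end, side="left")
        if hi == 0:
            return False
        return bool(self._maxend[chrom][hi - 1] > start)

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row labels (of the input frame) of all overlapping intervals."""
        if chrom not in self._starts:
            return np.empty(0, dtype=np.int64)
        hi = np.searchsorted(self._starts[chrom], end, side="left")
        mask = self._ends[chrom][:hi] > start
        return self._rows[chrom][:hi][mask]

    def count(self, chrom: str, start: int, end: int) -> int:
        return len(self.overlapping(chrom, start, end))

    def any_bulk(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorised ``any`` for arrays of queries on one chromosome."""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=bool)
        hi = np.searchsorted(self._starts[chrom], ends, side="left")
        maxend = np.concatenate(([np.iinfo(np.int64).min], self._maxend[chrom]))
        return maxend[hi] > starts

    def assign_points(self, chrom: str, positions) -> np.ndarray:
        """Row label of the interval containing each point, -1 if none.

        Requires the per-chromosome intervals to be non-overlapping; raises
        otherwise, because point-to-interval assignment would be ambiguous.
        """
        positions = np.asarray(positions)
        out = np.full(len(positions), -1, dtype=np.int64)
        if chrom not in self._starts:
            return out
        starts, ends = self._starts[chrom], self._ends[chrom]
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"intervals on {chrom} overlap; point assignment ambiguous")
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = self._rows[chrom][idx[ok]]
        return out


def _as_interval_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals
    rows = [
        {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": iv.strand,
         "name": iv.name, "score": iv.score}
        for iv in intervals
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "name", "score"])
    return pd.DataFrame(rows)


def overlap_any(query: GenomicInterval, subjects: IntervalIndex | Iterable) -> bool:
    idx = subjects if isinstance(subjects, IntervalIndex) else IntervalIndex(subjects)
    return idx.any(query.chrom, query.start, query.end)


def overlap_count(query: GenomicInterval, subjects: IntervalIndex | Iterable) -> int:
    idx = subjects if isinstance(subjects, IntervalIndex) else IntervalIndex(subjects)
    return idx.count(query.chrom, query.start, query.end)


def overlap_list(query: GenomicInterval, subjects: IntervalIndex | Iterable) -> np.ndarray:
    idx = subjects if isinstance(subjects, IntervalIndex) else IntervalIndex(subjects)
    return idx.overlapping(query.chrom, query.start, query.end)


# ---------------------------------------------------------------------------
# standard text formats
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_BED6 = ["chrom", "start", "end", "name", "score", "strand"]
_NARROWPEAK = _BED6 + ["signal", "pvalue", "qvalue", "summit_offset"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6(+); extra columns are kept with generic names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = _BED6[:ncol] if ncol <= 6 else _BED6 + [f"col{i}" for i in range(6, ncol)]
    df.columns = names
    return df


def write_bed(path, df: pd.DataFrame, columns: Sequence[str] | None = None) -> None:
    cols = list(columns) if columns else [c for c in _BED6 if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _NARROWPEAK[: df.shape[1]]
    return df


def write_narrowpeak(path, df: pd.DataFrame) -> None:
    out = df.copy()
    for col, default in [("name", "."), ("score", 0), ("strand", "."),
                         ("signal", 0.0), ("pvalue", -1.0), ("qvalue", -1.0),
                         ("summit_offset", -1)]:
        if col not in out.columns:
            out[col] = default
    out.to_csv(path, sep="\t", header=False, index=False, columns=_NARROWPEAK)
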