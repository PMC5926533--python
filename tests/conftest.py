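import numpy as np
import pandas as pd
import pytest

from oceanc.genome import GenomeAssembly, digest
from oceanc.hoci import build_coverage, call_hoci
from oceanc.pairs import filter_pairs
from oceanc.annotate import classify_hoci
from oceanc.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def tiny_assembly():
    # two small chromosomes with known GATC sites
    seq1 = "A" * 100 + "GATC" + "C" * 96 + "GATC" + "T" * 96  # cuts at 100, 200
    seq2 = "G" * 50 + "GATC" + "A" * 246  # cut at 50
    return GenomeAssembly({"c1": len(seq1), "c2": len(seq2)}, {"c1": seq1, "c2": seq2})


@pytest.fixture(scope="session")
def tiny_fragmap(tiny_assembly):
    return digest(tiny_assembly, "GATC")


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study: 2 x 5 Mb, 40 hubs, 200k pairs."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_products(default_bundle):
    """Shared downstream products of the default bundle."""
    b = default_bundle
    fragmap = digest(b.assembly, "GATC")
    valid, counts = filter_pairs(b.pairs, fragmap)
    track = build_coverage(valid, b.assembly)
    hocis = call_hoci(track)
    annotated = classify_hoci(hocis, b.h3k4me3, b.h3k4me1, b.h3k27ac, b.genes,
                              b.assembly)
    return {
        "bundle": b,
        "fragmap": fragmap,
        "valid": valid,
        "counts": counts,
        "track": track,
        "hocis": hocis,
        "annotated": annotated,
    }


def make_pairs_frame(rows):
    """Helper: build a pair table from (chrom1,pos1,s1,chrom2,pos2,s2[,mq1,mq2])."""
    cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
            "mapq1", "mapq2"]
    recs = []
    for r in rows:
        r = list(r) + [30, 30][: max(0, 8 - len(r))]
        recs.append(dict(zip(cols, r)))
    return pd.DataFrame(recs, columns=cols)
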