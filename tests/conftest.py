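from __future__ import annotations

import numpy as np
import pytest

from karyoevo.core_io import Contig, Gene, Genome


def make_gene(gid, contig, start, end, strand="+", marker="none"):
    return Gene(gid, contig, start, end, strand, marker)


def linear_genome(name: str, layout: dict[str, list[tuple]], length=None):
    """Build a genome from {contig: [(gene_id, start, end, strand[, class])]}.

    Contig length defaults to the last gene end plus 1 kb."""
    contigs = []
    for cid, genes in layout.items():
        gg = [
            Gene(
                g[0],
                cid,
                g[1],
                g[2],
                g[3] if len(g) > 3 else "+",
                g[4] if len(g) > 4 else "none",
            )
            for g in genes
        ]
        clen = length or (max((g.end for g in gg), default=0) + 1_000)
        contigs.append(Contig(cid, clen, gg))
    return Genome(name, contigs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
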