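"""1:1 putative orthologue inference from reciprocal hit tables.

The criterion is the reciprocal best hit (RBH): a pair (a, b) is kept when b
is a's unique best hit and a is b's unique best hit, both under the E-value
ceiling.  Best hits are ranked by bitscore (desc), then E-value (asc), then
subject id; a tie surviving all three disqualifies the gene as ambiguous.
Downstream filters mirror the curation rules used for draft fungal genomes:
repetitive classes (5S rDNA, tRNA) and multi-copy genes are dropped, and only
pairs supported by concordant neighbouring pairs on both genomes (synteny
support) survive — isolated single-gene matches are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from karyoevo.core_io import Gene, Genome, HitRecord


@dataclass(frozen=True)
class OrthologuePair:
    """A mutual-best-hit gene pair with its synteny support count."""

    gene_a: str
    gene_b: str
    evalue_ab: float
    evalue_ba: float
    synteny_support: int = 0


def _best_hits(hits: Sequence[HitRecord], evalue_max: float) -> dict[str, HitRecord]:
    """Unique best hit per query; ambiguous (fully tied) queries are dropped."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.evalue <= evalue_max:
            by_query.setdefault(h.query_id, []).append(h)
    best: dict[str, HitRecord] = {}
    for q, rows in by_query.items():
        rows.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        top = rows[0]
        if len(rows) > 1:
            nxt = rows[1]
            if (nxt.bitscore, nxt.evalue, nxt.subject_id) == (
                top.bitscore,
                top.evalue,
                top.subject_id,
            ):
                continue  # indistinguishable duplicates: ambiguous query
            if nxt.bitscore == top.bitscore and nxt.evalue == top.evalue:
                pass  # resolved by subject id ordering: keep top
        best[q] = top
    return best


def infer_rbh(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    evalue_max: float = 1e-3,
) -> list[OrthologuePair]:
    """Reciprocal best hits under the E-value ceiling.

    Returns exactly the pairs (a, b) where b is a's unique best hit and a is
    b's unique best hit, in both directions below ``evalue_max``.  The output
    is a partial matching: no gene appears twice.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    best_ab = _best_hits(hits_ab, evalue_max)
    best_ba = _best_hits(hits_ba, evalue_max)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append(
                OrthologuePair(a, b, evalue_ab=hit.evalue, evalue_ba=back.evalue)
            )
    return pairs


def drop_multicopy(
    pairs: Sequence[OrthologuePair],
    genome_a: Genome,
    genome_b: Genome,
) -> list[OrthologuePair]:
    """Remove pairs whose gene participates in more than one candidate pair or
    whose marker class is a dispersed repeat (5S rDNA, tRNA)."""
    repeat_classes = {"rdna5S", "trna"}
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for p in pairs:
        count_a[p.gene_a] = count_a.get(p.gene_a, 0) + 1
        count_b[p.gene_b] = count_b.get(p.gene_b, 0) + 1
    out = []
    for p in pairs:
        if count_a[p.gene_a] > 1 or count_b[p.gene_b] > 1:
            continue
        ga, gb = idx_a.get(p.gene_a), idx_b.get(p.gene_b)
        if ga is not None and ga.marker_class in repeat_classes:
            continue
        if gb is not None and gb.marker_class in repeat_classes:
            continue
        out.append(p)
    return out


def _gene_positions(genome: Genome) -> dict[str, tuple[str, int, str]]:
    """gene id -> (contig id, ordinal position along the contig, strand)."""
    pos = {}
    for c in genome.chromosomes:
        for i, g in enumerate(c.genes):
            pos[g.id] = (c.id, i, g.strand)
    return pos


def filter_by_synteny(
    pairs: Sequence[OrthologuePair],
    genome_a: Genome,
    genome_b: Genome,
    min_neighbors: int = 1,
    window_genes: int = 5,
) -> list[OrthologuePair]:
    """Keep pairs with at least ``min_neighbors`` concordant neighbouring pairs
    within ``window_genes`` gene positions on BOTH genomes.

    A neighbour is concordant when it lies within the window on both genomes,
    its relative strand matches the pair's, and its relative order agrees with
    the pair's orientation.  Removal is iterated to a fixed point, so the
    operation is idempotent; surviving pairs carry their final support count.
    """
    pos_a = _gene_positions(genome_a)
    pos_b = _gene_positions(genome_b)
    for p in pairs:
        if p.gene_a not in pos_a:
            raise KeyError(f"gene {p.gene_a} not in genome {genome_a.name}")
        if p.gene_b not in pos_b:
            raise KeyError(f"gene {p.gene_b} not in genome {genome_b.name}")

    def rel(p: OrthologuePair) -> int:
        sa, sb = pos_a[p.gene_a][2], pos_b[p.gene_b][2]
        return 1 if sa == sb else -1

    current = list(pairs)
    while True:
        # index pairs by contig_a ordinal so each pair only scans its window
        by_contig_a: dict[str, dict[int, list[OrthologuePair]]] = {}
        for q in current:
            ca2, ia2, _ = pos_a[q.gene_a]
            by_contig_a.setdefault(ca2, {}).setdefault(ia2, []).append(q)
        supports = []
        for p in current:
            ca, ia, _ = pos_a[p.gene_a]
            cb, ib, _ = pos_b[p.gene_b]
            rp = rel(p)
            n = 0
            local = by_contig_a[ca]
            for ia2 in range(ia - window_genes, ia + window_genes + 1):
                for q in local.get(ia2, ()):
                    if q is p:
                        continue
                    cb2, ib2, _ = pos_b[q.gene_b]
                    if cb2 != cb:
                        continue
                    da, db = ia2 - ia, ib2 - ib
                    if abs(db) > window_genes:
                        continue
                    if rel(q) != rp:
                        continue
                    if da * db * rp <= 0:
                        continue
                    n += 1
            supports.append(n)
        survivors = [
            replace(p, synteny_support=n)
            for p, n in zip(current, supports)
            if n >= min_neighbors
        ]
        if len(survivors) == len(current):
            return survivors
        current = [replace(p, synteny_support=0) for p in survivors]


def write_orthologue_table(
    pairs: Iterable[OrthologuePair], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tevalue_ab\tevalue_ba\tsupport\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.evalue_ab:.6g}\t"
                f"{p.evalue_ba:.6g}\t{p.synteny_support}\n"
            )
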