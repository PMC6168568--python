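"""Chain orthologue anchors into signed locally collinear blocks (LCBs).

An LCB is a maximal run of orthologous anchors conserved in order and relative
orientation between two genomes.  Chaining is per-contig-pair sparse dynamic
programming maximizing anchor count, with consecutive anchors constrained to
lie within ``max_gap_bp`` on both genomes; chains below ``min_anchors`` are
discarded.  Overlaps between extracted blocks on either genome are resolved by
keeping the heavier block intact and trimming the lighter at the midpoint of
the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from karyoevo.core_io import Gene, Genome, concatenated_offsets
from karyoevo.orthology import OrthologuePair


@dataclass(frozen=True)
class Anchor:
    """One orthologue pair placed on both genomes."""

    pair: OrthologuePair
    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    rel_strand: int  # +1 same strand, -1 opposite


@dataclass
class SyntenyBlock:
    """A signed collinear block: chained anchors with spans on both genomes."""

    id: int
    contig_a: str
    contig_b: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    sign: str  # '+' or '-'
    anchors: list[Anchor] = field(default_factory=list)

    @property
    def weight(self) -> int:
        return len(self.anchors)

    @property
    def length_bp(self) -> int:
        return min(
            self.span_a[1] - self.span_a[0], self.span_b[1] - self.span_b[0]
        )


def _anchors_from_pairs(
    pairs: Sequence[OrthologuePair], genome_a: Genome, genome_b: Genome
) -> list[Anchor]:
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    anchors = []
    for p in pairs:
        ga, gb = idx_a[p.gene_a], idx_b[p.gene_b]
        anchors.append(
            Anchor(
                pair=p,
                contig_a=ga.contig_id,
                start_a=ga.start,
                end_a=ga.end,
                contig_b=gb.contig_id,
                start_b=gb.start,
                end_b=gb.end,
                rel_strand=1 if ga.strand == gb.strand else -1,
            )
        )
    return anchors


def _chainable(u: Anchor, v: Anchor, sign: int, max_gap_bp: int) -> bool:
    """Can v follow u (in a-order) in a chain of the given sign?"""
    gap_a = v.start_a - u.end_a
    if gap_a < 0 or gap_a > max_gap_bp:
        return False
    if sign > 0:
        gap_b = v.start_b - u.end_b
    else:
        gap_b = u.start_b - v.end_b
    return 0 <= gap_b <= max_gap_bp


def _extract_chains(
    anchors: list[Anchor], sign: int, max_gap_bp: int
) -> list[list[Anchor]]:
    """Repeatedly extract the best (max-count) chain by DP until exhausted.

    Deterministic: anchors are processed in a-position order and ties favour
    the earlier predecessor.
    """
    pool = sorted(anchors, key=lambda a: (a.start_a, a.start_b))
    chains = []
    while pool:
        n = len(pool)
        score = [1] * n
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                if _chainable(pool[i], pool[j], sign, max_gap_bp) and (
                    score[i] + 1 > score[j]
                ):
                    score[j] = score[i] + 1
                    prev[j] = i
        best = max(range(n), key=lambda j: (score[j], -j))
        if score[best] == 0:
            break
        chain = []
        j = best
        while j >= 0:
            chain.append(pool[j])
            j = prev[j]
        chain.reverse()
        chains.append(chain)
        used = set(id(a) for a in chain)
        pool = [a for a in pool if id(a) not in used]
        if score[best] == 1:
            # remaining anchors can only yield singletons
            chains.extend([a] for a in pool)
            break
    return chains


def chain_anchors(
    pairs: Sequence[OrthologuePair],
    genome_a: Genome,
    genome_b: Genome,
    max_gap_bp: int = 30_000,
    min_anchors: int = 3,
) -> list[SyntenyBlock]:
    """Build signed collinear blocks from orthologue anchors.

    The result is invariant under shuffling of the input pair order, blocks do
    not overlap on either genome, and every block carries >= ``min_anchors``
    anchors strictly increasing on genome a and monotone (by sign) on genome b.
    """
    anchors = _anchors_from_pairs(pairs, genome_a, genome_b)
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.contig_a, a.contig_b), []).append(a)

    raw_blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_pair):
        group = by_pair[(ca, cb)]
        candidates: list[tuple[int, list[Anchor]]] = []
        for sign in (+1, -1):
            oriented = [a for a in group if a.rel_strand == sign]
            for chain in _extract_chains(oriented, sign, max_gap_bp):
                if len(chain) >= min_anchors:
                    candidates.append((sign, chain))
        for sign, chain in candidates:
            span_a = (min(a.start_a for a in chain), max(a.end_a for a in chain))
            span_b = (min(a.start_b for a in chain), max(a.end_b for a in chain))
            raw_blocks.append(
                SyntenyBlock(
                    id=0,
                    contig_a=ca,
                    contig_b=cb,
                    span_a=span_a,
                    span_b=span_b,
                    sign="+" if sign > 0 else "-",
                    anchors=list(chain),
                )
            )

    blocks = _resolve_overlaps(raw_blocks)
    blocks.sort(key=lambda b: (b.contig_a, b.span_a, b.contig_b, b.span_b))
    for i, b in enumerate(blocks, start=1):
        b.id = i
    return blocks


def _resolve_overlaps(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Trim the lighter block at the midpoint of any span overlap, per genome."""
    for side in ("a", "b"):
        key_contig = "contig_" + side
        key_span = "span_" + side
        by_contig: dict[str, list[SyntenyBlock]] = {}
        for b in blocks:
            by_contig.setdefault(getattr(b, key_contig), []).append(b)
        for contig_blocks in by_contig.values():
            contig_blocks.sort(key=lambda b: getattr(b, key_span))
            for u, v in zip(contig_blocks, contig_blocks[1:]):
                su, sv = getattr(u, key_span), getattr(v, key_span)
                if sv[0] < su[1]:  # overlap
                    mid = (sv[0] + su[1]) // 2
                    if u.weight >= v.weight:
                        setattr(v, key_span, (max(mid, sv[0]), max(mid, sv[1])))
                    else:
                        setattr(u, key_span, (min(mid, su[0]), min(mid, su[1])))
    return [
        b
        for b in blocks
        if b.span_a[1] > b.span_a[0] and b.span_b[1] > b.span_b[0]
    ]


def classify_blocks(
    blocks: Sequence[SyntenyBlock],
    gross_min_block_bp: int = 20_000,
    subtelomere_margin_bp: int = 50_000,
    subtelomeric_ends: set[tuple[str, str]] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[list[SyntenyBlock], list[SyntenyBlock]]:
    """Split blocks into (gross_blocks, all_blocks).

    Gross blocks are strictly larger than ``gross_min_block_bp`` and do not
    lie within ``subtelomere_margin_bp`` of a contig end flagged subtelomeric
    (``subtelomeric_ends``: set of (contig_id, 'left'|'right'); requires
    ``contig_lengths`` for 'right' ends).  Subtelomeric regions rearrange
    promiscuously and are excluded from gross-change counting.
    """
    subtelomeric_ends = subtelomeric_ends or set()
    contig_lengths = contig_lengths or {}
    gross = []
    for b in blocks:
        if b.length_bp <= gross_min_block_bp:
            continue
        in_margin = False
        for contig, span in ((b.contig_a, b.span_a), (b.contig_b, b.span_b)):
            if (contig, "left") in subtelomeric_ends and span[0] < subtelomere_margin_bp:
                in_margin = True
            if (contig, "right") in subtelomeric_ends:
                length = contig_lengths.get(contig)
                if length is not None and span[1] > length - subtelomere_margin_bp:
                    in_margin = True
        if not in_margin:
            gross.append(b)
    return gross, list(blocks)


def export_dotplot(
    blocks: Sequence[SyntenyBlock],
    genome_a: Genome,
    genome_b: Genome,
    path: str | Path,
) -> None:
    """Write block coordinates on concatenated genome axes as TSV
    (x_start, x_end, y_start, y_end, sign) for dot-plot style rendering."""
    off_a = concatenated_offsets(genome_a)
    off_b = concatenated_offsets(genome_b)
    with open(path, "w") as fh:
        fh.write("x_start\tx_end\ty_start\ty_end\tsign\n")
        for b in blocks:
            xa = (off_a[b.contig_a] + b.span_a[0], off_a[b.contig_a] + b.span_a[1])
            yb = (off_b[b.contig_b] + b.span_b[0], off_b[b.contig_b] + b.span_b[1])
            fh.write(f"{xa[0]}\t{xa[1]}\t{yb[0]}\t{yb[1]}\t{b.sign}\n")


def write_block_table(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tcontig_a\ta_start\ta_end\tcontig_b\tb_start\tb_end\t"
            "sign\tweight\tlength_bp\n"
        )
        for b in blocks:
            fh.write(
                f"{b.id}\t{b.contig_a}\t{b.span_a[0]}\t{b.span_a[1]}\t"
                f"{b.contig_b}\t{b.span_b[0]}\t{b.span_b[1]}\t{b.sign}\t"
                f"{b.weight}\t{b.length_bp}\n"
            )
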