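"""Synthetic multichromosomal genomes with known rearrangement histories.

The generator models the study system: a small haploid genome (3 chromosomes,
~500 syntenic blocks of log-normal length, ~11-12 Mb total) carrying
subtelomeric marker genes in the terminal blocks, pericentromeric markers in
the central blocks, and dispersed 5S rDNA / tRNA repeats at inter-block
boundaries.  Genomes evolve by inversions and translocations whose cut sites
fall on inter-block adjacencies, either uniformly (random breakage) or
concentrated on repeat-flanking adjacencies (repeat-biased breakage).  Draft
assemblies are emulated by fragmenting a genome at inter-block boundaries
into shuffled, randomly oriented contigs, and similarity searches by noisy
orthologue hit tables (decoy hits at worse scores; repeat families produce
many-to-many hits).

All randomness flows through one seeded numpy generator per call, so every
fixture is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np

from karyoevo.core_io import Contig, Gene, Genome, HitRecord, SignedGenome


@dataclass
class SimulationSpec:
    """Study-scale defaults: 3 chromosomes, ~500 blocks, 9 contigs; the
    planted history mirrors the closely-related-pair regime (7 translocations,
    4 inversions)."""

    n_chromosomes: int = 3
    n_blocks: int = 500
    block_length_mean: float = 23_000.0  # bp, of the log-normal itself
    block_length_sd: float = 15_000.0
    n_inversions: int = 4
    n_translocations: int = 7
    breakpoint_model: str = "uniform"  # or "repeat_biased"
    repeat_bias_weight: float = 10.0
    n_contigs: int = 9
    n_subtelomeric_blocks: int = 3
    n_pericentromeric_blocks: int = 3
    n_repeat_loci: int = 30
    n_trna: int = 20
    decoy_rate: float = 0.1
    gene_margin_bp: int = 500
    min_contig_blocks: int = 20  # draft contigs carry >= this many anchors
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < self.n_chromosomes:
            raise ValueError("n_blocks must be >= n_chromosomes")
        if self.n_contigs < self.n_chromosomes:
            raise ValueError("n_contigs must be >= n_chromosomes")
        for name in ("n_inversions", "n_translocations", "n_repeat_loci", "n_trna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.breakpoint_model not in ("uniform", "repeat_biased"):
            raise ValueError("breakpoint_model must be uniform or repeat_biased")


@dataclass
class BlockGenome:
    """Blocks-and-attachments representation that evolution operates on.

    ``chroms`` holds signed block ids; ``repeats`` attaches repeat genes to a
    block end ('head'/'tail' in block-local orientation), so repeats travel
    with their flanking sequence through inversions and translocations.
    """

    chroms: list[list[int]]
    block_len: dict[int, int]
    gene_strand: dict[int, str]
    marker_class: dict[int, str]
    repeats: list[tuple[int, str, int, str]] = field(default_factory=list)
    # (repeat index, class, block id, 'head'|'tail')

    def copy(self) -> "BlockGenome":
        return BlockGenome(
            [list(c) for c in self.chroms],
            dict(self.block_len),
            dict(self.gene_strand),
            dict(self.marker_class),
            list(self.repeats),
        )

    def to_signed_genome(self) -> SignedGenome:
        return SignedGenome([list(c) for c in self.chroms if c])


@dataclass
class SimOperation:
    kind: str  # 'inversion' | 'translocation'
    chromosomes: tuple[int, ...]
    gaps: tuple[int, ...]
    cut_adjacencies: tuple[frozenset, ...]
    crossed: bool = False
    at_repeat: tuple[bool, ...] = ()  # did each cut face a repeat locus?


@dataclass
class FragmentationTruth:
    """Ground truth of a fragmentation: per source chromosome the ordered
    (contig id, orientation) path, and the junction adjacencies cut."""

    order: list[list[tuple[str, str]]]
    junctions: list[tuple[int, int]]  # (chromosome index, gap index)
    junction_adjacencies: list[frozenset]


# ---------------------------------------------------------------------------
# Ancestor generation
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_ancestor(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> BlockGenome:
    """K chromosomes of log-normal-length blocks with marker classes placed:
    subtelomeric in the terminal blocks, pericentromeric in the central
    blocks, 5S rDNA repeats at random internal adjacencies and tRNA repeats
    near the chromosome centres.  Deterministic given the seed."""
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    mu, sigma = _lognormal_params(spec.block_length_mean, spec.block_length_sd)
    min_len = 2 * spec.gene_margin_bp + 1_000
    lengths = np.maximum(
        rng.lognormal(mu, sigma, size=spec.n_blocks).astype(int), min_len
    )

    counts = [spec.n_blocks // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_blocks % spec.n_chromosomes):
        counts[i] += 1
    chroms: list[list[int]] = []
    nxt = 1
    for c in counts:
        chroms.append(list(range(nxt, nxt + c)))
        nxt += c

    marker_class = {}
    for chrom in chroms:
        n_sub = min(spec.n_subtelomeric_blocks, len(chrom) // 2)
        for b in chrom[:n_sub]:
            marker_class[b] = "subtelomeric"
        for b in chrom[-n_sub:] if n_sub else []:
            marker_class[b] = "subtelomeric"
        centre = len(chrom) // 2
        half = spec.n_pericentromeric_blocks // 2
        for b in chrom[max(0, centre - half) : centre + half + 1]:
            marker_class[b] = "pericentromeric"

    gene_strand = {
        b: ("+" if rng.random() < 0.5 else "-")
        for b in range(1, spec.n_blocks + 1)
    }

    bg = BlockGenome(
        chroms=chroms,
        block_len={b: int(l) for b, l in zip(range(1, spec.n_blocks + 1), lengths)},
        gene_strand=gene_strand,
        marker_class=marker_class,
    )

    # dispersed repeats: 5S rDNA at random internal adjacencies, tRNA near
    # the pericentromeric centres
    internal = [
        (ci, g) for ci, chrom in enumerate(chroms) for g in range(1, len(chrom))
    ]
    if spec.n_repeat_loci > 0 and internal:
        picks = rng.choice(len(internal), size=min(spec.n_repeat_loci, len(internal)), replace=False)
        for k, pi in enumerate(sorted(picks)):
            ci, g = internal[pi]
            left = chroms[ci][g - 1]
            bg.repeats.append((len(bg.repeats), "rdna5S", abs(left), "head"))
    for ci, chrom in enumerate(chroms):
        centre = len(chrom) // 2
        lo, hi = max(0, centre - 5), min(len(chrom), centre + 5)
        zone = chrom[lo:hi]
        for _ in range(spec.n_trna // spec.n_chromosomes):
            b = int(zone[rng.integers(len(zone))])
            bg.repeats.append((len(bg.repeats), "trna", b, "tail"))
    return bg


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def _rc(seg: Sequence[int]) -> list[int]:
    return [-m for m in reversed(seg)]


def _repeat_sides(bg: BlockGenome) -> set[tuple[int, str]]:
    return {(b, side) for _, _, b, side in bg.repeats}


def _adjacency_blocks(chrom: Sequence[int], gap: int) -> frozenset:
    return frozenset((abs(chrom[gap - 1]), abs(chrom[gap])))


def _gap_faces_repeat(
    chrom: Sequence[int], gap: int, repeat_sides: set[tuple[int, str]]
) -> bool:
    left, right = chrom[gap - 1], chrom[gap]
    left_face = (abs(left), "head" if left > 0 else "tail")
    right_face = (abs(right), "tail" if right > 0 else "head")
    return left_face in repeat_sides or right_face in repeat_sides


def _candidate_gaps(
    bg: BlockGenome,
    forbidden: set[frozenset],
    repeat_sides: set[tuple[int, str]],
    bias: float,
) -> dict[tuple[int, int], float]:
    """Cuttable (chromosome, gap) positions with unnormalized weights."""
    gapw: dict[tuple[int, int], float] = {}
    for ci, chrom in enumerate(bg.chroms):
        for g in range(1, len(chrom)):
            if _adjacency_blocks(chrom, g) in forbidden:
                continue
            w = bias if (bias > 1 and _gap_faces_repeat(chrom, g, repeat_sides)) else 1.0
            gapw[(ci, g)] = w
    return gapw


def evolve(
    bg: BlockGenome,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    forbidden_adjacencies: set[frozenset] | None = None,
) -> tuple[BlockGenome, list[SimOperation]]:
    """Apply the spec's inversions and translocations in random order.

    Cut sites are drawn over inter-block adjacencies — uniformly, or with
    mass concentrated on repeat-flanking adjacencies under the repeat-biased
    model.  ``forbidden_adjacencies`` (sets of flanking block-id pairs) are
    never cut.  Returns the derived genome and the exact history.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    forbidden = forbidden_adjacencies or set()
    bias = spec.repeat_bias_weight if spec.breakpoint_model == "repeat_biased" else 1.0
    out = bg.copy()
    kinds = ["inversion"] * spec.n_inversions + [
        "translocation"
    ] * spec.n_translocations
    rng.shuffle(kinds)
    ops: list[SimOperation] = []
    repeat_sides = _repeat_sides(out)
    for kind in kinds:
        gapw = _candidate_gaps(out, forbidden, repeat_sides, bias)
        by_chrom: dict[int, list[int]] = {}
        for (ci, g) in gapw:
            by_chrom.setdefault(ci, []).append(g)
        for gs in by_chrom.values():
            gs.sort()
        if kind == "inversion":
            eligible = sorted(ci for ci, gs in by_chrom.items() if len(gs) >= 2)
            if not eligible:
                raise ValueError("no chromosome with two available cut sites")
            cw = np.array(
                [sum(gapw[(ci, g)] for g in by_chrom[ci]) for ci in eligible]
            )
            ci = int(eligible[rng.choice(len(eligible), p=cw / cw.sum())])
            gsel = by_chrom[ci]
            pw = np.array([gapw[(ci, g)] for g in gsel])
            pick = rng.choice(len(gsel), size=2, replace=False, p=pw / pw.sum())
            l, r = sorted(int(gsel[i]) for i in pick)
            chrom = out.chroms[ci]
            cuts = (_adjacency_blocks(chrom, l), _adjacency_blocks(chrom, r))
            faces = (
                _gap_faces_repeat(chrom, l, repeat_sides),
                _gap_faces_repeat(chrom, r, repeat_sides),
            )
            out.chroms[ci] = chrom[:l] + _rc(chrom[l:r]) + chrom[r:]
            ops.append(
                SimOperation("inversion", (ci,), (l, r), cuts, at_repeat=faces)
            )
        else:
            chrom_ids = sorted(by_chrom)
            if len(chrom_ids) < 2:
                raise ValueError("translocation needs two cuttable chromosomes")
            ci, cj = (
                int(x) for x in rng.choice(chrom_ids, size=2, replace=False)
            )
            gi, gj = by_chrom[ci], by_chrom[cj]
            pwi = np.array([gapw[(ci, g)] for g in gi])
            pwj = np.array([gapw[(cj, g)] for g in gj])
            p = int(gi[rng.choice(len(gi), p=pwi / pwi.sum())])
            q = int(gj[rng.choice(len(gj), p=pwj / pwj.sum())])
            a, b = out.chroms[ci], out.chroms[cj]
            cuts = (_adjacency_blocks(a, p), _adjacency_blocks(b, q))
            faces = (
                _gap_faces_repeat(a, p, repeat_sides),
                _gap_faces_repeat(b, q, repeat_sides),
            )
            crossed = bool(rng.random() < 0.5)
            if crossed:
                out.chroms[ci], out.chroms[cj] = a[:p] + _rc(b[:q]), _rc(a[p:]) + b[q:]
            else:
                out.chroms[ci], out.chroms[cj] = a[:p] + b[q:], b[:q] + a[p:]
            ops.append(
                SimOperation(
                    "translocation", (ci, cj), (p, q), cuts, crossed,
                    at_repeat=faces,
                )
            )
    return out, ops


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


def fragment_genome(
    bg: BlockGenome,
    n_contigs: int,
    rng: np.random.Generator | None = None,
    min_blocks: int = 1,
) -> tuple[BlockGenome, FragmentationTruth]:
    """Cut the genome into shuffled, randomly oriented contigs.

    Cut points fall between blocks only and every piece keeps at least
    ``min_blocks`` blocks (a draft supercontig small enough to carry no
    anchors could never be placed); the true contig order, orientation and
    the cut (junction) adjacencies are recorded.  With
    ``n_contigs == n_chromosomes`` the contigs are whole chromosomes."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n_cuts = n_contigs - len(bg.chroms)
    if n_cuts < 0:
        raise ValueError("n_contigs must be >= number of chromosomes")
    internal = [
        (ci, g) for ci, chrom in enumerate(bg.chroms) for g in range(1, len(chrom))
    ]
    if n_cuts > len(internal):
        raise ValueError("not enough inter-block adjacencies to cut")
    picks: list[tuple[int, int]] = []
    for _ in range(1_000):
        picks = sorted(
            internal[i]
            for i in rng.choice(len(internal), size=n_cuts, replace=False)
        )
        if _pieces_ok(bg, picks, min_blocks):
            break
    else:
        raise ValueError(
            f"could not fragment into {n_contigs} pieces of >= {min_blocks} blocks"
        )
    junction_adj = [
        _adjacency_blocks(bg.chroms[ci], g) for ci, g in picks
    ]

    pieces: list[tuple[int, list[int]]] = []  # (source chromosome, blocks)
    for ci, chrom in enumerate(bg.chroms):
        cuts = [g for (c, g) in picks if c == ci]
        prev = 0
        for g in cuts + [len(chrom)]:
            pieces.append((ci, chrom[prev:g]))
            prev = g

    order = rng.permutation(len(pieces))
    flips = rng.random(len(pieces)) < 0.5
    contig_chroms: list[list[int]] = []
    placed: dict[int, tuple[str, str]] = {}  # piece index -> (contig id, orient)
    for rank, pi in enumerate(order):
        name = f"ctg{rank + 1}"
        src, blocks = pieces[pi]
        if flips[rank]:
            contig_chroms.append(_rc(blocks))
            placed[int(pi)] = (name, "-")
        else:
            contig_chroms.append(list(blocks))
            placed[int(pi)] = (name, "+")

    truth_order: list[list[tuple[str, str]]] = []
    pi = 0
    for ci, chrom in enumerate(bg.chroms):
        n_pieces = 1 + sum(1 for c, _ in picks if c == ci)
        truth_order.append([placed[pi + k] for k in range(n_pieces)])
        pi += n_pieces

    frag = BlockGenome(
        chroms=contig_chroms,
        block_len=dict(bg.block_len),
        gene_strand=dict(bg.gene_strand),
        marker_class=dict(bg.marker_class),
        repeats=list(bg.repeats),
    )
    return frag, FragmentationTruth(truth_order, picks, junction_adj)


def _pieces_ok(
    bg: BlockGenome, picks: list[tuple[int, int]], min_blocks: int
) -> bool:
    for ci, chrom in enumerate(bg.chroms):
        cuts = [g for (c, g) in picks if c == ci]
        prev = 0
        for g in cuts + [len(chrom)]:
            if g - prev < min_blocks:
                return False
            prev = g
    return True


def junction_exclusion_zone(
    bg: BlockGenome, truth: FragmentationTruth, width: int = 3
) -> set[frozenset]:
    """Adjacencies within ``width`` inter-block gaps of any planted contig
    junction (used to keep reference histories from erasing junction
    support)."""
    zone: set[frozenset] = set()
    for ci, gap in truth.junctions:
        chrom = bg.chroms[ci]
        for g in range(max(1, gap - width), min(len(chrom), gap + width + 1)):
            zone.add(_adjacency_blocks(chrom, g))
    return zone


# ---------------------------------------------------------------------------
# Materialization to annotated genomes
# ---------------------------------------------------------------------------


def materialize(
    bg: BlockGenome,
    name: str,
    contig_prefix: str = "chr",
    gene_margin_bp: int = 500,
) -> Genome:
    """Realize block coordinates as an annotated Genome.

    Each block contributes one gene spanning the block minus the margins;
    repeats become short (120 bp) genes inside the margin at their attached
    block end.  Contigs are named ``{contig_prefix}1..K`` (use 'ctg' for a
    fragmented draft)."""
    rep_by_block: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for idx, cls, b, side in bg.repeats:
        rep_by_block.setdefault((b, side), []).append((idx, cls))

    contigs = []
    for ci, chrom in enumerate(bg.chroms):
        cid = f"{contig_prefix}{ci + 1}"
        genes: list[Gene] = []
        off = 0
        for m in chrom:
            b = abs(m)
            length = bg.block_len[b]
            strand = bg.gene_strand[b]
            if m < 0:
                strand = "-" if strand == "+" else "+"
            genes.append(
                Gene(
                    id=f"{name}_b{b:05d}",
                    contig_id=cid,
                    start=off + gene_margin_bp,
                    end=off + length - gene_margin_bp,
                    strand=strand,
                    marker_class=bg.marker_class.get(b, "none"),
                )
            )
            # repeats attached to this block: head side sits in the right
            # margin when the block is forward, in the left margin otherwise
            for side in ("head", "tail"):
                attached = rep_by_block.get((b, side), ())
                if not attached:
                    continue
                at_right = (side == "head") == (m > 0)
                for k, (idx, cls) in enumerate(attached):
                    if at_right:
                        s = off + length - gene_margin_bp + 40 + 130 * k
                    else:
                        s = off + 40 + 130 * k
                    e = s + 120
                    if e > off + length:
                        continue  # margin too crowded; drop the extra copy
                    genes.append(
                        Gene(
                            id=f"{name}_r{idx:03d}",
                            contig_id=cid,
                            start=s,
                            end=e,
                            strand="+",
                            marker_class=cls,
                        )
                    )
            off += length
        contigs.append(Contig(cid, off, genes))
    return Genome(name, contigs)


def true_orthologue_map(
    bg_a: BlockGenome, name_a: str, bg_b: BlockGenome, name_b: str
) -> dict[str, str]:
    """Main block genes shared by both genomes, by block id."""
    blocks_a = {abs(m) for c in bg_a.chroms for m in c}
    blocks_b = {abs(m) for c in bg_b.chroms for m in c}
    return {
        f"{name_a}_b{b:05d}": f"{name_b}_b{b:05d}"
        for b in sorted(blocks_a & blocks_b)
    }


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


def emit_hit_tables(
    genome_a: Genome,
    genome_b: Genome,
    ortho_map: dict[str, str],
    rng: np.random.Generator | None = None,
    decoy_rate: float = 0.1,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Noisy reciprocal hit tables with planted truth.

    True pairs are mutual best hits far below the E-value ceiling; decoys are
    added at ``decoy_rate`` with strictly worse bitscores; repeat-class genes
    (5S rDNA, tRNA) hit every member of their family in the other genome, so
    they are many-to-many by construction."""
    rng = rng if rng is not None else np.random.default_rng(0)
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    ids_b = [g.id for g in genome_b.genes]

    for ga, gb in sorted(ortho_map.items()):
        bs = float(rng.uniform(500, 2000))
        ev_ab = 10.0 ** rng.uniform(-180, -20)
        ev_ba = 10.0 ** rng.uniform(-180, -20)
        hits_ab.append(HitRecord(ga, gb, ev_ab, bs))
        hits_ba.append(HitRecord(gb, ga, ev_ba, bs * float(rng.uniform(0.95, 1.05))))
        if rng.random() < decoy_rate:
            decoy = ids_b[int(rng.integers(len(ids_b)))]
            if decoy != gb:
                hits_ab.append(
                    HitRecord(
                        ga,
                        decoy,
                        10.0 ** rng.uniform(-15, -4),
                        bs * float(rng.uniform(0.3, 0.8)),
                    )
                )

    # repeat families: all-vs-all within class
    for cls in ("rdna5S", "trna"):
        fam_a = [g.id for g in genome_a.genes if g.marker_class == cls]
        fam_b = [g.id for g in genome_b.genes if g.marker_class == cls]
        for ra in fam_a:
            for rb in fam_b:
                hits_ab.append(
                    HitRecord(ra, rb, 10.0 ** rng.uniform(-40, -20), float(rng.uniform(150, 260)))
                )
                hits_ba.append(
                    HitRecord(rb, ra, 10.0 ** rng.uniform(-40, -20), float(rng.uniform(150, 260)))
                )
    return hits_ab, hits_ba


# ---------------------------------------------------------------------------
# Signed-permutation-level helpers (for distance benchmarks)
# ---------------------------------------------------------------------------


def identity_signed_genome(n_blocks: int, n_chromosomes: int) -> SignedGenome:
    counts = [n_blocks // n_chromosomes] * n_chromosomes
    for i in range(n_blocks % n_chromosomes):
        counts[i] += 1
    chroms = []
    nxt = 1
    for c in counts:
        chroms.append(list(range(nxt, nxt + c)))
        nxt += c
    return SignedGenome(chroms)


def evolve_signed(
    genome: SignedGenome,
    n_inversions: int,
    n_translocations: int,
    rng: np.random.Generator,
) -> tuple[SignedGenome, list[str]]:
    """Apply a shuffled history of inversions and translocations with uniform
    cut sites directly on a signed genome; returns the derived genome and the
    kind sequence."""
    chroms = [list(c) for c in genome.chromosomes]
    kinds = ["inversion"] * n_inversions + ["translocation"] * n_translocations
    rng.shuffle(kinds)
    for kind in kinds:
        if kind == "inversion":
            eligible = [i for i, c in enumerate(chroms) if len(c) >= 3]
            ci = int(eligible[rng.integers(len(eligible))])
            c = chroms[ci]
            l, r = sorted(
                int(x) + 1 for x in rng.choice(len(c) - 1, size=2, replace=False)
            )
            chroms[ci] = c[:l] + _rc(c[l:r]) + c[r:]
        else:
            eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
            i, j = (int(x) for x in rng.choice(eligible, size=2, replace=False))
            p = int(rng.integers(1, len(chroms[i])))
            q = int(rng.integers(1, len(chroms[j])))
            if rng.random() < 0.5:
                chroms[i], chroms[j] = (
                    chroms[i][:p] + _rc(chroms[j][:q]),
                    _rc(chroms[i][p:]) + chroms[j][q:],
                )
            else:
                chroms[i], chroms[j] = (
                    chroms[i][:p] + chroms[j][q:],
                    chroms[j][:q] + chroms[i][p:],
                )
    return SignedGenome(chroms), kinds


def clustered_segment_lengths(
    n: int, mean: float, rng: np.random.Generator, short: float = 0.2, long: float = 1.8
) -> np.ndarray:
    """Repeat-clustered breakage alternative: a two-point mixture of segment
    lengths (half near ``short``x the mean, half near ``long``x), preserving
    the overall mean but grossly violating the exponential law."""
    half = n // 2
    lengths = np.concatenate(
        [np.full(half, short * mean), np.full(n - half, long * mean)]
    )
    return lengths * rng.uniform(0.95, 1.05, size=n)


def write_ground_truth(
    path: str | Path,
    operations: Sequence[SimOperation] = (),
    truth: FragmentationTruth | None = None,
    ortho_map: dict[str, str] | None = None,
) -> None:
    """Serialize ground truth as structured JSON text."""
    doc: dict = {
        "operations": [
            {
                "kind": op.kind,
                "chromosomes": list(op.chromosomes),
                "gaps": list(op.gaps),
                "cut_adjacencies": [sorted(a) for a in op.cut_adjacencies],
                "crossed": op.crossed,
            }
            for op in operations
        ]
    }
    if truth is not None:
        doc["contig_order"] = [
            [list(step) for step in path] for path in truth.order
        ]
        doc["junctions"] = [list(j) for j in truth.junctions]
    if ortho_map is not None:
        doc["orthologues"] = ortho_map
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
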