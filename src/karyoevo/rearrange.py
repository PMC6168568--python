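"""Multichromosomal rearrangement distance and scenarios (DCJ model).

Genomes are signed permutations over a shared marker universe, one list per
(linear) chromosome.  The distance is the double-cut-and-join (DCJ) minimum,
computed with the adjacency-graph closed form

    d = N - C - I/2

where N is the number of markers, C the number of cycles and I the number of
odd paths in the adjacency graph of the two genomes.  DCJ unifies inversion,
translocation, fusion and fission under one operation and has an exact
closed-form distance; it matches the classical inversion+translocation
distance on the overwhelming majority of instances and is used here
comparatively, as a multichromosomal distance (MCD).

A minimal scenario is constructed greedily: each step creates a target
adjacency (which always decreases the distance by one), preferring operations
that keep every intermediate chromosome linear.  On the rare instances where
no linear-safe step exists, a segment is excised as a transient circular
intermediate and reintegrated by a later step ('excision'/'reintegration'
kinds); both steps still decrease the distance, so the scenario length always
equals the distance.  Planted histories of independent inversions and
translocations are recovered with their exact operation types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from karyoevo.core_io import Genome, SignedGenome
from karyoevo.synteny import SyntenyBlock

# An extremity is (marker, 0) for the tail or (marker, 1) for the head.
Extremity = tuple[int, int]
Adjacency = tuple[Extremity, Extremity]  # stored sorted


@dataclass(frozen=True)
class Operation:
    """One step of a rearrangement scenario.

    ``created`` is the genome-B adjacency realized by the step (None for the
    pure-cut steps), ``cut`` the adjacency severed by a pure cut.  The
    human-readable fields record where the cuts fell when the operation was
    constructed.
    """

    step: int
    kind: str  # inversion | translocation | fusion | fission | excision | reintegration
    created: Adjacency | None = None
    cut: Adjacency | None = None
    chromosomes: tuple[int, ...] = ()
    positions: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Adjacency bookkeeping
# ---------------------------------------------------------------------------


def _walk(chrom: Sequence[int]) -> list[Extremity]:
    out: list[Extremity] = []
    for m in chrom:
        if m > 0:
            out.extend([(m, 0), (m, 1)])
        else:
            out.extend([(-m, 1), (-m, 0)])
    return out


def _adjacencies(chrom: Sequence[int], circular: bool = False) -> list[Adjacency]:
    w = _walk(chrom)
    adj = [
        tuple(sorted((w[i], w[i + 1]))) for i in range(1, len(w) - 1, 2)
    ]
    if circular and w:
        adj.append(tuple(sorted((w[-1], w[0]))))
    return adj  # type: ignore[return-value]


def _genome_adjacencies(g: SignedGenome) -> tuple[set[Adjacency], set[Extremity]]:
    adj: set[Adjacency] = set()
    tel: set[Extremity] = set()
    for chrom in g.chromosomes:
        if not chrom:
            continue
        w = _walk(chrom)
        tel.add(w[0])
        tel.add(w[-1])
        adj.update(_adjacencies(chrom))
    return adj, tel


def rearrangement_distance(a: SignedGenome, b: SignedGenome) -> int:
    """Minimal number of DCJ operations transforming ``a`` into ``b``.

    Symmetric, and 0 iff the genomes agree up to chromosome order and
    whole-chromosome reflection.  Marker universes must match exactly.
    """
    ma, mb = a.markers, b.markers
    if ma != mb:
        raise ValueError(
            f"marker sets differ: only in a={sorted(ma - mb)}, "
            f"only in b={sorted(mb - ma)}"
        )
    n = len(ma)
    if n == 0:
        return 0
    adj_a, _ = _genome_adjacencies(a)
    adj_b, _ = _genome_adjacencies(b)

    link_a: dict[Extremity, Extremity | None] = {}
    link_b: dict[Extremity, Extremity | None] = {}
    for m in ma:
        for side in (0, 1):
            link_a[(m, side)] = None
            link_b[(m, side)] = None
    for x, y in adj_a:
        link_a[x], link_a[y] = y, x
    for x, y in adj_b:
        link_b[x], link_b[y] = y, x

    visited: set[Extremity] = set()
    cycles = 0
    odd_paths = 0
    # path components start at an extremity missing at least one link
    for e in link_a:
        if e in visited:
            continue
        if link_a[e] is not None and link_b[e] is not None:
            continue
        verts = 1
        visited.add(e)
        use_a = link_a[e] is not None
        cur = e
        while True:
            nxt = link_a[cur] if use_a else link_b[cur]
            if nxt is None:
                break
            visited.add(nxt)
            verts += 1
            cur = nxt
            use_a = not use_a
        if verts % 2 == 1:
            odd_paths += 1
    for e in link_a:
        if e in visited:
            continue
        cycles += 1
        cur = e
        use_a = True
        while True:
            visited.add(cur)
            nxt = link_a[cur] if use_a else link_b[cur]
            use_a = not use_a
            cur = nxt  # type: ignore[assignment]
            if cur == e and use_a:
                break
    assert odd_paths % 2 == 0
    return n - cycles - odd_paths // 2


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------


def _rc(seg: Sequence[int]) -> list[int]:
    return [-m for m in reversed(seg)]


@dataclass
class _State:
    linear: list[list[int]]
    circular: list[list[int]] = field(default_factory=list)

    def all_adjacencies(self) -> set[Adjacency]:
        adj: set[Adjacency] = set()
        for chrom in self.linear:
            adj.update(_adjacencies(chrom))
        for ring in self.circular:
            adj.update(_adjacencies(ring, circular=True))
        return adj

    def locate(self) -> dict[Extremity, tuple[str, int, int, str]]:
        """extremity -> (kind, chrom index, marker index, side 'L'|'R')."""
        loc: dict[Extremity, tuple[str, int, int, str]] = {}
        for kind, chroms in (("lin", self.linear), ("circ", self.circular)):
            for ci, chrom in enumerate(chroms):
                w = _walk(chrom)
                for i, e in enumerate(w):
                    loc[e] = (kind, ci, i // 2, "L" if i % 2 == 0 else "R")
        return loc

    def to_signed_genome(self) -> SignedGenome:
        if self.circular:
            raise ValueError("circular intermediates remain")
        return SignedGenome([list(c) for c in self.linear if c])


def _gap(marker_index: int, side: str) -> int:
    return marker_index if side == "L" else marker_index + 1


def _apply_created(state: _State, created: Adjacency) -> str:
    """Perform the unique DCJ realizing ``created``; returns the op kind."""
    p, q = created
    loc = state.locate()
    kp, cp, mp, sp = loc[p]
    kq, cq, mq, sq = loc[q]

    if kp == "lin" and kq == "lin":
        if cp != cq:
            return _join_two_linear(state, (cp, mp, sp), (cq, mq, sq))
        return _same_linear(state, cp, (mp, sp), (mq, sq))
    if kp == "circ" and kq == "circ":
        if cp != cq:
            return _join_two_circles(state, (cp, mp, sp), (cq, mq, sq))
        return _same_circle(state, cp, (mp, sp), (mq, sq))
    # one on a circle, one on a linear chromosome: reintegration
    if kp == "circ":
        return _reintegrate(state, (cp, mp, sp), (cq, mq, sq))
    return _reintegrate(state, (cq, mq, sq), (cp, mp, sp))


def _join_two_linear(
    state: _State, at_p: tuple[int, int, str], at_q: tuple[int, int, str]
) -> str:
    cp, mp, sp = at_p
    cq, mq, sq = at_q
    ci, cj = state.linear[cp], state.linear[cq]
    gp, gq = _gap(mp, sp), _gap(mq, sq)
    a1, a2 = ci[:gp], ci[gp:]
    b1, b2 = cj[:gq], cj[gq:]
    if sp == "R" and sq == "L":
        new1, new2 = a1 + b2, b1 + a2
    elif sp == "R" and sq == "R":
        new1, new2 = a1 + _rc(b1), _rc(a2) + b2
    elif sp == "L" and sq == "L":
        new1, new2 = _rc(a2) + b2, a1 + _rc(b1)
    else:  # L, R
        new1, new2 = b1 + a2, a1 + b2
    replacement = [c for c in (new1, new2) if c]
    for idx in sorted((cp, cq), reverse=True):
        del state.linear[idx]
    state.linear.extend(replacement)
    return "fusion" if len(replacement) == 1 else "translocation"


def _same_linear(
    state: _State, ci_idx: int, at_p: tuple[int, str], at_q: tuple[int, str]
) -> str:
    (mp, sp), (mq, sq) = at_p, at_q
    chrom = state.linear[ci_idx]
    gp, gq = _gap(mp, sp), _gap(mq, sq)
    if sp == sq:
        # inversion: reverse the enclosed segment
        lo, hi = min(gp, gq), max(gp, gq)
        state.linear[ci_idx] = chrom[:lo] + _rc(chrom[lo:hi]) + chrom[hi:]
        return "inversion"
    # sides differ: a segment is excised as a circular intermediate; the
    # target adjacency lands either in the remainder or on the ring closure
    lo, hi = min(gp, gq), max(gp, gq)
    ring = chrom[lo:hi]
    remainder = chrom[:lo] + chrom[hi:]
    state.circular.append(ring)
    if remainder:
        state.linear[ci_idx] = remainder
    else:
        del state.linear[ci_idx]
    return "excision"


def _same_circle(
    state: _State, ci_idx: int, at_p: tuple[int, str], at_q: tuple[int, str]
) -> str:
    (mp, sp), (mq, sq) = at_p, at_q
    ring = state.circular[ci_idx]
    gp, gq = _gap(mp, sp) % len(ring), _gap(mq, sq) % len(ring)
    if sp == sq:
        # inversion within the circle: rotate so the segment is contiguous
        lo, hi = min(gp, gq), max(gp, gq)
        state.circular[ci_idx] = ring[:lo] + _rc(ring[lo:hi]) + ring[hi:]
        return "inversion"
    lo, hi = min(gp, gq), max(gp, gq)
    ring1, ring2 = ring[lo:hi], ring[hi:] + ring[:lo]
    state.circular[ci_idx] = ring1
    if ring2:
        state.circular.append(ring2)
    return "excision"


def _open_circle(ring: list[int], m: int, side: str, p_at: str) -> list[int]:
    """Linearize a circle so the extremity at (marker index m, side) sits at
    the requested end ('right' or 'left') of the returned segment."""
    if side == "R":
        seg = ring[m + 1 :] + ring[: m + 1]  # ends with marker m
        return seg if p_at == "right" else _rc(seg)
    seg = ring[m:] + ring[:m]  # starts with marker m
    return seg if p_at == "left" else _rc(seg)


def _reintegrate(
    state: _State, at_p: tuple[int, int, str], at_q: tuple[int, int, str]
) -> str:
    """p on a circle, q on a linear chromosome: one DCJ reinserts the circle."""
    cp, mp, sp = at_p
    cq, mq, sq = at_q
    ring = state.circular[cp]
    cj = state.linear[cq]
    gq = _gap(mq, sq)
    if sq == "L":
        seg = _open_circle(ring, mp, sp, "right")
        new = cj[:gq] + seg + cj[gq:]
    else:
        seg = _open_circle(ring, mp, sp, "left")
        new = cj[:gq] + seg + cj[gq:]
    del state.circular[cp]
    state.linear[cq] = new
    return "reintegration"


def _join_two_circles(
    state: _State, at_p: tuple[int, int, str], at_q: tuple[int, int, str]
) -> str:
    cp, mp, sp = at_p
    cq, mq, sq = at_q
    s1 = _open_circle(state.circular[cp], mp, sp, "right")
    s2 = _open_circle(state.circular[cq], mq, sq, "left")
    merged = s1 + s2
    for idx in sorted((cp, cq), reverse=True):
        del state.circular[idx]
    state.circular.append(merged)
    return "reintegration"


def _apply_cut(state: _State, cut: Adjacency) -> str:
    """Sever an adjacency: fission of a linear chromosome, or linearization
    of a circular intermediate."""
    loc = state.locate()
    x, _y = cut
    kind, ci, mi, side = loc[x]
    g = _gap(mi, side)
    if kind == "lin":
        chrom = state.linear[ci]
        left, right = chrom[:g], chrom[g:]
        del state.linear[ci]
        state.linear.extend([c for c in (left, right) if c])
        return "fission"
    ring = state.circular[ci]
    g = g % len(ring)
    del state.circular[ci]
    state.linear.append(ring[g:] + ring[:g])
    return "fission"


def _is_linear_safe(
    loc: dict[Extremity, tuple[str, int, int, str]], adj: Adjacency
) -> bool:
    """Does realizing this adjacency avoid creating a new circular piece?"""
    p, q = adj
    kp, cp, _, sp = loc[p]
    kq, cq, _, sq = loc[q]
    if kp == "circ" or kq == "circ":
        # touching a circle shrinks/merges it: progress towards linearity
        return not (kp == "circ" and kq == "circ" and cp == cq and sp != sq)
    if cp != cq:
        return True
    return sp == sq  # same-chromosome inversion


def sort_scenario(a: SignedGenome, b: SignedGenome) -> list[Operation]:
    """A minimal typed scenario transforming ``a`` into ``b``.

    Deterministic: target adjacencies are realized in sorted order, linear-
    safe operations first.  Scenario length always equals
    ``rearrangement_distance(a, b)``; replaying the operations on ``a`` gives
    ``b`` up to chromosome order and whole-chromosome reflection.
    """
    d0 = rearrangement_distance(a, b)
    target_adj, _ = _genome_adjacencies(b)
    state = _State(linear=[list(c) for c in a.chromosomes if c])
    ops: list[Operation] = []
    while True:
        current = state.all_adjacencies()
        missing = sorted(target_adj - current)
        if missing:
            loc = state.locate()
            partner: dict[Extremity, Extremity] = {}
            for x, y in current:
                partner[x] = y
                partner[y] = x

            def rank(adj: Adjacency) -> tuple[int, int, Adjacency]:
                # prefer steps whose leftover join realizes a second target
                # adjacency (resolving a whole cycle), and among those,
                # same-chromosome inversions before cross-chromosome joins
                p, q = adj
                x, y = partner.get(p), partner.get(q)
                double = 0
                if x is not None and y is not None:
                    left: Adjacency = tuple(sorted((x, y)))  # type: ignore[assignment]
                    if left in target_adj and left not in current:
                        double = 1
                kp, cp, _, sp = loc[p]
                kq, cq, _, sq = loc[q]
                if kp == kq == "lin" and cp == cq and sp == sq:
                    saferank = 0
                elif _is_linear_safe(loc, adj):
                    saferank = 1
                else:
                    saferank = 2
                return (-double, saferank, adj)

            chosen = min(missing, key=rank)
            info = _op_location(loc, chosen)
            kind = _apply_created(state, chosen)
            ops.append(
                Operation(
                    step=len(ops) + 1,
                    kind=kind,
                    created=chosen,
                    chromosomes=info[0],
                    positions=info[1],
                )
            )
            continue
        extra = sorted(current - target_adj)
        if not extra:
            break
        loc = state.locate()
        info = _op_location(loc, extra[0])
        kind = _apply_cut(state, extra[0])
        ops.append(
            Operation(
                step=len(ops) + 1,
                kind=kind,
                cut=extra[0],
                chromosomes=info[0],
                positions=info[1],
            )
        )
    assert len(ops) == d0, f"scenario length {len(ops)} != distance {d0}"
    return ops


def _op_location(
    loc: dict[Extremity, tuple[str, int, int, str]], adj: Adjacency
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    p, q = adj
    _, cp, mp, sp = loc[p]
    _, cq, mq, sq = loc[q]
    return (cp, cq), (_gap(mp, sp), _gap(mq, sq))


def replay_scenario(a: SignedGenome, ops: Sequence[Operation]) -> SignedGenome:
    """Re-apply a scenario; the result equals the target genome up to
    chromosome order and reflection."""
    state = _State(linear=[list(c) for c in a.chromosomes if c])
    for op in ops:
        if op.created is not None:
            _apply_created(state, op.created)
        elif op.cut is not None:
            _apply_cut(state, op.cut)
        else:
            raise ValueError(f"operation {op.step} has neither join nor cut")
    return state.to_signed_genome()


# ---------------------------------------------------------------------------
# Blocks -> signed genomes
# ---------------------------------------------------------------------------


def blocks_to_signed_genomes(
    blocks: Sequence[SyntenyBlock], genome_a: Genome, genome_b: Genome
) -> tuple[SignedGenome, SignedGenome]:
    """Number shared blocks along genome_a (all +) and derive genome_b's
    induced signed order, preserving chromosome boundaries."""
    ids_a = {c.id for c in genome_a.chromosomes}
    ids_b = {c.id for c in genome_b.chromosomes}
    for blk in blocks:
        if blk.contig_a not in ids_a or blk.contig_b not in ids_b:
            raise ValueError(
                f"block {blk.id} not present on both genomes "
                f"({blk.contig_a!r}/{blk.contig_b!r})"
            )
    order_a = {c.id: i for i, c in enumerate(genome_a.chromosomes)}
    numbered = sorted(blocks, key=lambda b: (order_a[b.contig_a], b.span_a))
    number = {id(b): i + 1 for i, b in enumerate(numbered)}

    chroms_a: list[list[int]] = []
    for c in genome_a.chromosomes:
        row = [number[id(b)] for b in numbered if b.contig_a == c.id]
        if row:
            chroms_a.append(row)

    chroms_b: list[list[int]] = []
    for c in genome_b.chromosomes:
        on_b = sorted(
            (b for b in blocks if b.contig_b == c.id), key=lambda b: b.span_b
        )
        row = [
            number[id(b)] if b.sign == "+" else -number[id(b)] for b in on_b
        ]
        if row:
            chroms_b.append(row)
    return SignedGenome(chroms_a), SignedGenome(chroms_b)


# ---------------------------------------------------------------------------
# MCD summary (Table-2-style arithmetic)
# ---------------------------------------------------------------------------


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MCDSummary:
    all_changes: int
    gross_changes: int
    n_chromosomes: int
    genome_size_mb: float | None
    per_chromosome_all: float
    per_chromosome_gross: float
    per_mb_all: float | None
    per_mb_gross: float | None
    gross_over_all_pct: int


def mcd_summary(
    all_changes: int,
    gross_changes: int,
    n_chromosomes: int,
    genome_size_mb: float | None = None,
) -> MCDSummary:
    """Normalize rearrangement counts per chromosome and per megabase.

    Ratios are rounded half-away-from-zero to 2 decimals; the gross/all
    percentage to the nearest integer.  The counts refer to one genome of the
    compared pair (the distance is symmetric).
    """
    if not (all_changes >= gross_changes >= 0):
        raise ValueError("need all_changes >= gross_changes >= 0")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if all_changes == 0:
        warnings.warn("all_changes is 0: percentage undefined, reported as 0")
        pct = 0
    else:
        pct = int(_round_half_up(100.0 * gross_changes / all_changes, 0))
    per_mb_all = per_mb_gross = None
    if genome_size_mb is not None:
        if genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be > 0")
        per_mb_all = _round_half_up(all_changes / genome_size_mb, 2)
        per_mb_gross = _round_half_up(gross_changes / genome_size_mb, 2)
    return MCDSummary(
        all_changes=all_changes,
        gross_changes=gross_changes,
        n_chromosomes=n_chromosomes,
        genome_size_mb=genome_size_mb,
        per_chromosome_all=_round_half_up(all_changes / n_chromosomes, 2),
        per_chromosome_gross=_round_half_up(gross_changes / n_chromosomes, 2),
        per_mb_all=per_mb_all,
        per_mb_gross=per_mb_gross,
        gross_over_all_pct=pct,
    )


def write_scenario(ops: Sequence[Operation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tkind\tchromosomes\tpositions\n")
        for op in ops:
            fh.write(
                f"{op.step}\t{op.kind}\t"
                f"{','.join(map(str, op.chromosomes))}\t"
                f"{','.join(map(str, op.positions))}\n"
            )


def write_mcd_table(
    rows: Sequence[tuple[str, MCDSummary]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "comparison\tn_chromosomes\tall_changes\tgross_changes\t"
            "per_chromosome_all\tper_chromosome_gross\t"
            "per_mb_all\tper_mb_gross\tgross_over_all_pct\n"
        )
        for name, s in rows:
            fh.write(
                f"{name}\t{s.n_chromosomes}\t{s.all_changes}\t{s.gross_changes}\t"
                f"{s.per_chromosome_all:.2f}\t{s.per_chromosome_gross:.2f}\t"
                f"{'' if s.per_mb_all is None else f'{s.per_mb_all:.2f}'}\t"
                f"{'' if s.per_mb_gross is None else f'{s.per_mb_gross:.2f}'}\t"
                f"{s.gross_over_all_pct}\n"
            )
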