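"""Order and orient draft contigs into chromosomes.

Evidence model: two contigs are adjacency candidates when a single reference
chromosome carries two synteny blocks, close together on the reference, whose
contig-side spans abut the respective contig ends with consistent orientation.
Subtelomeric marker genes pin chromosome ends, pericentromeric markers pin
centromere-bearing contigs, and the final order is a maximum-support path
cover satisfying those constraints, found by greedy selection with
backtracking (problem sizes are at most dozens of contigs).  When two
references disagree on a partner for the same contig end, the earlier genome
in the reference priority wins and the conflict is reported.  If several
covers achieve the maximum support the assembler reports the ambiguity rather
than silently choosing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from karyoevo.core_io import Contig, Gene, Genome
from karyoevo.synteny import SyntenyBlock


@dataclass(frozen=True)
class EndLabel:
    contig_id: str
    end: str  # 'left' | 'right'
    label: str  # 'subtelomeric' | 'pericentromeric' | 'internal'
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class AdjacencyCandidate:
    """A candidate join between two contig ends, supported on one reference."""

    end_1: tuple[str, str]  # (contig_id, 'left'|'right')
    end_2: tuple[str, str]
    support: int
    reference: str

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.end_1[0] == self.end_2[0]:
            raise ValueError("adjacency candidate must join different contigs")

    @property
    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return tuple(sorted((self.end_1, self.end_2)))  # type: ignore[return-value]


@dataclass
class ChromosomeAssembly:
    """An ordered, oriented contig path forming one chromosome."""

    name: str
    path: list[tuple[str, str]]  # (contig_id, '+'|'-')

    def canonical(self) -> "ChromosomeAssembly":
        """Reversing a whole assembly is the same assembly; canonical form
        puts the lexicographically smaller end first."""
        return ChromosomeAssembly(self.name, _canonical_path(self.path))


def _canonical_path(path: list[tuple[str, str]]) -> list[tuple[str, str]]:
    rev = [(cid, "-" if o == "+" else "+") for cid, o in reversed(path)]
    return min(path, rev)


@dataclass
class ScaffoldResult:
    assemblies: list[ChromosomeAssembly]
    conflicts: list[str] = field(default_factory=list)
    unique: bool = True
    alternatives: int = 0


def classify_contig_ends(
    contig: Contig, margin_bp: int = 50_000
) -> tuple[EndLabel, EndLabel, bool]:
    """Label both ends of a contig by the marker classes within ``margin_bp``.

    Returns (left label, right label, pericentromeric_flag); the flag records
    pericentromeric markers anywhere on the contig, since a centromere need
    not sit near a contig end.
    """
    labels = []
    for end in ("left", "right"):
        if end == "left":
            near = [g for g in contig.genes if g.start < margin_bp]
        else:
            near = [g for g in contig.genes if g.end > contig.length - margin_bp]
        sub = [g.id for g in near if g.marker_class == "subtelomeric"]
        peri = [g.id for g in near if g.marker_class == "pericentromeric"]
        if sub:
            labels.append(EndLabel(contig.id, end, "subtelomeric", tuple(sub)))
        elif peri:
            labels.append(EndLabel(contig.id, end, "pericentromeric", tuple(peri)))
        else:
            labels.append(EndLabel(contig.id, end, "internal"))
    peri_flag = any(g.marker_class == "pericentromeric" for g in contig.genes)
    return labels[0], labels[1], peri_flag


def _junction_end(block: SyntenyBlock, role: str) -> tuple[str, str]:
    """Which contig end faces the junction, for the block preceding ('first')
    or following ('second') the junction in reference order."""
    if role == "first":
        end = "right" if block.sign == "+" else "left"
    else:
        end = "left" if block.sign == "+" else "right"
    return (block.contig_a, end)


def build_adjacency_graph(
    contigs: Genome,
    blocks_by_reference: dict[str, tuple[Genome, list[SyntenyBlock]]],
    max_reference_gap_bp: int = 50_000,
    end_margin_bp: int = 50_000,
) -> list[AdjacencyCandidate]:
    """Derive contig-end adjacency candidates from synteny continuity on each
    reference genome.

    ``blocks_by_reference`` maps reference name -> (reference genome, blocks)
    where each block has the draft contig on side a and the reference
    chromosome on side b.  Support is the bridging anchor count (sum of the
    two flanking block weights), summed over all bridges on that reference.
    """
    lengths = {c.id: c.length for c in contigs.chromosomes}
    support: dict[tuple[str, tuple[tuple[str, str], tuple[str, str]]], int] = {}
    for ref_name in sorted(blocks_by_reference):
        _, blocks = blocks_by_reference[ref_name]
        by_chrom: dict[str, list[SyntenyBlock]] = {}
        for b in blocks:
            by_chrom.setdefault(b.contig_b, []).append(b)
        for chrom_blocks in by_chrom.values():
            chrom_blocks.sort(key=lambda b: b.span_b)
            for u, v in zip(chrom_blocks, chrom_blocks[1:]):
                if u.contig_a == v.contig_a:
                    continue
                gap = v.span_b[0] - u.span_b[1]
                if gap > max_reference_gap_bp:
                    continue
                e1 = _junction_end(u, "first")
                e2 = _junction_end(v, "second")
                # the blocks must abut the ends they nominate
                if not _abuts(u, e1[1], lengths[u.contig_a], end_margin_bp):
                    continue
                if not _abuts(v, e2[1], lengths[v.contig_a], end_margin_bp):
                    continue
                key = (ref_name, tuple(sorted((e1, e2))))
                support[key] = support.get(key, 0) + u.weight + v.weight
    out = []
    for (ref_name, ends), s in sorted(support.items()):
        out.append(AdjacencyCandidate(ends[0], ends[1], s, ref_name))
    return out


def _abuts(block: SyntenyBlock, end: str, contig_length: int, margin: int) -> bool:
    if end == "left":
        return block.span_a[0] <= margin
    return block.span_a[1] >= contig_length - margin


def order_contigs(
    candidates: Sequence[AdjacencyCandidate],
    end_labels: dict[tuple[str, str], str],
    n_chromosomes: int,
    reference_priority: Sequence[str],
    contig_lengths: dict[str, int],
    peri_flags: dict[str, bool] | None = None,
) -> ScaffoldResult:
    """Assemble contigs into exactly ``n_chromosomes`` paths.

    Constraints: every contig used once; each path starts and ends at a
    subtelomeric-labelled end; each path contains at least one
    pericentromeric-flagged contig (when flags are supplied).  Infeasible
    marker evidence is a hard error listing what is missing.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    contig_ids = sorted(contig_lengths)
    sub_ends = [e for e, lab in end_labels.items() if lab == "subtelomeric"]
    if len(sub_ends) < 2 * n_chromosomes:
        raise ValueError(
            f"infeasible: need >= {2 * n_chromosomes} subtelomeric contig ends "
            f"for {n_chromosomes} chromosomes, found {len(sub_ends)}: {sub_ends}"
        )

    conflicts: list[str] = []
    pruned = _resolve_reference_conflicts(candidates, reference_priority, conflicts)

    # aggregate surviving per-reference candidates into weighted edges
    edges: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    for c in pruned:
        edges[c.key] = edges.get(c.key, 0) + c.support
    edge_list = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))

    best = _search_path_cover(
        edge_list, contig_ids, end_labels, n_chromosomes, peri_flags or {}
    )
    if best is None:
        raise ValueError(
            "infeasible: no path cover satisfies the marker constraints "
            f"(edges={list(edges)}, subtelomeric ends={sub_ends})"
        )
    chosen, total, n_best = best

    paths = _edges_to_paths(chosen, contig_ids)
    paths = [_canonical_path(p) for p in paths]
    paths.sort(
        key=lambda p: -sum(contig_lengths[cid] for cid, _ in p)
    )
    assemblies = [
        ChromosomeAssembly(f"chr{i + 1}", p) for i, p in enumerate(paths)
    ]
    return ScaffoldResult(
        assemblies=assemblies,
        conflicts=conflicts,
        unique=(n_best == 1),
        alternatives=n_best - 1,
    )


def _resolve_reference_conflicts(
    candidates: Sequence[AdjacencyCandidate],
    reference_priority: Sequence[str],
    conflicts: list[str],
) -> list[AdjacencyCandidate]:
    """Where references propose different partners for one end, the earlier
    reference in the priority list wins; the disagreement is recorded."""
    prio = {r: i for i, r in enumerate(reference_priority)}

    partners: dict[tuple[str, str], dict[tuple[tuple, tuple], list[AdjacencyCandidate]]] = {}
    for c in candidates:
        for e in (c.end_1, c.end_2):
            partners.setdefault(e, {}).setdefault(c.key, []).append(c)

    dropped: set[int] = set()
    for end, by_key in sorted(partners.items()):
        if len(by_key) <= 1:
            continue
        refs_per_key = {
            k: {c.reference for c in cs} for k, cs in by_key.items()
        }
        if len(set().union(*refs_per_key.values())) <= 1:
            # one reference proposing several partners is ambiguity, not a
            # between-reference disagreement; the cover search reports it
            continue
        best = min(
            prio.get(r, len(prio)) for rs in refs_per_key.values() for r in rs
        )
        winners = {
            k for k, rs in refs_per_key.items()
            if any(prio.get(r, len(prio)) == best for r in rs)
        }
        for k in sorted(set(by_key) - winners):
            for c in by_key[k]:
                dropped.add(id(c))
            conflicts.append(
                f"end {end}: kept {sorted(winners)}, dropped {k} "
                f"(reference priority)"
            )
    return [c for c in candidates if id(c) not in dropped]


def _edges_to_paths(
    chosen: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    contig_ids: Sequence[str],
) -> list[list[tuple[str, str]]]:
    """Turn selected end-end edges into oriented contig paths."""
    partner: dict[tuple[str, str], tuple[str, str]] = {}
    for e1, e2 in chosen:
        partner[e1] = e2
        partner[e2] = e1
    unvisited = set(contig_ids)
    paths = []
    # find path starts: contigs with a free end
    while unvisited:
        start = None
        for cid in sorted(unvisited):
            for end in ("left", "right"):
                if (cid, end) not in partner:
                    start = (cid, end)
                    break
            if start:
                break
        assert start is not None, "cycle in scaffold edges"
        path = []
        cid, entry_end = start
        while True:
            unvisited.discard(cid)
            orient = "+" if entry_end == "left" else "-"
            path.append((cid, orient))
            exit_end = "right" if entry_end == "left" else "left"
            nxt = partner.get((cid, exit_end))
            if nxt is None:
                break
            cid, entry_end = nxt
        paths.append(path)
    return paths


def _search_path_cover(
    edge_list: Sequence[tuple[tuple[tuple[str, str], tuple[str, str]], int]],
    contig_ids: Sequence[str],
    end_labels: dict[tuple[str, str], str],
    n_chromosomes: int,
    peri_flags: dict[str, bool],
) -> tuple[list, int, int] | None:
    """Greedy maximum-support path cover with constraint backtracking.

    Explores edge subsets in descending-support order, pruning states whose
    attainable support cannot beat the incumbent; counts how many distinct
    covers attain the maximum (to report ambiguity).
    """
    n_edges = len(edge_list)
    suffix = [0] * (n_edges + 1)
    for i in range(n_edges - 1, -1, -1):
        suffix[i] = suffix[i + 1] + edge_list[i][1]

    best: dict[str, object] = {"support": None, "edges": None, "count": 0}

    def feasible_final(used_edges: list) -> bool:
        paths = _edges_to_paths(used_edges, contig_ids)
        if len(paths) != n_chromosomes:
            return False
        for p in paths:
            first_cid, first_or = p[0]
            last_cid, last_or = p[-1]
            outer1 = (first_cid, "left" if first_or == "+" else "right")
            outer2 = (last_cid, "right" if last_or == "+" else "left")
            if end_labels.get(outer1, "internal") != "subtelomeric":
                return False
            if end_labels.get(outer2, "internal") != "subtelomeric":
                return False
            if peri_flags and not any(peri_flags.get(cid, False) for cid, _ in p):
                return False
        return True

    def recurse(i: int, used: list, degree: dict, comp: dict, total: int) -> None:
        if best["support"] is not None and total + suffix[i] < best["support"]:
            return
        if i == n_edges:
            if feasible_final(used):
                if best["support"] is None or total > best["support"]:
                    best.update(support=total, edges=list(used), count=1)
                elif total == best["support"]:
                    if used != best["edges"]:
                        best["count"] = best["count"] + 1  # type: ignore[operator]
            return
        (e1, e2), w = edge_list[i]
        # try taking the edge
        c1, c2 = e1[0], e2[0]
        root1, root2 = _find(comp, c1), _find(comp, c2)
        if (
            degree.get(e1, 0) == 0
            and degree.get(e2, 0) == 0
            and root1 != root2  # no cycles
        ):
            degree[e1] = degree[e2] = 1
            comp[root1] = root2
            used.append((e1, e2))
            recurse(i + 1, used, degree, comp, total + w)
            used.pop()
            comp[root1] = root1
            degree[e1] = degree[e2] = 0
        # try skipping the edge
        recurse(i + 1, used, degree, comp, total)

    comp = {cid: cid for cid in contig_ids}
    recurse(0, [], {}, comp, 0)
    if best["support"] is None:
        return None
    return best["edges"], best["support"], best["count"]  # type: ignore[return-value]


def _find(comp: dict, x: str) -> str:
    while comp[x] != x:
        x = comp[x]
    return x


def write_agp(
    assemblies: Sequence[ChromosomeAssembly], path: str | Path
) -> None:
    """AGP-like TSV: chromosome, order index, contig, orientation."""
    with open(path, "w") as fh:
        fh.write("chromosome\torder\tcontig\torientation\n")
        for asm in assemblies:
            for i, (cid, orient) in enumerate(asm.path, start=1):
                fh.write(f"{asm.name}\t{i}\t{cid}\t{orient}\n")


def export_assembled_fasta(
    assemblies: Sequence[ChromosomeAssembly],
    contigs: Genome,
    path: str | Path,
    spacer_n: int = 100,
) -> None:
    """Multi-FASTA of assembled chromosomes, contigs joined by N-spacers.

    Overlapping contig-end sequences are deliberately not merged; the spacer
    marks every junction explicitly.  The Genome carries no sequence, so
    placeholder records of the correct lengths are emitted — downstream
    coordinate arithmetic stays valid.
    """
    with open(path, "w") as fh:
        for asm in assemblies:
            parts = []
            for cid, orient in asm.path:
                c = contigs.contig(cid)
                parts.append("N" * c.length)
            joined = ("N" * spacer_n).join(parts)
            fh.write(f">{asm.name}\n")
            for i in range(0, len(joined), 80):
                fh.write(joined[i : i + 80] + "\n")
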