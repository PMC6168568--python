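"""End-to-end workflows over simulated data.

Each function wires the stage modules together the way the chromosome-level
study runs on real data: simulate (or load) a draft genome and assembled
references, infer orthologues from hit tables, chain them into blocks,
scaffold the draft, convert shared blocks to signed genomes, measure
rearrangement distances, and test breakpoint randomness.  These workflows are
what the CLI, the analysis scripts and the benchmark suites call; they return
plain results so callers decide what to write where.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from karyoevo.core_io import AnalysisConfig, Genome, SignedGenome
from karyoevo.orthology import (
    OrthologuePair,
    drop_multicopy,
    filter_by_synteny,
    infer_rbh,
)
from karyoevo.breakpoints import random_breakage_test
from karyoevo.rearrange import rearrangement_distance
from karyoevo.scaffold import (
    ScaffoldResult,
    build_adjacency_graph,
    classify_contig_ends,
    order_contigs,
    _canonical_path,
)
from karyoevo.simulate import (
    BlockGenome,
    FragmentationTruth,
    SimulationSpec,
    clustered_segment_lengths,
    emit_hit_tables,
    evolve,
    evolve_signed,
    fragment_genome,
    generate_ancestor,
    identity_signed_genome,
    junction_exclusion_zone,
    materialize,
    true_orthologue_map,
)
from karyoevo.synteny import SyntenyBlock, chain_anchors


def orthologues_from_hits(
    hits_ab,
    hits_ba,
    genome_a: Genome,
    genome_b: Genome,
    config: AnalysisConfig | None = None,
) -> list[OrthologuePair]:
    """The full orthologue curation: RBH, repeat/multi-copy removal, synteny
    support filtering."""
    cfg = config or AnalysisConfig()
    pairs = infer_rbh(hits_ab, hits_ba, evalue_max=cfg.evalue_max)
    pairs = drop_multicopy(pairs, genome_a, genome_b)
    return filter_by_synteny(
        pairs,
        genome_a,
        genome_b,
        min_neighbors=cfg.min_neighbors,
        window_genes=cfg.window_genes,
    )


def blocks_between(
    genome_a: Genome,
    genome_b: Genome,
    pairs: Sequence[OrthologuePair],
    config: AnalysisConfig | None = None,
) -> list[SyntenyBlock]:
    cfg = config or AnalysisConfig()
    return chain_anchors(
        pairs,
        genome_a,
        genome_b,
        max_gap_bp=cfg.max_anchor_gap_bp,
        min_anchors=cfg.min_block_anchors,
    )


@dataclass
class SimulatedStudy:
    """A simulated draft genome plus evolved, assembled references."""

    spec: SimulationSpec
    ancestor: BlockGenome
    query: Genome
    query_bg: BlockGenome
    truth: FragmentationTruth
    references: dict[str, Genome]
    reference_bgs: dict[str, BlockGenome]
    reference_ops: dict[str, list]
    hit_tables: dict[str, tuple[list, list]]


def simulate_study(
    seed: int,
    spec: SimulationSpec | None = None,
    reference_histories: dict[str, tuple[int, int]] | None = None,
    protect_junctions: int = 3,
) -> SimulatedStudy:
    """Generate the draft-vs-references study design.

    The draft (query) is the fragmented ancestor; each reference evolves from
    the ancestor by (n_inversions, n_translocations) from
    ``reference_histories`` (default: one close and one more distant
    relative, echoing the study's reference pair).  Reference breakpoints
    avoid a ``protect_junctions``-block window around the planted contig
    junctions so that every junction stays recoverable in principle.
    """
    spec = spec or SimulationSpec(rng_seed=seed)
    rng = np.random.default_rng(seed)
    histories = reference_histories or {
        "ref1": (spec.n_inversions, spec.n_translocations),
        "ref2": (spec.n_inversions * 3, spec.n_translocations + 1),
    }
    anc = generate_ancestor(spec, rng)
    frag, truth = fragment_genome(
        anc, spec.n_contigs, rng, min_blocks=spec.min_contig_blocks
    )
    zone = (
        junction_exclusion_zone(anc, truth, width=protect_junctions)
        if protect_junctions
        else set()
    )
    query = materialize(frag, "qry", contig_prefix="ctg",
                        gene_margin_bp=spec.gene_margin_bp)

    references: dict[str, Genome] = {}
    reference_bgs: dict[str, BlockGenome] = {}
    reference_ops: dict[str, list] = {}
    hit_tables: dict[str, tuple[list, list]] = {}
    for name in sorted(histories):
        n_inv, n_trans = histories[name]
        rspec = dc_replace(spec, n_inversions=n_inv, n_translocations=n_trans)
        ref_bg, ops = evolve(anc, rspec, rng, forbidden_adjacencies=zone)
        ref = materialize(ref_bg, name, contig_prefix="chr",
                          gene_margin_bp=spec.gene_margin_bp)
        omap = true_orthologue_map(frag, "qry", ref_bg, name)
        hit_tables[name] = emit_hit_tables(
            query, ref, omap, rng, decoy_rate=spec.decoy_rate
        )
        references[name] = ref
        reference_bgs[name] = ref_bg
        reference_ops[name] = ops
    return SimulatedStudy(
        spec=spec,
        ancestor=anc,
        query=query,
        query_bg=frag,
        truth=truth,
        references=references,
        reference_bgs=reference_bgs,
        reference_ops=reference_ops,
        hit_tables=hit_tables,
    )


@dataclass
class ScaffoldTrial:
    result: ScaffoldResult
    truth_paths: list[list[tuple[str, str]]]
    recovered: bool
    blocks: dict[str, list[SyntenyBlock]] = field(default_factory=dict)


def scaffold_study(
    study: SimulatedStudy, config: AnalysisConfig | None = None
) -> ScaffoldTrial:
    """Run orthology -> blocks -> adjacency graph -> path cover on a
    simulated study, and compare against the planted contig order."""
    cfg = config or AnalysisConfig()
    blocks_by_ref: dict[str, tuple[Genome, list[SyntenyBlock]]] = {}
    for name, ref in study.references.items():
        hits_ab, hits_ba = study.hit_tables[name]
        pairs = orthologues_from_hits(hits_ab, hits_ba, study.query, ref, cfg)
        blocks = blocks_between(study.query, ref, pairs, cfg)
        blocks_by_ref[name] = (ref, blocks)

    # reference priority: ascending whole-genome rearrangement distance,
    # measured from the shared blocks themselves
    from karyoevo.rearrange import blocks_to_signed_genomes

    distances = {}
    for name, (ref, blocks) in blocks_by_ref.items():
        sga, sgb = blocks_to_signed_genomes(blocks, study.query, ref)
        distances[name] = rearrangement_distance(sga, sgb)
    priority = sorted(distances, key=lambda n: (distances[n], n))

    end_labels = {}
    peri_flags = {}
    for contig in study.query.chromosomes:
        left, right, peri = classify_contig_ends(
            contig, margin_bp=cfg.subtelomere_margin_bp
        )
        end_labels[(contig.id, "left")] = left.label
        end_labels[(contig.id, "right")] = right.label
        peri_flags[contig.id] = peri

    candidates = build_adjacency_graph(
        study.query,
        blocks_by_ref,
        max_reference_gap_bp=cfg.max_reference_gap_bp,
        end_margin_bp=cfg.subtelomere_margin_bp,
    )
    result = order_contigs(
        candidates,
        end_labels,
        n_chromosomes=len(study.ancestor.chroms),
        reference_priority=priority,
        contig_lengths={c.id: c.length for c in study.query.chromosomes},
        peri_flags=peri_flags,
    )
    truth_paths = [_canonical_path(p) for p in study.truth.order]
    found = sorted(tuple(a.path) for a in result.assemblies)
    expect = sorted(tuple(p) for p in truth_paths)
    return ScaffoldTrial(
        result=result,
        truth_paths=truth_paths,
        recovered=(found == expect) and result.unique,
        blocks={n: b for n, (_, b) in blocks_by_ref.items()},
    )


def signed_genomes_for_assembly(
    assemblies,
    blocks: Sequence[SyntenyBlock],
    genome_b: Genome,
) -> tuple[SignedGenome, SignedGenome]:
    """Number blocks along the assembled query chromosomes (all +) and derive
    the reference's induced signed order.

    A contig placed in '-' orientation contributes its blocks in reverse
    order with flipped relative signs."""
    numbered: list[tuple[SyntenyBlock, int]] = []  # (block, composed sign)
    chroms_a: list[list[int]] = []
    k = 0
    for asm in assemblies:
        row = []
        for cid, orient in asm.path:
            cb = sorted(
                (b for b in blocks if b.contig_a == cid), key=lambda b: b.span_a
            )
            flip = orient == "-"
            if flip:
                cb = list(reversed(cb))
            for b in cb:
                k += 1
                rel = (1 if b.sign == "+" else -1) * (-1 if flip else 1)
                numbered.append((b, rel))
                row.append(k)
        if row:
            chroms_a.append(row)

    marker = {id(b): i + 1 for i, (b, _) in enumerate(numbered)}
    rels = {id(b): rel for (b, rel) in numbered}
    chroms_b: list[list[int]] = []
    for c in genome_b.chromosomes:
        on_b = sorted(
            (b for b, _ in numbered if b.contig_b == c.id),
            key=lambda b: b.span_b,
        )
        row = [marker[id(b)] * rels[id(b)] for b in on_b]
        if row:
            chroms_b.append(row)
    return SignedGenome(chroms_a), SignedGenome(chroms_b)


def scaffold_recovery_rate(
    n_seeds: int = 50,
    seed0: int = 0,
    spec: SimulationSpec | None = None,
) -> float:
    """Fraction of seeded simulations whose planted contig order+orientation
    is recovered exactly (up to whole-chromosome reflection)."""
    hits = 0
    for s in range(n_seeds):
        study = simulate_study(seed0 + s, spec=spec)
        if scaffold_study(study).recovered:
            hits += 1
    return hits / n_seeds


def distance_recovery_rate(
    n_seeds: int = 100,
    n_blocks: int = 500,
    n_chromosomes: int = 3,
    n_inversions: int = 10,
    n_translocations: int = 10,
    seed0: int = 0,
) -> float:
    """Fraction of seeds where the DCJ distance equals the planted operation
    count (breakpoint reuse at this block density is rare); the distance
    never exceeds the count."""
    k = n_inversions + n_translocations
    hits = 0
    base = identity_signed_genome(n_blocks, n_chromosomes)
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        derived, _ = evolve_signed(base, n_inversions, n_translocations, rng)
        d = rearrangement_distance(base, derived)
        if d > k:
            raise AssertionError("distance exceeded planted history length")
        if d == k:
            hits += 1
    return hits / n_seeds


def breakage_calibration(
    n_seeds: int = 500,
    n_segments: int = 200,
    bootstrap_reps: int = 499,
    alpha: float = 0.05,
    mean_bp: float = 500_000.0,
    seed0: int = 0,
) -> tuple[float, np.ndarray]:
    """Null calibration of the random-breakage test: exponential segment
    lengths should be rejected at ~alpha.  Returns (rejection rate, p-values)."""
    pvals = np.empty(n_seeds)
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        lengths = rng.exponential(mean_bp, size=n_segments)
        res = random_breakage_test(
            lengths, bootstrap_reps=bootstrap_reps, rng_seed=seed0 + 100_000 + s
        )
        pvals[s] = res.p_value
    return float(np.mean(pvals < alpha)), pvals


def breakage_power(
    n_seeds: int = 200,
    n_segments: int = 200,
    bootstrap_reps: int = 499,
    alpha: float = 0.05,
    mean_bp: float = 500_000.0,
    seed0: int = 0,
) -> float:
    """Power against the repeat-clustered (two-point mixture) alternative."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        lengths = clustered_segment_lengths(n_segments, mean_bp, rng)
        res = random_breakage_test(
            lengths, bootstrap_reps=bootstrap_reps, rng_seed=seed0 + 200_000 + s
        )
        if res.p_value < alpha:
            hits += 1
    return hits / n_seeds
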