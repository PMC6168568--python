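"""Domain types, coordinate conventions, and on-disk format readers/writers.

Internal coordinates are 0-based half-open everywhere.  GFF3 (1-based closed)
is converted at the I/O boundary and only there.  Marker classes (subtelomeric,
pericentromeric, rDNA, tRNA) come from a curated sidecar table rather than
free-text GFF attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("karyoevo")

MARKER_CLASSES = (
    "subtelomeric",
    "pericentromeric",
    "rdna5S",
    "rdna_large",
    "trna",
    "none",
)


@dataclass(frozen=True)
class Gene:
    """An annotated gene on a contig; span is 0-based half-open."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    marker_class: str = "none"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.id}: invalid span [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(
                f"gene {self.id}: unknown marker class {self.marker_class!r}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class Contig:
    """A contig/supercontig/chromosome with its ordered gene annotation."""

    id: str
    length: int
    genes: list[Gene] = field(default_factory=list)
    orientation_flag: str = "+"

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.contig_id != self.id:
                raise ValueError(
                    f"gene {g.id} claims contig {g.contig_id}, found on {self.id}"
                )
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.id} exceeds contig {self.id} bounds "
                    f"({g.end} > {self.length})"
                )

    def flipped(self) -> "Contig":
        """Reverse-complement view; gene strands recomputed on the fly."""
        genes = [
            replace(
                g,
                start=self.length - g.end,
                end=self.length - g.start,
                strand="-" if g.strand == "+" else "+",
            )
            for g in reversed(self.genes)
        ]
        flag = "-" if self.orientation_flag == "+" else "+"
        return Contig(self.id, self.length, genes, orientation_flag=flag)


@dataclass
class Genome:
    """A haploid genome: an ordered collection of contigs or chromosomes."""

    name: str
    chromosomes: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.name}: duplicate contig ids")
        gene_ids = [g.id for c in self.chromosomes for g in c.genes]
        if len(gene_ids) != len(set(gene_ids)):
            raise ValueError(f"genome {self.name}: duplicate gene ids")

    def contig(self, contig_id: str) -> Contig:
        for c in self.chromosomes:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def genes(self) -> list[Gene]:
        return [g for c in self.chromosomes for g in c.genes]

    def gene_index(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}

    @property
    def size_bp(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True)
class HitRecord:
    """One row of a pairwise protein-similarity hit table."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class SignedGenome:
    """A genome abstracted to chromosomes of signed integer marker ids."""

    chromosomes: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for chrom in self.chromosomes:
            for m in chrom:
                if m == 0:
                    raise ValueError("marker id 0 is not allowed")
                if abs(m) in seen:
                    raise ValueError(f"duplicate marker id {abs(m)}")
                seen.add(abs(m))

    @property
    def markers(self) -> set[int]:
        return {abs(m) for chrom in self.chromosomes for m in chrom}

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def canonical(self) -> "SignedGenome":
        """Canonical form: each chromosome oriented to its lexicographically
        smaller reading, chromosomes sorted; reflection- and order-invariant."""
        chroms = []
        for chrom in self.chromosomes:
            fwd = tuple(chrom)
            rev = tuple(-m for m in reversed(chrom))
            chroms.append(list(min(fwd, rev)))
        chroms.sort()
        return SignedGenome(chroms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGenome):
            return NotImplemented
        return self.chromosomes == other.chromosomes


@dataclass
class AnalysisConfig:
    """Thresholds shared across the pipeline stages.

    evalue_max: reciprocal-best-hit E-value ceiling (1e-3, the search setting
        the whole orthologue set is built under).
    min_block_anchors: minimum anchors per collinear block (the block-weight
        criterion expressed in anchor counts).
    max_anchor_gap_bp: maximum gap between consecutive anchors of a chain, on
        both genomes.
    gross_min_block_bp: blocks strictly larger than this count as "gross"
        (large-scale) synteny; 20 kb.
    breakpoint_margin_bp: feature-association margin around breakpoint regions.
    subtelomere_margin_bp: distance from a contig end within which subtelomeric
        markers label the end, and within which gross blocks are excluded.
    bootstrap_reps: parametric-bootstrap replicates for the breakage test.
    """

    evalue_max: float = 1e-3
    min_block_anchors: int = 3
    max_anchor_gap_bp: int = 30_000
    min_block_weight: int = 40
    gross_min_block_bp: int = 20_000
    breakpoint_margin_bp: int = 5_000
    subtelomere_margin_bp: int = 50_000
    max_reference_gap_bp: int = 50_000
    min_neighbors: int = 1
    window_genes: int = 5
    bootstrap_reps: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "evalue_max",
            "min_block_anchors",
            "max_anchor_gap_bp",
            "min_block_weight",
            "gross_min_block_bp",
            "breakpoint_margin_bp",
            "subtelomere_margin_bp",
            "max_reference_gap_bp",
            "min_neighbors",
            "window_genes",
            "bootstrap_reps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_marker_table(path: str | Path) -> dict[str, str]:
    """Read a curated gene_id -> marker class TSV (two columns, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "class"],
                     dtype=str, comment="#")
    table = {}
    for row in df.itertuples(index=False):
        if row[1] not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {row[1]!r} for {row[0]}")
        table[str(row[0])] = str(row[1])
    return table


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    marker_table: str | Path | None = None,
    name: str | None = None,
) -> Genome:
    """Assemble a Genome from FASTA sequences, GFF3 gene lines and an optional
    marker-class sidecar table.

    GFF3 intervals (1-based closed) are converted to 0-based half-open here.
    A gene on a seqid absent from the FASTA, or exceeding its contig length,
    is a hard error naming the offending gene.
    """
    lengths: dict[str, int] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        lengths[rec.id] = len(rec.seq)
        order.append(rec.id)

    markers = read_marker_table(marker_table) if marker_table else {}

    genes_by_contig: dict[str, list[Gene]] = {cid: [] for cid in order}
    gff_text = Path(gff_path).read_text()
    if gff_text.strip():
        db = gffutils.create_db(
            gff_text, dbfn=":memory:", from_string=True,
            merge_strategy="create_unique", keep_order=True,
        )
        for feat in db.all_features():
            if feat.featuretype not in ("gene", "tRNA_gene", "rRNA_gene"):
                continue
            gid = feat.attributes.get("ID", [feat.id])[0]
            if feat.seqid not in lengths:
                raise ValueError(
                    f"gene {gid} annotated on unknown contig {feat.seqid}"
                )
            start0, end0 = feat.start - 1, feat.end  # GFF3 -> half-open
            if end0 > lengths[feat.seqid]:
                raise ValueError(
                    f"gene {gid} exceeds contig {feat.seqid} bounds "
                    f"({end0} > {lengths[feat.seqid]})"
                )
            genes_by_contig[feat.seqid].append(
                Gene(
                    id=gid,
                    contig_id=feat.seqid,
                    start=start0,
                    end=end0,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    marker_class=markers.get(gid, "none"),
                )
            )

    contigs = [Contig(cid, lengths[cid], genes_by_contig[cid]) for cid in order]
    return Genome(name or Path(fasta_path).stem, contigs)


def write_genome_gff(genome: Genome, path: str | Path) -> None:
    """Write gene annotations as GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.chromosomes:
            fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for c in genome.chromosomes:
            for g in c.genes:
                ftype = {
                    "trna": "tRNA_gene",
                    "rdna5S": "rRNA_gene",
                    "rdna_large": "rRNA_gene",
                }.get(g.marker_class, "gene")
                fh.write(
                    f"{c.id}\tkaryoevo\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.id}\n"
                )


def write_genome_fasta(
    genome: Genome, path: str | Path, rng_seed: int = 0
) -> None:
    """Emit one random-nucleotide record per contig (coordinates, not sequence,
    carry the analysis; the sequence is a placeholder of the right length)."""
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    alphabet = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for c in genome.chromosomes:
            seq = "".join(rng.choice(alphabet, size=c.length))
            fh.write(f">{c.id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_marker_table(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            if g.marker_class != "none":
                fh.write(f"{g.id}\t{g.marker_class}\n")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a TSV hit table (query, subject, evalue, bitscore); malformed rows
    are rejected with a logged count."""
    hits: list[HitRecord] = []
    bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                q, s, ev, bs = parts[0], parts[1], float(parts[2]), float(parts[3])
                hits.append(HitRecord(q, s, ev, bs))
            except (IndexError, ValueError):
                bad += 1
    if bad:
        logger.warning("rejected %d malformed hit rows in %s", bad, path)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.evalue:.6g}\t{h.bitscore:.6g}\n")


def write_signed_genome(g: SignedGenome, path: str | Path, name: str = "genome") -> None:
    """Serialize to the GRIMM genome text format: one '>'-named genome, one
    line per chromosome, signed integers space-separated, '$'-terminated."""
    seen: set[int] = set()
    for chrom in g.chromosomes:
        for m in chrom:
            if abs(m) in seen:
                raise ValueError(f"duplicate marker id {abs(m)}")
            seen.add(abs(m))
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for chrom in g.chromosomes:
            fh.write(" ".join(str(m) for m in chrom) + " $\n" if chrom else "$\n")


def read_signed_genome(path: str | Path) -> SignedGenome:
    chroms: list[list[int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(">") or line.startswith("#"):
            continue
        tokens = line.split()
        if tokens and tokens[-1] == "$":
            tokens = tokens[:-1]
        if tokens:
            chroms.append([int(t) for t in tokens])
        elif line == "$":
            chroms.append([])
    return SignedGenome([c for c in chroms if c])


def concatenated_offsets(genome: Genome) -> dict[str, int]:
    """Cumulative bp offset of each contig on a single concatenated axis."""
    offsets: dict[str, int] = {}
    total = 0
    for c in genome.chromosomes:
        offsets[c.id] = total
        total += c.length
    return offsets
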