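"""Genomes, genes, operons and upstream regions.

This module holds the coordinate conventions every downstream step relies
on: 1-based inclusive gene coordinates (GFF3 style), operons as maximal
runs of co-directional adjacent genes, and upstream regions reported on
the coding strand in a window anchored at the translation start.

Upstream-region offsets are 0-based within the extracted sequence; the
genomic position of the translation start is carried alongside so that
site calls can be mapped back to genome coordinates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Gene:
    """A protein-coding gene on one replicon, 1-based inclusive coordinates."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    protein: str = ""
    product: str = ""
    is_tf: bool = False
    tf_family: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")


@dataclass
class Genome:
    """One annotated genome: replicon sequences plus an ordered gene list."""

    id: str
    lineage: str
    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id} in genome {self.id}")
            seen.add(g.id)
            if g.replicon not in self.sequences:
                raise ValueError(f"gene {g.id}: unknown replicon {g.replicon}")
            if g.end > len(self.sequences[g.replicon]):
                raise ValueError(f"gene {g.id}: end {g.end} outside replicon")
        self.genes.sort(key=lambda g: (g.replicon, g.start, g.end))

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def proteome(self) -> dict[str, str]:
        return {g.id: g.protein for g in self.genes if g.protein}


@dataclass
class Operon:
    """Run of same-strand, consecutive genes transcribed from one promoter."""

    id: str
    genome: str
    replicon: str
    strand: str
    genes: list[str]
    lead_gene: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("operon must contain at least one gene")


@dataclass
class UpstreamRegion:
    """Coding-strand sequence around a translation start.

    ``offset_of_start`` is the genomic coordinate (1-based) of the first
    base of the start codon.  ``sequence[i]`` sits at upstream offset
    ``i - n_upstream`` relative to the start codon, with offset -1 the
    base immediately 5' of it.
    """

    operon: str
    genome: str
    sequence: str
    offset_of_start: int
    window: tuple[int, int]
    strand: str
    n_upstream: int
    empty: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSet:
    """The universe of an analysis: genomes partitioned into named lineages."""

    genomes: dict[str, Genome]

    @property
    def lineages(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, g in self.genomes.items():
            out.setdefault(g.lineage, []).append(gid)
        return {k: sorted(v) for k, v in out.items()}

    def lineage_genomes(self, lineage: str) -> list[Genome]:
        return [g for g in self.genomes.values() if g.lineage == lineage]

    def __iter__(self):
        return iter(self.genomes.values())

    def __len__(self) -> int:
        return len(self.genomes)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, _, v = chunk.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_genome(
    annotation_path: str | Path,
    fasta_path: str | Path,
    genome_id: str | None = None,
    lineage: str = "",
) -> Genome:
    """Read a genome from GFF3+FASTA or from a TSV gene table+FASTA.

    The annotation format is chosen by extension (``.tsv`` vs GFF3
    otherwise).  Records that violate the gene invariants are skipped
    with a warning and counted on ``Genome.n_skipped_records``.
    """
    annotation_path = Path(annotation_path)
    fasta_path = Path(fasta_path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)

    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    gid = genome_id or annotation_path.stem

    if annotation_path.suffix == ".tsv":
        genes, skipped = _genes_from_tsv(annotation_path, sequences)
        if genome_id is None:
            with open(annotation_path) as fh:
                reader = csv.DictReader(fh, delimiter="\t")
                row = next(iter(reader), None)
            if row and row.get("genome_id"):
                gid = row["genome_id"]
    else:
        genes, skipped = _genes_from_gff(annotation_path, sequences)

    genome = Genome(id=gid, lineage=lineage, sequences=sequences, genes=genes)
    genome.n_skipped_records = skipped
    return genome


def _genes_from_gff(path: Path, sequences: dict[str, str]) -> tuple[list[Gene], int]:
    genes, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            seqid, _, _, start_s, end_s, _, strand, _, attr_s = parts
            attrs = _parse_gff_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            try:
                start, end = int(start_s), int(end_s)
                if gene_id is None:
                    raise ValueError("no ID/locus_tag")
                if seqid not in sequences:
                    raise ValueError(f"unknown replicon {seqid}")
                if end > len(sequences[seqid]) or start < 1:
                    raise ValueError("coordinates outside replicon")
                protein = attrs.get("translation", "")
                if not protein:
                    cds = sequences[seqid][start - 1 : end]
                    if strand == "-":
                        cds = reverse_complement(cds)
                    protein = str(Seq(cds).translate(to_stop=True))
                gene = Gene(
                    id=gene_id,
                    replicon=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=protein,
                    product=attrs.get("product", ""),
                    is_tf=attrs.get("is_tf", "") in ("1", "true", "True"),
                    tf_family=attrs.get("tf_family") or None,
                )
            except (ValueError, KeyError) as exc:
                log.warning("%s:%d skipped CDS record: %s", path.name, lineno, exc)
                skipped += 1
                continue
            genes.append(gene)
    return genes, skipped


def _genes_from_tsv(path: Path, sequences: dict[str, str]) -> tuple[list[Gene], int]:
    genes, skipped = [], 0
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            try:
                replicon = row["replicon"]
                start, end = int(row["start"]), int(row["end"])
                if replicon not in sequences or end > len(sequences[replicon]) or start < 1:
                    raise ValueError("coordinates outside replicon")
                gene = Gene(
                    id=row["gene_id"],
                    replicon=replicon,
                    start=start,
                    end=end,
                    strand=row["strand"],
                    protein=row.get("protein", ""),
                    product=row.get("product", ""),
                    is_tf=row.get("is_tf", "") in ("1", "true", "True"),
                    tf_family=row.get("tf_family") or None,
                )
            except (ValueError, KeyError) as exc:
                log.warning("%s skipped gene row: %s", path.name, exc)
                skipped += 1
                continue
            genes.append(gene)
    return genes, skipped


def write_genome(
    genome: Genome,
    gff_path: str | Path,
    fasta_path: str | Path,
    protein_path: str | Path | None = None,
) -> None:
    """Write GFF3 + genomic FASTA (+ optional protein FASTA) for a genome."""
    with open(fasta_path, "w") as fh:
        for rep, seq in sorted(genome.sequences.items()):
            fh.write(f">{rep}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep, seq in sorted(genome.sequences.items()):
            fh.write(f"##sequence-region {rep} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = [f"ID={g.id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.protein:
                attrs.append(f"translation={g.protein}")
            if g.is_tf:
                attrs.append("is_tf=1")
            if g.tf_family:
                attrs.append(f"tf_family={g.tf_family}")
            fh.write(
                f"{g.replicon}\tregulonkit\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                + ";".join(attrs)
                + "\n"
            )
    if protein_path is not None:
        with open(protein_path, "w") as fh:
            for g in genome.genes:
                if g.protein:
                    fh.write(f">{g.id}\n{g.protein}\n")


def write_operons_gff(operons: list[Operon], genome: Genome, path: str | Path) -> None:
    by_id = {g.id: g for g in genome.genes}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for op in operons:
            genes = [by_id[g] for g in op.genes]
            start = min(g.start for g in genes)
            end = max(g.end for g in genes)
            fh.write(
                f"{op.replicon}\tregulonkit\toperon\t{start}\t{end}\t.\t{op.strand}\t.\t"
                f"ID={op.id};genes={','.join(op.genes)}\n"
            )


def write_upstream_fasta(regions: list[UpstreamRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.empty:
                continue
            fh.write(f">{r.genome}|{r.operon}|{r.window[0]},{r.window[1]}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# operon prediction and upstream extraction


def predict_operons(genome: Genome, max_intergenic_gap: int = 100) -> list[Operon]:
    """Group adjacent genes into operons.

    Two neighbouring genes join the same operon iff they sit on the same
    replicon and strand and the intergenic gap is at most
    ``max_intergenic_gap``.  Every protein-coding gene ends up in exactly
    one operon; a gene with no eligible neighbour forms a singleton.
    """
    operons: list[Operon] = []
    run: list[Gene] = []

    def _flush() -> None:
        if not run:
            return
        lead = run[0] if run[0].strand == "+" else run[-1]
        genes = [g.id for g in run] if run[0].strand == "+" else [g.id for g in reversed(run)]
        operons.append(
            Operon(
                id=f"{genome.id}:opn{len(operons) + 1:04d}",
                genome=genome.id,
                replicon=run[0].replicon,
                strand=run[0].strand,
                genes=genes,
                lead_gene=lead.id,
            )
        )

    for g in genome.genes:  # genes are kept coordinate-sorted by Genome
        if run and (
            g.replicon != run[-1].replicon
            or g.strand != run[-1].strand
            or g.start - run[-1].end - 1 > max_intergenic_gap
        ):
            _flush()
            run = []
        run.append(g)
    _flush()
    return operons


def extract_upstream(
    operon: Operon,
    genome: Genome,
    upstream_bp: int = 300,
    downstream_bp: int = 25,
    truncate_at_upstream_gene: bool = True,
) -> UpstreamRegion:
    """Extract the coding-strand sequence around an operon's translation start.

    The window runs from ``upstream_bp`` bases 5' of the lead gene's start
    codon to ``downstream_bp`` bases into it, clipped at replicon edges
    and, when ``truncate_at_upstream_gene`` is set, at the 3' boundary of
    the nearest upstream gene (so neighbouring coding sequence is never
    scanned).
    """
    if operon.genome != genome.id:
        raise ValueError(f"operon {operon.id} does not belong to genome {genome.id}")
    lead = genome.gene(operon.lead_gene)
    seq = genome.sequences[lead.replicon]
    length = len(seq)
    members = set(operon.genes)

    if lead.strand == "+":
        lo = lead.start - upstream_bp
        hi = lead.start + downstream_bp - 1
        if truncate_at_upstream_gene:
            bounds = [g.end for g in genome.genes
                      if g.replicon == lead.replicon and g.id not in members and g.end < lead.start]
            if bounds:
                lo = max(lo, max(bounds) + 1)
        lo, hi = max(lo, 1), min(hi, length)
        region_seq = seq[lo - 1 : hi] if lo <= hi else ""
        n_upstream = lead.start - lo if region_seq else 0
        start_coord = lead.start
    else:
        lo = lead.end - downstream_bp + 1
        hi = lead.end + upstream_bp
        if truncate_at_upstream_gene:
            bounds = [g.start for g in genome.genes
                      if g.replicon == lead.replicon and g.id not in members and g.start > lead.end]
            if bounds:
                hi = min(hi, min(bounds) - 1)
        lo, hi = max(lo, 1), min(hi, length)
        region_seq = reverse_complement(seq[lo - 1 : hi]) if lo <= hi else ""
        n_upstream = hi - lead.end if region_seq else 0
        start_coord = lead.end

    return UpstreamRegion(
        operon=operon.id,
        genome=genome.id,
        sequence=region_seq,
        offset_of_start=start_coord,
        window=(upstream_bp, downstream_bp),
        strand=lead.strand,
        n_upstream=n_upstream,
        empty=not region_seq,
    )
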