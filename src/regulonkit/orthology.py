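"""Cross-genome ortholog clustering of proteins.

The clustering follows the classic bidirectional-best-hit (BBH) recipe:
all-vs-all local protein alignment, reciprocal best hits kept when
identity exceeds 50% and the aligned region covers more than two thirds
of the shorter protein, same-genome paralogs attached when they are more
similar to a cluster member than that member is to its BBH partner, and
finally transitive merging of clusters that share genes.

Alignment is affine-gap Smith-Waterman with BLOSUM62 (gap open 11,
extend 1) via Bio.Align.PairwiseAligner.  An exact alignment of every
protein pair is wasteful at scale, so candidate pairs are pre-screened by
shared 5-mer count (two unrelated proteins essentially never share two
distinct 5-mers; homologs above ~50% identity share many).  Externally
computed hits in 12-column tabular format can be substituted for the
built-in aligner.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .genomes import GenomeSet

log = logging.getLogger(__name__)

GeneKey = tuple[str, str]  # (genome id, gene id)


@dataclass
class SimilarityHit:
    query_genome: str
    query: str
    subject_genome: str
    subject: str
    identity: float
    aligned_length: int
    score: float
    query_length: int
    subject_length: int

    @property
    def query_key(self) -> GeneKey:
        return (self.query_genome, self.query)

    @property
    def subject_key(self) -> GeneKey:
        return (self.subject_genome, self.subject)


@dataclass
class AlignerConfig:
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"
    # reporting floor: local alignments of unrelated proteins routinely
    # reach 30% identity over short stretches, so the floor is a joint
    # identity + coverage + score condition; the score floor sits above
    # the maximum observed on a seeded null of 1000 random protein pairs
    min_identity: float = 0.30
    min_coverage: float = 1 / 3
    min_score: float = 75.0
    kmer_prescreen: int | None = 2  # min shared distinct 5-mers; None disables
    kmer_size: int = 5


@dataclass
class OrthologGroup:
    """A cross-genome cluster of genes, with per-lineage conservation."""

    id: str
    members: dict[str, set[str]]  # genome id -> gene ids
    conservation: dict[str, str] = field(default_factory=dict)

    @property
    def genomes(self) -> set[str]:
        return {g for g, genes in self.members.items() if genes}

    @property
    def gene_keys(self) -> set[GeneKey]:
        return {(g, x) for g, genes in self.members.items() for x in genes}

    def presence_profile(self, genome_ids: list[str]) -> list[int]:
        return [1 if self.members.get(g) else 0 for g in genome_ids]

    def __len__(self) -> int:
        return sum(len(v) for v in self.members.values())


def _make_aligner(config: AlignerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_pair(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[float, int, int]:
    """Best local alignment of two proteins.

    Returns (score, aligned residue pairs, identical pairs).  Gap columns
    do not count toward the aligned length.
    """
    alignments = aligner.align(a, b)
    if len(alignments) == 0:
        return 0.0, 0, 0
    aln = alignments[0]
    aligned = identical = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        aligned += qe - qs
        identical += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
    return float(aln.score), aligned, identical


def all_vs_all_similarity(
    proteomes: dict[str, dict[str, str]],
    config: AlignerConfig | None = None,
    include_intra_genome: bool = True,
) -> list[SimilarityHit]:
    """All-vs-all protein similarity across (and within) genomes.

    Emits one hit per ordered pair above the reporting floor, so both
    directions of every alignment are present in the result.
    """
    config = config or AlignerConfig()
    proteomes = dict(proteomes)
    for gid in list(proteomes):
        if not proteomes[gid]:
            log.warning("genome %s has an empty proteome; excluded", gid)
            del proteomes[gid]
    if len(proteomes) < 2:
        raise ValueError("need at least 2 genomes with non-empty proteomes")

    aligner = _make_aligner(config)
    entries: list[tuple[str, str, str]] = [
        (gid, gene, seq)
        for gid in sorted(proteomes)
        for gene, seq in sorted(proteomes[gid].items())
    ]
    kmer_sets = (
        [_kmers(seq, config.kmer_size) for _, _, seq in entries]
        if config.kmer_prescreen is not None
        else None
    )

    hits: list[SimilarityHit] = []
    for i, j in itertools.combinations(range(len(entries)), 2):
        gi, genei, seqi = entries[i]
        gj, genej, seqj = entries[j]
        if gi == gj and not include_intra_genome:
            continue
        if kmer_sets is not None and len(kmer_sets[i] & kmer_sets[j]) < config.kmer_prescreen:
            continue
        score, aligned, identical = align_pair(aligner, seqi, seqj)
        if aligned == 0:
            continue
        identity = identical / aligned
        shorter = min(len(seqi), len(seqj))
        if (
            identity < config.min_identity
            or aligned < config.min_coverage * shorter
            or score < config.min_score
        ):
            continue
        hits.append(
            SimilarityHit(gi, genei, gj, genej, identity, aligned, score, len(seqi), len(seqj))
        )
        hits.append(
            SimilarityHit(gj, genej, gi, genei, identity, aligned, score, len(seqj), len(seqi))
        )
    return hits


def read_tabular_hits(path: str | Path, gene_genome: dict[str, str],
                      lengths: dict[str, int]) -> list[SimilarityHit]:
    """Read hits from 12-column tabular output of an external aligner.

    Columns: query, subject, %identity, aln_length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore.
    """
    hits = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            q, s = row[0], row[1]
            hits.append(
                SimilarityHit(
                    query_genome=gene_genome[q],
                    query=q,
                    subject_genome=gene_genome[s],
                    subject=s,
                    identity=float(row[2]) / 100.0,
                    aligned_length=int(row[3]),
                    score=float(row[11]),
                    query_length=lengths[q],
                    subject_length=lengths[s],
                )
            )
    return hits


def _best_hits(hits: list[SimilarityHit]) -> dict[tuple[GeneKey, str], SimilarityHit]:
    """Best cross-genome hit per (query gene, subject genome).

    Ties on score break to the lexicographically smallest subject id.
    """
    best: dict[tuple[GeneKey, str], SimilarityHit] = {}
    for h in hits:
        if h.query_genome == h.subject_genome:
            continue
        key = (h.query_key, h.subject_genome)
        cur = best.get(key)
        if cur is None or h.score > cur.score or (h.score == cur.score and h.subject < cur.subject):
            best[key] = h
    return best


def find_bbh_pairs(
    hits: list[SimilarityHit],
    min_identity: float = 0.50,
    min_coverage: float = 2 / 3,
) -> set[frozenset[GeneKey]]:
    """Reciprocal best hits passing the identity and coverage rules.

    A pair is kept iff each gene is the other's best-scoring hit in its
    genome, identity is strictly above ``min_identity``, and the aligned
    region is strictly longer than ``min_coverage`` times the shorter
    protein's length.
    """
    best = _best_hits(hits)
    pairs: set[frozenset[GeneKey]] = set()
    for (qkey, sgenome), h in best.items():
        skey = h.subject_key
        back = best.get((skey, h.query_genome))
        if back is None or back.subject_key != qkey:
            continue
        shorter = min(h.query_length, h.subject_length)
        if h.identity > min_identity and h.aligned_length > min_coverage * shorter:
            pairs.add(frozenset((qkey, skey)))
    return pairs


def attach_paralogs(
    bbh_pairs: set[frozenset[GeneKey]],
    hits: list[SimilarityHit],
) -> list[set[GeneKey]]:
    """Grow each BBH pair with same-genome paralogs.

    A paralog p of cluster member a joins the cluster when p is more
    similar to a than a is to its BBH partner; similarity is compared on
    alignment score, ties broken by identity.
    """
    intra: dict[GeneKey, list[SimilarityHit]] = {}
    by_pair: dict[frozenset[GeneKey], SimilarityHit] = {}
    for h in hits:
        if h.query_genome == h.subject_genome:
            intra.setdefault(h.query_key, []).append(h)
        else:
            key = frozenset((h.query_key, h.subject_key))
            cur = by_pair.get(key)
            if cur is None or h.score > cur.score:
                by_pair[key] = h
    seeds: list[set[GeneKey]] = []
    for pair in sorted(bbh_pairs, key=sorted):
        a, b = sorted(pair)
        seed = {a, b}
        anchor = by_pair.get(pair)
        if anchor is not None:
            for member in (a, b):
                for h in intra.get(member, []):
                    if (h.score, h.identity) > (anchor.score, anchor.identity):
                        seed.add(h.subject_key)
        seeds.append(seed)
    return seeds


def merge_clusters(cluster_seeds: list[set[GeneKey]]) -> list[OrthologGroup]:
    """Union clusters sharing at least one gene, to fixpoint.

    The result partitions the clustered genes; groups are numbered in
    order of their smallest member for determinism.
    """
    graph = nx.Graph()
    for seed in cluster_seeds:
        members = sorted(seed)
        graph.add_nodes_from(members)
        graph.add_edges_from(zip(members, members[1:]))
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    groups = []
    for idx, comp in enumerate(components, 1):
        members: dict[str, set[str]] = {}
        for genome, gene in comp:
            members.setdefault(genome, set()).add(gene)
        groups.append(OrthologGroup(id=f"OG{idx:04d}", members=members))
    return groups


def classify_conservation(group: OrthologGroup, genome_set: GenomeSet, lineage: str) -> str:
    """Conservation class of a group within one lineage.

    universal = present in all genomes of the lineage; conserved = in
    more than half (but not all); sporadic = in 2 up to half; unique =
    exactly 1; absent otherwise.
    """
    lineage_ids = genome_set.lineages.get(lineage, [])
    if not lineage_ids:
        raise ValueError(f"lineage {lineage!r} has no genomes")
    n = len(lineage_ids)
    present = sum(1 for g in lineage_ids if group.members.get(g))
    if present == 0:
        return "absent"
    if present == n:
        return "universal"
    if present > n / 2:
        return "conserved"
    if present >= 2:
        return "sporadic"
    return "unique"


def build_ortholog_groups(
    genome_set: GenomeSet,
    config: AlignerConfig | None = None,
    min_identity: float = 0.50,
    min_coverage: float = 2 / 3,
    tf_only: bool = False,
) -> tuple[list[OrthologGroup], list[SimilarityHit]]:
    """End-to-end clustering: similarity, BBH, paralogs, merge, classify.

    With ``tf_only`` the proteome is restricted to genes flagged as TFs,
    mirroring a census computed on regulator sets alone.
    """
    proteomes = {}
    for genome in genome_set:
        prot = {
            g.id: g.protein
            for g in genome.genes
            if g.protein and (g.is_tf or not tf_only)
        }
        proteomes[genome.id] = prot
    hits = all_vs_all_similarity(proteomes, config)
    pairs = find_bbh_pairs(hits, min_identity=min_identity, min_coverage=min_coverage)
    seeds = attach_paralogs(pairs, hits)
    groups = merge_clusters(seeds)
    for grp in groups:
        for lineage in genome_set.lineages:
            grp.conservation[lineage] = classify_conservation(grp, genome_set, lineage)
    return groups, hits


def groups_to_tsv(groups: list[OrthologGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_id", "genome_id", "gene_id", "conservation"])
        for grp in groups:
            cons = ";".join(f"{k}={v}" for k, v in sorted(grp.conservation.items()))
            for genome in sorted(grp.members):
                for gene in sorted(grp.members[genome]):
                    writer.writerow([grp.id, genome, gene, cons])


def gene_to_group_map(groups: list[OrthologGroup]) -> dict[GeneKey, str]:
    return {key: grp.id for grp in groups for key in grp.gene_keys}
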