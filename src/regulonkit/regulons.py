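"""Regulon reconstruction workflows and regulatory-network analysis.

A regulon is the set of operons directly controlled by one TF in one
genome.  Reconstruction starts from some notion of a training set of
binding sites and proceeds by scanning all upstream regions of a genome
collection, then filtering candidate sites by cross-genome consistency:
a site is trusted only when orthologous operons in several genomes carry
sites for the same TF (or when the target is vouched for by an external
functional-relatedness whitelist).

Three workflows differ in where the training set comes from:

1a. known regulon with known sites — build a profile from the sites,
    scan, accept consistent novel targets, rebuild the PWM once with the
    accepted sites, and rescan;
1b. known regulon, unknown sites — pool upstream regions of the known
    genes and their orthologs, discover the motif de novo, then proceed
    as 1a;
2.  regulon known only in an organism outside the collection — map its
    genes into the collection through an ortholog map, then as 1b;
3.  ab initio — candidate co-regulated genes are taken from conserved
    gene neighborhoods around the TF, and their pooled upstream regions
    feed motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .genomes import GenomeSet, Operon, UpstreamRegion, extract_upstream, predict_operons
from .motifs import (
    MotifResult,
    Profile,
    Site,
    build_pwm,
    discover_motif,
    scan,
    score_site,
)
from .orthology import GeneKey, OrthologGroup, gene_to_group_map

log = logging.getLogger(__name__)


@dataclass
class KnownRegulon:
    """A literature-derived regulon used to seed reconstruction."""

    tf: str
    source_organism: str
    regulated_genes: list[str]
    known_sites: list[str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.regulated_genes:
            raise ValueError("regulated_genes must be non-empty")


@dataclass
class Interaction:
    """One accepted TF -> operon regulatory interaction in one genome."""

    genome: str
    tf_group: str
    operon: str
    sites: list[Site]
    support: int
    whitelisted: bool = False


@dataclass
class RegulonModel:
    """Reconstructed regulon of one TF ortholog group across a lineage."""

    tf_group: str
    lineage: str
    profile: Profile
    interactions: list[Interaction]
    workflow: str
    discovery: MotifResult | None = None
    candidate_sites: list[Site] = field(default_factory=list)  # pre-filter scan hits

    @property
    def targets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for i in self.interactions:
            out.setdefault(i.genome, set()).add(i.operon)
        return out


@dataclass
class RegionIndex:
    """Operons and upstream regions for every genome of a collection."""

    genome_set: GenomeSet
    operons: dict[str, dict[str, Operon]]  # genome -> operon id -> Operon
    regions: dict[str, dict[str, UpstreamRegion]]
    operon_of_gene: dict[GeneKey, str]

    def lead_gene_key(self, genome: str, operon_id: str) -> GeneKey:
        return (genome, self.operons[genome][operon_id].lead_gene)

    def all_regions(self, genome_ids: list[str] | None = None) -> list[UpstreamRegion]:
        ids = genome_ids if genome_ids is not None else sorted(self.regions)
        return [r for g in ids for r in self.regions[g].values() if not r.empty]


def prepare_regions(
    genome_set: GenomeSet,
    max_intergenic_gap: int = 100,
    upstream_bp: int = 300,
    downstream_bp: int = 25,
    truncate_at_upstream_gene: bool = True,
) -> RegionIndex:
    """Predict operons and extract every operon's upstream region."""
    operons: dict[str, dict[str, Operon]] = {}
    regions: dict[str, dict[str, UpstreamRegion]] = {}
    operon_of_gene: dict[GeneKey, str] = {}
    for genome in genome_set:
        ops = predict_operons(genome, max_intergenic_gap)
        operons[genome.id] = {op.id: op for op in ops}
        regions[genome.id] = {
            op.id: extract_upstream(
                op, genome, upstream_bp, downstream_bp, truncate_at_upstream_gene
            )
            for op in ops
        }
        for op in ops:
            for gid in op.genes:
                operon_of_gene[(genome.id, gid)] = op.id
    return RegionIndex(genome_set, operons, regions, operon_of_gene)


# ---------------------------------------------------------------------------
# consistency filtering


def consistency_filter(
    candidate_sites: list[Site],
    ortholog_groups: list[OrthologGroup],
    index: RegionIndex,
    tf_group: str,
    min_support: int = 3,
    functional_whitelist: set[str] | None = None,
) -> list[Interaction]:
    """Keep candidate interactions seen in orthologous operons of enough
    genomes.

    A candidate (genome, operon) is accepted iff the operon's lead gene
    belongs to an ortholog group whose members' operons carry candidate
    sites in at least ``min_support`` genomes (counting the candidate's
    own genome), or the lead gene is whitelisted as functionally related.
    Lead genes outside every group count as singleton groups.
    """
    whitelist = functional_whitelist or set()
    to_group = gene_to_group_map(ortholog_groups)

    by_operon: dict[tuple[str, str], list[Site]] = {}
    for s in candidate_sites:
        by_operon.setdefault((s.genome, s.region), []).append(s)

    group_genomes: dict[str, set[str]] = {}
    lead_groups: dict[tuple[str, str], str] = {}
    for genome, operon in by_operon:
        lead = index.lead_gene_key(genome, operon)
        grp = to_group.get(lead, f"singleton:{lead[0]}:{lead[1]}")
        lead_groups[(genome, operon)] = grp
        group_genomes.setdefault(grp, set()).add(genome)

    out = []
    for (genome, operon), sites in sorted(by_operon.items()):
        grp = lead_groups[(genome, operon)]
        support = len(group_genomes[grp])
        lead_gene = index.lead_gene_key(genome, operon)[1]
        wl = lead_gene in whitelist
        if support >= min_support or wl:
            out.append(
                Interaction(
                    genome=genome,
                    tf_group=tf_group,
                    operon=operon,
                    sites=sorted(sites, key=lambda s: s.offset),
                    support=support,
                    whitelisted=wl,
                )
            )
    return out


# ---------------------------------------------------------------------------
# shared workflow machinery


def resolve_tf_group(tf: str, groups: list[OrthologGroup]) -> OrthologGroup:
    """Find the ortholog group named ``tf`` or containing a gene ``tf``."""
    for grp in groups:
        if grp.id == tf:
            return grp
    for grp in groups:
        if any(tf == gene for _, gene in grp.gene_keys):
            return grp
    raise ValueError(f"TF {tf!r} matches no ortholog group")


def _gene_occurrences(gene_id: str, genome_set: GenomeSet) -> list[GeneKey]:
    return [
        (genome.id, g.id)
        for genome in genome_set
        for g in genome.genes
        if g.id == gene_id
    ]


def _ortholog_closure(keys: list[GeneKey], groups: list[OrthologGroup]) -> set[GeneKey]:
    """The genes plus every member of their ortholog groups."""
    to_group = gene_to_group_map(groups)
    by_id = {g.id: g for g in groups}
    out = set(keys)
    for key in keys:
        gid = to_group.get(key)
        if gid:
            out |= by_id[gid].gene_keys
    return out


def _regions_of_genes(keys: set[GeneKey], index: RegionIndex) -> list[UpstreamRegion]:
    seen: set[tuple[str, str]] = set()
    regions = []
    for genome, gene in sorted(keys):
        op = index.operon_of_gene.get((genome, gene))
        if op is None or (genome, op) in seen:
            continue
        seen.add((genome, op))
        region = index.regions[genome][op]
        if not region.empty:
            regions.append(region)
    return regions


@dataclass
class WorkflowConfig:
    symmetry: str = "palindrome"
    width_range: tuple[int, int] = (14, 24)
    width_step: int = 2
    n_restarts: int = 20
    seed: int = 17
    min_support: int = 3
    pseudocount: float = 0.5
    functional_whitelist: set[str] = field(default_factory=set)


def _scan_filter(
    profile: Profile,
    tf_group: OrthologGroup,
    groups: list[OrthologGroup],
    index: RegionIndex,
    config: WorkflowConfig,
    genome_ids: list[str],
) -> tuple[list[Site], list[Interaction]]:
    regions = index.all_regions(genome_ids)
    candidates = scan(profile, regions)
    accepted = consistency_filter(
        candidates, groups, index, tf_group.id,
        min_support=config.min_support,
        functional_whitelist=config.functional_whitelist,
    )
    return candidates, accepted


def _tf_genomes(tf_group: OrthologGroup, index: RegionIndex,
                lineage: str | None) -> list[str]:
    """Genomes carrying the TF (a genome without the TF contributes no
    targets), optionally restricted to one lineage."""
    ids = sorted(tf_group.genomes)
    if lineage is not None:
        ids = [g for g in ids if index.genome_set.genomes[g].lineage == lineage]
    return [g for g in ids if g in index.regions]


def _expand_once(
    training_sites: list[str],
    tf_group: OrthologGroup,
    groups: list[OrthologGroup],
    index: RegionIndex,
    config: WorkflowConfig,
    lineage: str | None,
    workflow: str,
    discovery: MotifResult | None = None,
) -> RegulonModel:
    """Scan with the training profile, accept consistent novel sites into
    the training set, rebuild the PWM once, and rescan (the single
    profile-update round of workflow 1a)."""
    genome_ids = _tf_genomes(tf_group, index, lineage)
    if not genome_ids:
        raise ValueError(f"TF group {tf_group.id} absent from every scanned genome")
    bg_regions = index.all_regions(genome_ids)
    background = None
    if bg_regions:
        from .motifs import estimate_background

        background = estimate_background([r.sequence for r in bg_regions])

    # prior strength grows as sqrt(n): small curated training sets need
    # strong regularization toward background or the min-of-training
    # threshold inherits the full sampling noise of rare-base frequencies
    def _pc(n_sites: int) -> float:
        return max(config.pseudocount, 0.25 * np.sqrt(n_sites))

    profile = Profile(
        pwm=build_pwm(
            training_sites,
            pseudocount=_pc(len(training_sites)),
            background=background,
            symmetry=config.symmetry,
        ),
        training_sites=list(training_sites),
        name=tf_group.id,
    )
    candidates, accepted = _scan_filter(profile, tf_group, groups, index, config, genome_ids)

    # Only confidently scoring novel sites are promoted into the training
    # set (score at or above the training-set median), standing in for the
    # curation step that vets additions: borderline hits remain candidate
    # interactions but must not dilute the profile or drag its threshold.
    median_score = float(
        np.median([score_site(profile.pwm, s) for s in training_sites])
    )
    novel = sorted(
        {s.sequence for i in accepted for s in i.sites if s.score >= median_score}
        - set(training_sites)
    )
    if novel:
        updated = list(training_sites) + novel
        profile = Profile(
            pwm=build_pwm(
                updated,
                pseudocount=_pc(len(updated)),
                background=background,
                symmetry=config.symmetry,
            ),
            training_sites=updated,
            name=tf_group.id,
        )
        candidates, accepted = _scan_filter(
            profile, tf_group, groups, index, config, genome_ids
        )

    return RegulonModel(
        tf_group=tf_group.id,
        lineage=lineage or "all",
        profile=profile,
        interactions=accepted,
        workflow=workflow,
        discovery=discovery,
        candidate_sites=candidates,
    )


# ---------------------------------------------------------------------------
# the three workflows


def workflow1_expand(
    known: KnownRegulon,
    index: RegionIndex,
    groups: list[OrthologGroup],
    config: WorkflowConfig | None = None,
    lineage: str | None = None,
) -> RegulonModel:
    """Project and expand a regulon known in an organism of the collection.

    With known sites (1a) the profile comes straight from them; with only
    a gene list (1b) the motif is first discovered in the pooled upstream
    regions of the known genes and their orthologs.
    """
    config = config or WorkflowConfig()
    tf_group = resolve_tf_group(known.tf, groups)

    if known.known_sites:
        return _expand_once(
            list(known.known_sites), tf_group, groups, index, config, lineage, "1a"
        )

    keys: list[GeneKey] = []
    for gene in known.regulated_genes:
        keys.extend(_gene_occurrences(gene, index.genome_set))
    if not keys:
        raise ValueError("training set empty: no regulated genes found in the collection")
    regions = _regions_of_genes(_ortholog_closure(keys, groups), index)
    if len(regions) < 3:
        raise ValueError("training set empty: fewer than 3 usable upstream regions")
    discovery = discover_motif(
        regions,
        width_range=config.width_range,
        width_step=config.width_step,
        symmetry=config.symmetry,
        n_restarts=config.n_restarts,
        seed=config.seed,
        pseudocount=config.pseudocount,
    )
    sites = [s.sequence for s in discovery.sites]
    if not sites:
        raise ValueError("motif discovery produced no sites")
    return _expand_once(sites, tf_group, groups, index, config, lineage, "1b", discovery)


def workflow2_project(
    external: KnownRegulon,
    ortholog_map: dict[str, list[GeneKey]],
    index: RegionIndex,
    groups: list[OrthologGroup],
    config: WorkflowConfig | None = None,
    lineage: str | None = None,
) -> RegulonModel:
    """Project a regulon known in an organism outside the collection.

    ``ortholog_map`` links external gene ids to genes of the collection.
    At least 3 regulated genes must be mappable; the training set is the
    upstream regions of their in-collection orthologs.
    """
    config = config or WorkflowConfig()
    tf_keys = ortholog_map.get(external.tf, [])
    if not tf_keys:
        raise ValueError(f"external TF {external.tf!r} has no ortholog in the collection")
    tf_group = resolve_tf_group(tf_keys[0][1], groups)

    mapped = [g for g in external.regulated_genes if ortholog_map.get(g)]
    if len(mapped) < 3:
        raise ValueError(
            f"only {len(mapped)} regulated genes mappable; motif discovery unreliable"
        )
    keys = [key for g in mapped for key in ortholog_map[g]]
    regions = _regions_of_genes(_ortholog_closure(keys, groups), index)
    if len(regions) < 3:
        raise ValueError("training set empty: fewer than 3 usable upstream regions")
    discovery = discover_motif(
        regions,
        width_range=config.width_range,
        width_step=config.width_step,
        symmetry=config.symmetry,
        n_restarts=config.n_restarts,
        seed=config.seed,
        pseudocount=config.pseudocount,
    )
    sites = [s.sequence for s in discovery.sites]
    if not sites:
        raise ValueError("motif discovery produced no sites")
    return _expand_once(sites, tf_group, groups, index, config, lineage, "2", discovery)


def workflow3_ab_initio(
    tf_gene: GeneKey,
    index: RegionIndex,
    groups: list[OrthologGroup],
    config: WorkflowConfig | None = None,
    lineage: str | None = None,
    neighborhood_radius: int = 5,
    min_neighborhood_support: int = 3,
) -> RegulonModel:
    """Predict a novel regulon from conserved gene neighborhoods.

    Candidate co-regulated genes are those whose ortholog groups recur
    within ``neighborhood_radius`` genes of the TF in at least
    ``min_neighborhood_support`` genomes; their pooled upstream regions
    feed motif discovery, then scanning plus consistency filtering.
    """
    config = config or WorkflowConfig()
    tf_group = resolve_tf_group(tf_gene[1], groups)
    if len(tf_group.genomes) < 3:
        raise ValueError(f"TF group {tf_group.id} present in fewer than 3 genomes")
    to_group = gene_to_group_map(groups)

    neighbor_support: dict[str, set[str]] = {}
    neighbor_keys: dict[str, list[GeneKey]] = {}
    for genome_id in sorted(tf_group.genomes):
        genome = index.genome_set.genomes[genome_id]
        tf_ids = tf_group.members[genome_id]
        ordered = genome.genes
        for pos, g in enumerate(ordered):
            if g.id not in tf_ids:
                continue
            lo = max(0, pos - neighborhood_radius)
            for neighbor in ordered[lo : pos + neighborhood_radius + 1]:
                if neighbor.id in tf_ids:
                    continue
                grp = to_group.get((genome_id, neighbor.id))
                if grp is None or grp == tf_group.id:
                    continue
                neighbor_support.setdefault(grp, set()).add(genome_id)
                neighbor_keys.setdefault(grp, []).append((genome_id, neighbor.id))

    conserved = [
        grp for grp, genomes in neighbor_support.items()
        if len(genomes) >= min_neighborhood_support
    ]
    if not conserved:
        raise ValueError("no candidate training set: no conserved neighborhood")
    keys = {key for grp in conserved for key in neighbor_keys[grp]}
    regions = _regions_of_genes(keys, index)
    if len(regions) < 3:
        raise ValueError("no candidate training set: fewer than 3 usable regions")
    discovery = discover_motif(
        regions,
        width_range=config.width_range,
        width_step=config.width_step,
        symmetry=config.symmetry,
        n_restarts=config.n_restarts,
        seed=config.seed,
        pseudocount=config.pseudocount,
    )
    sites = [s.sequence for s in discovery.sites]
    if not sites:
        raise ValueError("motif discovery produced no sites")
    return _expand_once(sites, tf_group, groups, index, config, lineage, "3", discovery)


# ---------------------------------------------------------------------------
# network analysis


def detect_autoregulation(
    regulon: RegulonModel,
    index: RegionIndex,
    groups: list[OrthologGroup],
) -> dict[str, bool]:
    """Per genome with the TF present: does the TF target its own operon?"""
    tf_group = next(g for g in groups if g.id == regulon.tf_group)
    targets = regulon.targets
    out = {}
    for genome_id in sorted(tf_group.genomes):
        if genome_id not in index.regions:
            continue
        own_operons = {
            index.operon_of_gene.get((genome_id, gene))
            for gene in tf_group.members[genome_id]
        }
        out[genome_id] = bool(own_operons & targets.get(genome_id, set()))
    return out


def detect_cascades(
    regulons: list[RegulonModel],
    index: RegionIndex,
    groups: list[OrthologGroup],
) -> nx.DiGraph:
    """TF -> TF edges: regulon A targets an operon containing TF B's gene.

    Self-edges are excluded (they are autoregulation, not cascades).
    Each edge records the genomes where the cascade is observed.
    """
    if len(regulons) < 2:
        raise ValueError("need at least 2 regulons")
    by_id = {g.id: g for g in groups}
    graph = nx.DiGraph()
    for reg_a in regulons:
        for interaction in reg_a.interactions:
            op = index.operons[interaction.genome][interaction.operon]
            for gene in op.genes:
                for reg_b in regulons:
                    if reg_b.tf_group == reg_a.tf_group:
                        continue
                    members = by_id[reg_b.tf_group].members.get(interaction.genome, set())
                    if gene in members:
                        if graph.has_edge(reg_a.tf_group, reg_b.tf_group):
                            graph[reg_a.tf_group][reg_b.tf_group]["genomes"].add(
                                interaction.genome
                            )
                        else:
                            graph.add_edge(
                                reg_a.tf_group,
                                reg_b.tf_group,
                                genomes={interaction.genome},
                            )
    return graph


def detect_coregulation(regulons: list[RegulonModel]) -> dict[tuple[str, str], dict]:
    """Operons with accepted sites of two or more TFs.

    Returns (genome, operon) -> {"tf_groups": sorted ids, "tag":
    double/triple/quadruple/multiple}.
    """
    if len(regulons) < 2:
        raise ValueError("need at least 2 regulons")
    hits: dict[tuple[str, str], set[str]] = {}
    for reg in regulons:
        for i in reg.interactions:
            hits.setdefault((i.genome, i.operon), set()).add(reg.tf_group)
    tags = {2: "double", 3: "triple", 4: "quadruple"}
    return {
        key: {"tf_groups": sorted(tfs), "tag": tags.get(len(tfs), "multiple")}
        for key, tfs in sorted(hits.items())
        if len(tfs) >= 2
    }


# ---------------------------------------------------------------------------
# exports


def interactions_to_tsv(regulons: list[RegulonModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome\ttf_group\toperon\tsite_offset\tsite_strand\tsite_score\t"
            "site_sequence\tsupport\tworkflow\n"
        )
        for reg in regulons:
            for i in reg.interactions:
                for s in i.sites:
                    fh.write(
                        f"{i.genome}\t{i.tf_group}\t{i.operon}\t{s.offset}\t{s.strand}\t"
                        f"{s.score:.4f}\t{s.sequence}\t{i.support}\t{reg.workflow}\n"
                    )


def network_to_sif(regulons: list[RegulonModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg in regulons:
            for i in sorted(
                reg.interactions, key=lambda x: (x.genome, x.operon)
            ):
                fh.write(f"{reg.tf_group}\tregulates\t{i.genome}:{i.operon}\n")


def export_upstream_alignment(
    group: OrthologGroup, index: RegionIndex, path: str | Path
) -> None:
    """FASTA of orthologous upstream regions, for manual footprinting review."""
    with open(path, "w") as fh:
        for genome_id in sorted(group.genomes):
            for gene in sorted(group.members[genome_id]):
                op = index.operon_of_gene.get((genome_id, gene))
                if op is None:
                    continue
                region = index.regions[genome_id][op]
                if not region.empty:
                    fh.write(f">{genome_id}|{op}|{gene}\n{region.sequence}\n")
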