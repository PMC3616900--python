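"""Standard end-to-end benchmarks on synthetic collections.

Two reusable study designs:

* the *regulon recovery* benchmark — 10 genomes, 3 planted palindromic
  regulons at presence probability 0.8 with one near-threshold decoy
  per upstream region — runs the full pipeline (orthologs, profile from
  a few "known" genomes, expansion, consistency filter) and scores it
  against the planted truth;
* the *motif recovery* trial — 20 upstream-sized regions with one
  planted 18-bp palindromic site each (16 bits of information) — runs
  symmetry-constrained EM discovery and reports the per-column
  correlation between the recovered and planted PWMs.

Both are deterministic given a seed and small enough for a desk run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .comparative import pwm_similarity
from .motifs import discover_motif
from .orthology import build_ortholog_groups, gene_to_group_map
from .regulons import (
    KnownRegulon,
    RegulonModel,
    WorkflowConfig,
    detect_autoregulation,
    detect_cascades,
    prepare_regions,
    workflow1_expand,
)
from .reporting import evaluate
from .synthetic import RegulonSpec, SyntheticConfig, TruthTable, generate


def benchmark_config(
    n_genomes: int = 10,
    n_regulons: int = 3,
    presence_prob: float = 0.8,
    decoy_rate: float = 1.0,
    seed: int = 0,
    with_cascade: bool = True,
) -> SyntheticConfig:
    """The standard regulon-recovery benchmark conditions."""
    regulons = [
        RegulonSpec(name=f"R{i + 1}", presence_prob=presence_prob)
        for i in range(n_regulons)
    ]
    return SyntheticConfig(
        lineages={"lineage_a": n_genomes},
        regulons=regulons,
        decoy_rate=decoy_rate,
        cascades=[("R1", "R2")] if with_cascade and n_regulons >= 2 else [],
        seed=seed,
    )


def _training_sites(
    truth: TruthTable, regulon: str, genome_ids: list[str]
) -> list[str]:
    """Planted sites of the first few genomes, standing in for the
    literature-known part of a regulon."""
    chosen = set(genome_ids)
    return [
        s.sequence
        for s in truth.sites
        if s.regulon == regulon and not s.is_decoy and s.genome in chosen
    ]


def _unfiltered_metrics(
    models: list[RegulonModel],
    truth: TruthTable,
    groups,
) -> tuple[float, float]:
    """Precision and recall of the raw scan hits, before the
    cross-genome consistency filter."""
    to_group = gene_to_group_map(groups)
    group_to_regulon = {}
    for name, keys in truth.tf_genes.items():
        for key in keys:
            grp = to_group.get(key)
            if grp is not None:
                group_to_regulon[grp] = name
                break
    predicted = set()
    for model in models:
        name = group_to_regulon.get(model.tf_group, model.tf_group)
        for s in model.candidate_sites:
            predicted.add((name, s.genome, s.region))
    true_triples = truth.planted_interactions()
    tp = len(predicted & true_triples)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(true_triples) if true_triples else 1.0
    return precision, recall


def run_regulon_benchmark(
    seed: int,
    min_support: int = 3,
    n_training_genomes: int = 3,
    config: SyntheticConfig | None = None,
) -> dict:
    """Full-pipeline recovery of planted regulons, scored against truth.

    Returns interaction-level precision/recall/F1 (filtered and
    unfiltered), the site position-match rate, per-regulon motif
    correlations, and the predicted vs planted autoregulation fraction.
    """
    config = config or benchmark_config(seed=seed)
    genome_set, truth = generate(config, seed)
    index = prepare_regions(genome_set)
    groups, _ = build_ortholog_groups(genome_set)

    genome_ids = sorted(genome_set.genomes)
    wf_config = WorkflowConfig(min_support=min_support, seed=seed)
    models = []
    for name in sorted(truth.tf_genes):
        sites = _training_sites(truth, name, genome_ids[:n_training_genomes])
        if len(sites) < 2:
            continue
        tf_gene = truth.tf_genes[name][0][1]
        known = KnownRegulon(
            tf=tf_gene,
            source_organism=genome_ids[0],
            regulated_genes=[tf_gene],
            known_sites=sites,
        )
        models.append(workflow1_expand(known, index, groups, wf_config))

    report = evaluate(models, truth, groups)
    precision_unfiltered, recall_unfiltered = _unfiltered_metrics(models, truth, groups)

    auto_pred = []
    auto_true = []
    for model in models:
        flags = detect_autoregulation(model, index, groups)
        auto_pred.extend(flags.values())
    for name in truth.autoregulation:
        auto_true.extend(truth.autoregulation[name].values())

    cascade_edges = []
    if len(models) >= 2:
        graph = detect_cascades(models, index, groups)
        to_group = gene_to_group_map(groups)
        group_to_regulon = {}
        for name, keys in truth.tf_genes.items():
            grp = to_group.get(keys[0])
            if grp:
                group_to_regulon[grp] = name
        cascade_edges = sorted(
            (group_to_regulon.get(a, a), group_to_regulon.get(b, b))
            for a, b in graph.edges
        )

    return {
        "seed": seed,
        "n_genomes": len(genome_set),
        "n_regulons": len(models),
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "precision_unfiltered": precision_unfiltered,
        "recall_unfiltered": recall_unfiltered,
        "site_match_rate": report.site_match_rate,
        "motif_correlation": report.motif_correlation,
        "autoregulation_fraction": float(np.mean(auto_pred)) if auto_pred else 0.0,
        "planted_autoregulation_fraction": float(np.mean(auto_true)) if auto_true else 0.0,
        "cascade_edges": cascade_edges,
        "planted_cascades": sorted(truth.cascades),
        "n_predicted": report.n_predicted,
        "n_true": report.n_true,
    }


def motif_recovery_trial(
    seed: int,
    n_regions: int = 20,
    region_length: int = 200,
    width: int = 18,
    information_content: float = 16.0,
    n_restarts: int = 20,
    width_range: tuple[int, int] = (14, 24),
    gc: float = 0.40,
) -> dict:
    """Plant one palindromic site per background region and rediscover it.

    Returns the per-column frequency correlation between the recovered
    and planted PWMs and the number of planted positions recovered
    exactly (site offset within +-1 of the planted offset).
    """
    from .synthetic import _random_dna, make_planted_pwm, sample_site

    rng = np.random.default_rng(seed)
    pwm = make_planted_pwm(width, information_content, "palindrome", rng)
    floor = 0.5 * pwm.information_content
    regions, offsets = [], []
    for _ in range(n_regions):
        seq = _random_dna(rng, region_length, gc)
        off = int(rng.integers(0, region_length - width + 1))
        seq = seq[:off] + sample_site(pwm, rng, min_score=floor) + seq[off + width :]
        regions.append(seq)
        offsets.append(off)
    result = discover_motif(
        regions,
        width_range=width_range,
        symmetry="palindrome",
        n_restarts=n_restarts,
        seed=seed,
    )
    found = {s.region: s for s in result.sites}
    recovered = sum(
        1
        for i, off in enumerate(offsets)
        if f"region{i}" in found
        and abs(
            (found[f"region{i}"].offset + result.width / 2) - (off + width / 2)
        )
        <= 3
    )
    return {
        "seed": seed,
        "correlation": pwm_similarity(result.pwm, pwm),
        "recovered_sites": recovered,
        "n_regions": n_regions,
        "width": result.width,
        "information_content": result.information_content,
    }


def reconstruct_planted_regulons(
    run_dir: Path, min_support: int = 3, seed: int = 17
) -> dict:
    """Re-run the benchmark for a directory written by the simulator.

    The manifest's (config, seed) pair regenerates the collection and
    truth deterministically, so evaluation does not depend on parsing
    the emitted files back.
    """
    manifest = json.loads((Path(run_dir) / "manifest.json").read_text())
    raw = manifest["config"]
    if not raw or not raw.get("regulons"):
        raise ValueError("run has no planted regulons; nothing to evaluate")
    raw["regulons"] = [RegulonSpec(**r) for r in raw["regulons"]]
    raw["cascades"] = [tuple(c) for c in raw.get("cascades", [])]
    for key in ("protein_length", "gc_range", "intra_operon_gap", "inter_operon_gap",
                "operon_size_probs"):
        raw[key] = tuple(raw[key])
    config = SyntheticConfig(**raw)
    return run_regulon_benchmark(
        config.seed, min_support=min_support, config=config
    )
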