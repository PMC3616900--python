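"""Network statistics, distribution tables, truth-based evaluation and
exports.

Two kinds of inputs flow through here: per-genome statistics tables of a
published 30-genome reconstruction (shipped as TSV fixtures and
re-summarized, never re-derived — the underlying genomes and curation
are outside this package's scope), and reconstructed ``RegulonModel``
networks from synthetic runs, for which exact per-genome counts and
precision/recall against the planted truth are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .comparative import pwm_similarity
from .orthology import OrthologGroup, gene_to_group_map
from .regulons import RegionIndex, RegulonModel
from .synthetic import TruthTable


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("regulonkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """Per-genome statistics of the published 30-genome reconstruction."""
    return _fixture("table1.tsv")


def load_table1_nonoverlap() -> pd.DataFrame:
    """Distinct-union (non-overlapping) lineage rows of the published
    table; display values, not recomputable without the real regulons."""
    return _fixture("table1_nonoverlap.tsv")


def load_table2() -> pd.DataFrame:
    """Distribution of orthologous-TF regulons across the two lineages."""
    return _fixture("table2.tsv")


def load_workflow_counts() -> pd.DataFrame:
    """Published number of regulons reconstructed per workflow."""
    return _fixture("workflow_counts.tsv")


# ---------------------------------------------------------------------------
# network statistics


@dataclass
class NetworkStats:
    per_genome: pd.DataFrame  # columns: lineage, genome, tfs, target_genes, ...
    totals: dict[str, dict[str, int]]  # lineage (+ "all") -> column -> total
    mean: dict[str, float]  # column -> mean per genome, 1 decimal
    min: dict[str, tuple[str, int]]  # column -> (genome, value)
    max: dict[str, tuple[str, int]]

    _COLUMNS = ("tfs", "target_genes", "target_operons", "interactions")


def summarize_network(per_genome: pd.DataFrame) -> NetworkStats:
    """Aggregate a per-genome statistics table.

    Expects columns lineage, genome, tfs, target_genes, target_operons,
    interactions; totals are computed per lineage and overall, means to
    one decimal, and min/max with the genome attaining them.
    """
    df = per_genome.copy()
    cols = [c for c in NetworkStats._COLUMNS if c in df.columns]
    totals: dict[str, dict[str, int]] = {
        "all": {c: int(df[c].sum()) for c in cols}
    }
    for lineage, sub in df.groupby("lineage"):
        totals[str(lineage)] = {c: int(sub[c].sum()) for c in cols}
    mean = {c: round(float(df[c].mean()), 1) for c in cols}
    mn, mx = {}, {}
    for c in cols:
        if len(df):
            i_min, i_max = df[c].idxmin(), df[c].idxmax()
            mn[c] = (str(df.loc[i_min, "genome"]), int(df.loc[i_min, c]))
            mx[c] = (str(df.loc[i_max, "genome"]), int(df.loc[i_max, c]))
    return NetworkStats(per_genome=df, totals=totals, mean=mean, min=mn, max=mx)


def network_table_from_models(
    regulons: list[RegulonModel], index: RegionIndex
) -> pd.DataFrame:
    """Per-genome counts (TFs, target genes/operons, interactions) from
    reconstructed regulon models."""
    rows = []
    for genome_id in sorted(index.genome_set.genomes):
        lineage = index.genome_set.genomes[genome_id].lineage
        tfs = set()
        operons = set()
        genes = set()
        interactions = 0
        for reg in regulons:
            ops = reg.targets.get(genome_id, set())
            if ops:
                tfs.add(reg.tf_group)
            interactions += len(ops)
            for op in ops:
                operons.add(op)
                genes.update(index.operons[genome_id][op].genes)
        rows.append(
            dict(
                lineage=lineage, genome=genome_id, tfs=len(tfs),
                target_genes=len(genes), target_operons=len(operons),
                interactions=interactions,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distribution table


@dataclass
class DistributionTable:
    counts: pd.DataFrame  # index: (class_a, class_b), column: count
    total: int
    both_lineages: int
    only_first: int
    only_second: int


def summarize_distribution(table: pd.DataFrame) -> DistributionTable:
    """Class-pair counts of TF regulons across two lineages.

    Accepts a table with two ``*_class`` columns (universal / mosaic /
    absent) and a ``count`` column (one row per class pair) or one row
    per regulon without a count column.
    """
    class_cols = [c for c in table.columns if c.endswith("_class")]
    if len(class_cols) != 2:
        raise ValueError("expected exactly two *_class columns")
    a, b = class_cols
    if "count" in table.columns:
        grouped = table.set_index([a, b])["count"]
    else:
        grouped = table.groupby([a, b]).size()
    total = int(grouped.sum())
    present_a = grouped[[i for i in grouped.index if i[0] != "absent"]]
    both = int(present_a[[i for i in present_a.index if i[1] != "absent"]].sum())
    only_a = int(grouped[[i for i in grouped.index if i[0] != "absent" and i[1] == "absent"]].sum())
    only_b = int(grouped[[i for i in grouped.index if i[0] == "absent" and i[1] != "absent"]].sum())
    return DistributionTable(
        counts=grouped.reset_index(),
        total=total,
        both_lineages=both,
        only_first=only_a,
        only_second=only_b,
    )


def distribution_from_groups(
    tf_groups: list, genome_set, lineages: tuple[str, str]
) -> pd.DataFrame:
    """Universal/mosaic/absent class per TF group and lineage, one row
    per group (feed to :func:`summarize_distribution`)."""
    rows = []
    for grp in tf_groups:
        classes = []
        for lineage in lineages:
            ids = genome_set.lineages[lineage]
            present = sum(1 for g in ids if grp.members.get(g))
            classes.append(
                "universal" if present == len(ids) else "mosaic" if present else "absent"
            )
        rows.append({
            "tf_group": grp.id,
            f"{lineages[0]}_class": classes[0],
            f"{lineages[1]}_class": classes[1],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation against planted truth


@dataclass
class EvaluationReport:
    precision: float
    recall: float
    f1: float
    site_match_rate: float  # planted sites recovered within +-3 bp
    motif_correlation: dict[str, float]  # regulon -> PWM column correlation
    n_predicted: int
    n_true: int
    undefined_precision: bool = False
    notes: list[str] = field(default_factory=list)


def evaluate(
    regulons: list[RegulonModel],
    truth: TruthTable,
    ortholog_groups: list[OrthologGroup],
    site_tolerance_bp: int = 3,
) -> EvaluationReport:
    """Interaction-level precision/recall/F1 against the planted truth.

    Truth regulons are matched to reconstructed models through the
    ortholog group containing the planted TF gene.  Interactions are
    (regulon, genome, operon) triples; the site match rate is the
    fraction of planted sites with a predicted site of the same triple
    within ``site_tolerance_bp``.
    """
    to_group = gene_to_group_map(ortholog_groups)
    group_to_regulon: dict[str, str] = {}
    for name, keys in truth.tf_genes.items():
        for key in keys:
            grp = to_group.get(key)
            if grp is not None:
                group_to_regulon[grp] = name
                break

    predicted: set[tuple[str, str, str]] = set()
    predicted_sites: dict[tuple[str, str, str], list[int]] = {}
    for reg in regulons:
        name = group_to_regulon.get(reg.tf_group, reg.tf_group)
        for i in reg.interactions:
            triple = (name, i.genome, i.operon)
            predicted.add(triple)
            predicted_sites.setdefault(triple, []).extend(s.offset for s in i.sites)

    true_triples = truth.planted_interactions()
    tp = len(predicted & true_triples)
    notes = []
    undefined = len(predicted) == 0
    precision = tp / len(predicted) if predicted else 0.0
    if undefined:
        notes.append("no predicted interactions; precision reported as 0")
    recall = tp / len(true_triples) if true_triples else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )

    matched = total_sites = 0
    for s in truth.sites:
        if s.is_decoy:
            continue
        total_sites += 1
        offsets = predicted_sites.get((s.regulon, s.genome, s.operon), [])
        if any(abs(o - s.offset) <= site_tolerance_bp for o in offsets):
            matched += 1
    site_rate = matched / total_sites if total_sites else 1.0

    motif_corr = {}
    by_group = {reg.tf_group: reg for reg in regulons}
    for grp_id, name in group_to_regulon.items():
        reg = by_group.get(grp_id)
        if reg is not None and name in truth.pwms:
            motif_corr[name] = pwm_similarity(reg.profile.pwm, truth.pwms[name])

    return EvaluationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        site_match_rate=site_rate,
        motif_correlation=motif_corr,
        n_predicted=len(predicted),
        n_true=len(true_triples),
        undefined_precision=undefined,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# exports


def export_network(
    regulons: list[RegulonModel],
    index: RegionIndex,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the standard export set: interactions TSV, sites GFF3,
    network SIF and profiles in MEME minimal format."""
    from .motifs import sites_to_gff, write_meme
    from .regulons import interactions_to_tsv, network_to_sif

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "sites": out / "sites.gff3",
        "network": out / "network.sif",
        "profiles": out / "profiles.meme",
    }
    interactions_to_tsv(regulons, paths["interactions"])
    all_sites = [s for reg in regulons for i in reg.interactions for s in i.sites]
    sites_to_gff(all_sites, paths["sites"])
    network_to_sif(regulons, paths["network"])
    write_meme([reg.profile for reg in regulons], paths["profiles"])
    return paths


def report_markdown(stats: NetworkStats, dist: DistributionTable | None = None) -> str:
    lines = ["# Regulatory network report", "", "## Per-genome statistics", ""]
    lines.append(stats.per_genome.to_markdown(index=False))
    lines.append("")
    lines.append("## Aggregates")
    for lineage, cols in sorted(stats.totals.items()):
        pretty = ", ".join(f"{k}={v}" for k, v in cols.items())
        lines.append(f"- total ({lineage}): {pretty}")
    lines.append(f"- mean per genome: {stats.mean}")
    lines.append(f"- min: {stats.min}")
    lines.append(f"- max: {stats.max}")
    if dist is not None:
        lines += [
            "",
            "## Distribution of orthologous TF regulons",
            "",
            dist.counts.to_markdown(index=False),
            "",
            f"- total regulons: {dist.total}",
            f"- shared between lineages: {dist.both_lineages}",
            f"- specific to first lineage: {dist.only_first}",
            f"- specific to second lineage: {dist.only_second}",
        ]
    lines.append("")
    return "\n".join(lines)


def report_json(stats: NetworkStats, dist: DistributionTable | None = None) -> str:
    payload = {
        "per_genome": stats.per_genome.to_dict(orient="records"),
        "totals": stats.totals,
        "mean": stats.mean,
        "min": stats.min,
        "max": stats.max,
    }
    if dist is not None:
        payload["distribution"] = {
            "counts": dist.counts.to_dict(orient="records"),
            "total": dist.total,
            "both_lineages": dist.both_lineages,
            "only_first": dist.only_first,
            "only_second": dist.only_second,
        }
    return json.dumps(payload, indent=2, sort_keys=True)
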