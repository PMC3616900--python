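"""Cross-lineage comparison of TF repertoires, motifs and regulons.

Covers the evolutionary questions asked of a two-lineage reconstruction:
how the TF census differs between lineages, whether orthologous TFs kept
the same binding motif (conservation categories I/II/III by mismatches
at high-information positions), whether they kept the same targets
(strictly conserved / core-plus-periphery / different), and whether a
pathway switched to a non-orthologous regulator (displacement, called
xenologous when the replacement comes from the same protein family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomes import GenomeSet
from .motifs import PWM
from .orthology import OrthologGroup, classify_conservation, gene_to_group_map
from .regulons import RegionIndex, RegulonModel


# ---------------------------------------------------------------------------
# TF census


@dataclass
class TFCensus:
    family_counts: pd.DataFrame  # families x genomes
    per_genome_tf_count: pd.Series
    major_families: dict[str, list[str]]  # lineage -> families with mean >= 2/genome
    lineage_specific_families: dict[str, list[str]]
    group_conservation: dict[str, dict[str, str]]  # group id -> lineage -> class


def census(
    genome_set: GenomeSet,
    ortholog_groups: list[OrthologGroup],
) -> TFCensus:
    """Per-family, per-genome TF counts plus conservation classes.

    TF genes and their family labels are read from the gene annotations
    (``is_tf`` / ``tf_family``); a family is "major" in a lineage when
    its mean count per genome there is at least 2, and lineage-specific
    when all its representatives fall in one lineage.
    """
    rows = []
    for genome in genome_set:
        for g in genome.genes:
            if g.is_tf:
                rows.append((g.tf_family or "unassigned", genome.id))
    genome_ids = sorted(genome_set.genomes)
    if rows:
        df = pd.DataFrame(rows, columns=["family", "genome"])
        counts = (
            df.groupby(["family", "genome"]).size().unstack(fill_value=0)
            .reindex(columns=genome_ids, fill_value=0)
        )
    else:
        counts = pd.DataFrame(index=pd.Index([], name="family"), columns=genome_ids).fillna(0)
    per_genome = counts.sum(axis=0).astype(int)

    lineages = genome_set.lineages
    major: dict[str, list[str]] = {}
    for lineage, ids in lineages.items():
        mean_per_genome = counts[ids].sum(axis=1) / len(ids)
        major[lineage] = sorted(mean_per_genome[mean_per_genome >= 2].index)
    specific: dict[str, list[str]] = {lin: [] for lin in lineages}
    for family in counts.index:
        present_in = [lin for lin, ids in lineages.items() if counts.loc[family, ids].sum() > 0]
        if len(present_in) == 1:
            specific[present_in[0]].append(family)
    specific = {k: sorted(v) for k, v in specific.items()}

    conservation = {
        grp.id: {lin: classify_conservation(grp, genome_set, lin) for lin in lineages}
        for grp in ortholog_groups
    }
    return TFCensus(
        family_counts=counts,
        per_genome_tf_count=per_genome,
        major_families=major,
        lineage_specific_families=specific,
        group_conservation=conservation,
    )


# ---------------------------------------------------------------------------
# motif conservation


@dataclass
class MotifComparison:
    tf_group: str
    offset: int
    orientation: str  # "forward" or "reverse"
    mismatches: int | None  # None = not alignable
    conserved_positions: int
    mean_column_correlation: float
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.category = categorize_motif_conservation(self.mismatches)


def _column_correlations(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Pearson correlation of paired frequency columns (0 when a column
    is constant)."""
    a = fa - fa.mean(axis=1, keepdims=True)
    b = fb - fb.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (a * b).sum(axis=1) / denom
    return np.where(denom > 0, corr, 0.0)


def align_pwms(
    pwm_a: PWM,
    pwm_b: PWM,
    max_shift: int = 3,
    ic_threshold: float = 1.0,
    min_overlap: int = 8,
    tf_group: str = "",
) -> MotifComparison:
    """Best gapless alignment of two PWMs and the mismatch count.

    All offsets with |shift| <= ``max_shift`` are tried in both
    orientations; the alignment maximizing the summed per-column
    frequency correlation wins.  Conserved positions are column pairs
    where both motifs carry at least ``ic_threshold`` bits; a mismatch is
    a conserved pair whose consensus bases differ.  Alignments with
    fewer than ``min_overlap`` overlapping columns are "not alignable".
    """
    if abs(pwm_a.width - pwm_b.width) > 6:
        raise ValueError("PWM widths differ by more than 6")
    best = None
    for orientation, b in (("forward", pwm_b), ("reverse", pwm_b.reverse_complement())):
        fa, fb = pwm_a.frequencies, b.frequencies
        ia, ib = pwm_a.information_per_column, b.information_per_column
        for shift in range(-max_shift, max_shift + 1):
            a_lo, b_lo = max(0, shift), max(0, -shift)
            n = min(pwm_a.width - a_lo, b.width - b_lo)
            if n < min_overlap:
                continue
            corr = _column_correlations(fa[a_lo : a_lo + n], fb[b_lo : b_lo + n])
            total = float(corr.sum())
            if best is None or total > best[0]:
                conserved = (ia[a_lo : a_lo + n] >= ic_threshold) & (
                    ib[b_lo : b_lo + n] >= ic_threshold
                )
                cons_a = fa[a_lo : a_lo + n].argmax(axis=1)
                cons_b = fb[b_lo : b_lo + n].argmax(axis=1)
                mismatches = int(np.sum(conserved & (cons_a != cons_b)))
                best = (
                    total, shift, orientation, mismatches,
                    int(conserved.sum()), float(corr.mean()),
                )
    if best is None:
        return MotifComparison(
            tf_group=tf_group, offset=0, orientation="forward",
            mismatches=None, conserved_positions=0, mean_column_correlation=0.0,
        )
    total, shift, orientation, mismatches, n_cons, mean_corr = best
    return MotifComparison(
        tf_group=tf_group, offset=shift, orientation=orientation,
        mismatches=mismatches, conserved_positions=n_cons,
        mean_column_correlation=mean_corr,
    )


def categorize_motif_conservation(mismatches: int | None) -> str:
    """I = at most 1 mismatch, II = 2-4 mismatches, III = 5 or more or
    not alignable."""
    if mismatches is None:
        return "III"
    if mismatches <= 1:
        return "I"
    if mismatches <= 4:
        return "II"
    return "III"


def pwm_similarity(pwm_a: PWM, pwm_b: PWM, max_shift: int = 3) -> float:
    """Mean per-column frequency correlation at the best alignment."""
    try:
        cmp = align_pwms(pwm_a, pwm_b, max_shift=max_shift, min_overlap=min(
            8, min(pwm_a.width, pwm_b.width)
        ))
    except ValueError:
        return 0.0
    return cmp.mean_column_correlation


# ---------------------------------------------------------------------------
# regulon content conservation


@dataclass
class RegulonComparison:
    tf_group: str
    core: set[str]
    periphery_a: set[str]
    periphery_b: set[str]
    content_class: str  # strictly_conserved | core_periphery | different
    size_class: dict[str, str]  # lineage -> local | global
    jaccard: float


def _target_groups(regulon: RegulonModel, index: RegionIndex,
                   to_group: dict) -> set[str]:
    out = set()
    for genome, operons in regulon.targets.items():
        for op in operons:
            lead = index.lead_gene_key(genome, op)
            grp = to_group.get(lead)
            out.add(grp if grp else f"singleton:{lead[0]}:{lead[1]}")
    return out


def _size_class(regulon: RegulonModel) -> str:
    """local = fewer than 3 target operons per genome on average."""
    targets = regulon.targets
    if not targets:
        return "local"
    mean = sum(len(v) for v in targets.values()) / len(targets)
    return "local" if mean < 3 else "global"


def compare_regulon_content(
    regulon_a: RegulonModel,
    regulon_b: RegulonModel,
    ortholog_groups: list[OrthologGroup],
    index: RegionIndex,
    jaccard_conserved: float = 0.75,
) -> RegulonComparison:
    """Core/periphery decomposition of two lineage regulons.

    Targets are mapped to ortholog groups; the core is the intersection.
    Content is strictly conserved at Jaccard >= ``jaccard_conserved``,
    different when the intersection is empty, and core-plus-periphery
    otherwise.
    """
    to_group = gene_to_group_map(ortholog_groups)
    ga = _target_groups(regulon_a, index, to_group)
    gb = _target_groups(regulon_b, index, to_group)
    core = ga & gb
    union = ga | gb
    jaccard = len(core) / len(union) if union else 1.0
    if union and not core:
        content = "different"
    elif jaccard >= jaccard_conserved:
        content = "strictly_conserved"
    else:
        content = "core_periphery"
    return RegulonComparison(
        tf_group=regulon_a.tf_group,
        core=core,
        periphery_a=ga - gb,
        periphery_b=gb - ga,
        content_class=content,
        size_class={
            regulon_a.lineage: _size_class(regulon_a),
            regulon_b.lineage: _size_class(regulon_b),
        },
        jaccard=jaccard,
    )


# ---------------------------------------------------------------------------
# non-orthologous displacement


@dataclass
class DisplacementPair:
    subsystem: str
    tf_group_a: str
    tf_group_b: str
    same_family: bool
    overlap: set[str]  # genomes where both TFs are present
    complementarity: float  # fraction of carrier genomes with exactly one TF


def detect_displacements(
    subsystem_assignments: dict[str, str],  # tf group id -> subsystem label
    ortholog_groups: list[OrthologGroup],
    tf_families: dict[str, str] | None = None,  # tf group id -> protein family
) -> list[DisplacementPair]:
    """Pairs of non-orthologous TFs assigned to the same subsystem.

    Complementarity is the fraction of genomes carrying either TF that
    carry exactly one of them: 1.0 for a clean displacement, 0.0 for
    fully co-occurring (redundant) regulators.  A same-family pair is a
    candidate xenologous replacement.
    """
    by_id = {g.id: g for g in ortholog_groups}
    families = tf_families or {}
    by_subsystem: dict[str, list[str]] = {}
    for grp_id, label in sorted(subsystem_assignments.items()):
        by_subsystem.setdefault(label, []).append(grp_id)
    out = []
    for subsystem in sorted(by_subsystem):
        members = by_subsystem[subsystem]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = by_id[members[i]], by_id[members[j]]
                pa, pb = a.genomes, b.genomes
                union = pa | pb
                exactly_one = (pa ^ pb) & union
                fam_a, fam_b = families.get(a.id), families.get(b.id)
                out.append(
                    DisplacementPair(
                        subsystem=subsystem,
                        tf_group_a=a.id,
                        tf_group_b=b.id,
                        same_family=fam_a is not None and fam_a == fam_b,
                        overlap=pa & pb,
                        complementarity=len(exactly_one) / len(union) if union else 0.0,
                    )
                )
    return out
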