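"""Census, motif-conservation categories, regulon content, displacement."""

import numpy as np
import pytest

from regulonkit.comparative import (
    align_pwms,
    categorize_motif_conservation,
    census,
    compare_regulon_content,
    detect_displacements,
    pwm_similarity,
)
from regulonkit.genomes import Gene, Genome, GenomeSet
from regulonkit.motifs import PWM, build_pwm
from regulonkit.orthology import OrthologGroup


def _genome(gid, lineage, tf_families):
    genes = [
        Gene(id=f"{gid}_t{i}", replicon="c", start=100 * i + 1, end=100 * i + 60,
             strand="+", protein="M" * 20, is_tf=True, tf_family=fam)
        for i, fam in enumerate(tf_families)
    ]
    return Genome(id=gid, lineage=lineage,
                  sequences={"c": "A" * 2000}, genes=genes)


class TestCensus:
    def test_counts_majors_and_lineage_specific(self):
        gs = GenomeSet(genomes={
            "g1": _genome("g1", "L1", ["LacI", "LacI", "TetR"]),
            "g2": _genome("g2", "L1", ["LacI", "LacI", "LacI"]),
            "g3": _genome("g3", "L2", ["TetR"]),
        })
        c = census(gs, [])
        assert c.per_genome_tf_count.to_dict() == {"g1": 3, "g2": 3, "g3": 1}
        assert c.family_counts.loc["LacI", "g1"] == 2
        assert "LacI" in c.major_families["L1"]  # mean 2.5 per genome
        assert "TetR" not in c.major_families["L1"]
        assert c.lineage_specific_families == {"L1": ["LacI"], "L2": []}

    def test_census_invariant_under_genome_reordering(self):
        genomes = {
            "g1": _genome("g1", "L1", ["LacI"]),
            "g2": _genome("g2", "L1", ["TetR", "TetR"]),
        }
        a = census(GenomeSet(genomes=dict(genomes)), [])
        b = census(GenomeSet(genomes=dict(reversed(list(genomes.items())))), [])
        assert a.family_counts.equals(b.family_counts)
        assert a.per_genome_tf_count.equals(b.per_genome_tf_count)

    def test_planted_family_sizes_recovered(self, mini_world):
        gs = mini_world["genome_set"]
        truth = mini_world["truth"]
        c = census(gs, mini_world["groups"])
        for name, keys in truth.tf_genes.items():
            assert c.family_counts.loc[name].sum() == len(keys)


def _pwm_from_consensus(consensus, p=0.9):
    w = len(consensus)
    counts = np.full((w, 4), (1 - p) / 3 * 100)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = p * 100
    return PWM(counts, pseudocount=0.5)


class TestAlignPWMs:
    def test_identity_gives_zero_mismatches_at_zero_offset(self):
        pwm = _pwm_from_consensus("TTGACAATGTTGTCAA")
        cmp = align_pwms(pwm, pwm)
        assert (cmp.offset, cmp.orientation, cmp.mismatches) == (0, "forward", 0)
        assert cmp.category == "I"

    def test_reverse_complement_found_in_flipped_orientation(self):
        pwm = _pwm_from_consensus("TTGACAATGCAGTCAA")
        cmp = align_pwms(pwm, pwm.reverse_complement())
        assert cmp.orientation == "reverse"
        assert cmp.mismatches == 0

    def test_three_consensus_edits_count_as_three_mismatches(self):
        a = _pwm_from_consensus("TTGACAATGTTGTCAA")
        b = _pwm_from_consensus("TAGACCATGTTGTGAA")  # edits at 1, 5, 13
        cmp = align_pwms(a, b)
        assert cmp.mismatches == 3
        assert cmp.category == "II"

    def test_width_gap_over_six_rejected(self):
        a = _pwm_from_consensus("TTGACAAT")
        b = _pwm_from_consensus("TTGACAATGTTGTCAAT")
        with pytest.raises(ValueError):
            align_pwms(a, b)

    def test_too_little_overlap_is_category_three(self):
        a = _pwm_from_consensus("TTGACA")
        b = _pwm_from_consensus("GTCAAT")
        cmp = align_pwms(a, b)  # width 6 < min overlap 8
        assert cmp.mismatches is None
        assert cmp.category == "III"

    def test_pwm_similarity_of_identical_pwms_is_one(self):
        pwm = _pwm_from_consensus("TTGACAATGTTGTCAA")
        assert pwm_similarity(pwm, pwm) == pytest.approx(1.0)


class TestCategories:
    @pytest.mark.parametrize(
        "mismatches,expected",
        [(0, "I"), (1, "I"), (2, "II"), (3, "II"), (4, "II"),
         (5, "III"), (9, "III"), (None, "III")],
    )
    def test_boundaries_are_exact(self, mismatches, expected):
        assert categorize_motif_conservation(mismatches) == expected


class TestRegulonContent:
    def _models(self, mini_world, targets_a, targets_b):
        from regulonkit.motifs import Profile
        from regulonkit.regulons import Interaction, RegulonModel

        pwm = build_pwm(["TGACGTCA", "TGACGTCA"])
        prof = Profile(pwm=pwm, training_sites=["TGACGTCA"], name="x")

        def model(lineage, targets):
            inter = [
                Interaction(genome=g, tf_group="OGX", operon=o, sites=[], support=3)
                for g, o in targets
            ]
            return RegulonModel(tf_group="OGX", lineage=lineage, profile=prof,
                                interactions=inter, workflow="1a")

        return model("A", targets_a), model("B", targets_b)

    def test_identical_ortholog_content_is_strictly_conserved(self, mini_world):
        index = mini_world["index"]
        truth = mini_world["truth"]
        name = sorted(truth.regulon_members)[0]
        targets = [
            (g, o) for g, ops in truth.regulon_members[name].items() for o in ops
        ]
        a, b = self._models(mini_world, targets, targets)
        cmp = compare_regulon_content(a, b, mini_world["groups"], index)
        assert cmp.content_class == "strictly_conserved"
        assert cmp.jaccard == 1.0
        assert not cmp.periphery_a and not cmp.periphery_b

    def test_disjoint_content_is_different(self, mini_world):
        index = mini_world["index"]
        truth = mini_world["truth"]
        names = sorted(truth.regulon_members)[:2]
        t = [
            [(g, o) for g, ops in truth.regulon_members[n].items() for o in ops]
            for n in names
        ]
        # drop any operons shared between the two regulons (cascade targets)
        index_map = mini_world["index"]
        shared = {x for x in t[0]} & {x for x in t[1]}
        a, b = self._models(mini_world, [x for x in t[0] if x not in shared][:6],
                            [x for x in t[1] if x not in shared][:6])
        cmp = compare_regulon_content(a, b, mini_world["groups"], index)
        assert cmp.content_class == "different"
        assert not cmp.core

    def test_counts_are_conserved(self, mini_world):
        index = mini_world["index"]
        truth = mini_world["truth"]
        names = sorted(truth.regulon_members)[:2]
        t = [
            [(g, o) for g, ops in truth.regulon_members[n].items() for o in ops]
            for n in names
        ]
        a, b = self._models(mini_world, t[0], t[0][:3] + t[1][:3])
        cmp = compare_regulon_content(a, b, mini_world["groups"], index)
        from regulonkit.orthology import gene_to_group_map

        to_group = gene_to_group_map(mini_world["groups"])
        groups_a = set()
        for g, o in t[0]:
            lead = index.lead_gene_key(g, o)
            groups_a.add(to_group.get(lead, f"singleton:{lead[0]}:{lead[1]}"))
        assert len(cmp.core) + len(cmp.periphery_a) == len(groups_a)

    def test_mean_under_three_targets_per_genome_is_local(self, mini_world):
        # 5 genomes x 2-3 target operons: mean 2.4 -> local
        targets = [("g01", "a"), ("g01", "b"), ("g01", "c"),
                   ("g02", "a"), ("g02", "b"),
                   ("g03", "a"), ("g03", "b"), ("g03", "c"),
                   ("g04", "a"), ("g04", "b"),
                   ("g05", "a"), ("g05", "b")]
        from regulonkit.comparative import _size_class
        from regulonkit.motifs import Profile
        from regulonkit.regulons import Interaction, RegulonModel

        pwm = build_pwm(["TGACGTCA", "TGACGTCA"])
        model = RegulonModel(
            tf_group="OGX", lineage="A",
            profile=Profile(pwm=pwm, training_sites=["TGACGTCA"], name="x"),
            interactions=[
                Interaction(genome=g, tf_group="OGX", operon=o, sites=[], support=3)
                for g, o in targets
            ],
            workflow="1a",
        )
        assert _size_class(model) == "local"


class TestDisplacement:
    def _groups(self, presence_a, presence_b):
        a = OrthologGroup(id="OGa", members={g: {f"{g}_a"} for g in presence_a})
        b = OrthologGroup(id="OGb", members={g: {f"{g}_b"} for g in presence_b})
        return [a, b]

    def test_disjoint_same_family_pair_is_xenologous_with_full_complementarity(self):
        genomes = [f"g{i}" for i in range(10)]
        groups = self._groups(genomes[:5], genomes[5:])
        pairs = detect_displacements(
            {"OGa": "maltose", "OGb": "maltose"}, groups,
            tf_families={"OGa": "LacI", "OGb": "LacI"},
        )
        (pair,) = pairs
        assert pair.same_family
        assert pair.complementarity == 1.0
        assert pair.overlap == set()

    def test_fully_co_occurring_pair_has_zero_complementarity(self):
        genomes = [f"g{i}" for i in range(6)]
        groups = self._groups(genomes, genomes)
        (pair,) = detect_displacements(
            {"OGa": "s", "OGb": "s"}, groups,
            tf_families={"OGa": "LacI", "OGb": "TetR"},
        )
        assert not pair.same_family
        assert pair.complementarity == 0.0
        assert pair.overlap == set(genomes)

    def test_partial_overlap_counts(self):
        groups = self._groups(["g1", "g2", "g3"], ["g3", "g4"])
        (pair,) = detect_displacements({"OGa": "s", "OGb": "s"}, groups)
        assert pair.overlap == {"g3"}
        assert pair.complementarity == pytest.approx(3 / 4)
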