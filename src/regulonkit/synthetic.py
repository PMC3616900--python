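"""Seeded generator of genome collections with planted regulatory truth.

The generator emulates the statistical structure the reconstruction
pipeline assumes: ortholog families at a controlled protein identity,
genomes laid out as conserved operon blocks, upstream intergenic space
with an order-0 background, planted TF binding sites drawn from a known
PWM in a controlled fraction of genomes, and near-threshold decoy words
that exercise the consistency filter.  Everything is deterministic given
(config, seed), and every planted feature is recorded in a TruthTable
for precision/recall evaluation.

Layout model: a single ancestral gene order shared by all genomes, genes
grouped into operon blocks (1-3 genes, one strand per block), short
within-operon gaps and long between-operon gaps so that operon
prediction at the default 100 bp cutoff reproduces the blocks exactly.
TF and regulon-member families are present in every genome; filler
families drop out of genomes at random, which makes conservation
classes non-trivial.  Sites sit in the intergenic gap 5' of the member
operon's lead gene, inside the default upstream window and clear of
coding sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from . import __version__
from .genomes import Gene, Genome, GenomeSet, reverse_complement, write_genome
from .motifs import PWM, UNIFORM, project_symmetry, score_site
from .orthology import GeneKey

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


@dataclass
class RegulonSpec:
    """One planted regulon: its PWM and its per-genome realization."""

    name: str
    width: int = 18
    symmetry: str = "palindrome"
    information_content: float = 16.0
    n_member_operons: int = 6
    presence_prob: float = 0.8
    autoregulation_prob: float = 0.72

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")
        if self.width < 6:
            raise ValueError("width must be >= 6")


@dataclass
class SyntheticConfig:
    lineages: dict[str, int] = field(default_factory=lambda: {"lineage_a": 5, "lineage_b": 5})
    n_families: int = 60
    family_presence: float = 0.9
    within_family_identity: float = 0.60
    protein_length: tuple[int, int] = (150, 400)
    gc_range: tuple[float, float] = (0.35, 0.45)
    operon_size_probs: tuple[float, ...] = (0.6, 0.25, 0.15)  # sizes 1,2,3
    intra_operon_gap: tuple[int, int] = (5, 60)
    inter_operon_gap: tuple[int, int] = (150, 350)
    regulons: list[RegulonSpec] = field(default_factory=list)
    decoy_rate: float = 1.0  # expected near-threshold false sites per region
    cascades: list[tuple[str, str]] = field(default_factory=list)
    shared_targets: int = 0  # member operons shared by consecutive regulon pairs
    terminal_truncation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.within_family_identity <= 1.0:
            raise ValueError("within_family_identity must be in (0, 1]")
        n_reg_ops = sum(r.n_member_operons + 1 for r in self.regulons)
        if self.n_families < n_reg_ops + 3:
            raise ValueError("n_families too small for the requested regulons")
        for r in self.regulons:
            if r.width + 10 > self.inter_operon_gap[0]:
                raise ValueError(
                    f"regulon {r.name}: motif width {r.width} does not fit the "
                    f"minimum intergenic gap {self.inter_operon_gap[0]}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "regulons" in raw:
            raw["regulons"] = [RegulonSpec(**r) for r in raw["regulons"]]
        for key in ("protein_length", "gc_range", "intra_operon_gap", "inter_operon_gap"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cascades" in raw:
            raw["cascades"] = [tuple(c) for c in raw["cascades"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["regulons"] = [dict(r.__dict__) for r in self.regulons]
        d["cascades"] = [list(c) for c in self.cascades]
        for key in ("protein_length", "gc_range", "intra_operon_gap", "inter_operon_gap",
                    "operon_size_probs"):
            d[key] = list(d[key])
        return d


@dataclass
class TruthSite:
    regulon: str
    genome: str
    operon: str
    offset: int  # 0-based start within the default upstream region
    strand: str  # relative to the region (sites are planted on the coding strand)
    sequence: str
    replicon: str
    genomic_start: int  # 1-based
    is_decoy: bool = False
    score: float = 0.0


@dataclass
class TruthTable:
    families: dict[str, list[GeneKey]]
    tf_genes: dict[str, list[GeneKey]]  # regulon name -> TF gene per genome
    sites: list[TruthSite]
    regulon_members: dict[str, dict[str, set[str]]]  # regulon -> genome -> operons
    pwms: dict[str, PWM]
    thresholds: dict[str, float]  # min planted-site score per regulon
    cascades: list[tuple[str, str]]
    coregulated: list[tuple[str, str, tuple[str, ...]]]  # genome, operon, regulons
    autoregulation: dict[str, dict[str, bool]]

    def planted_interactions(self) -> set[tuple[str, str, str]]:
        """(regulon, genome, operon) triples with at least one planted site."""
        return {
            (s.regulon, s.genome, s.operon) for s in self.sites if not s.is_decoy
        }


# ---------------------------------------------------------------------------
# PWM and protein synthesis


def _consensus_prob_for_ic(bits_per_column: float) -> float:
    """Consensus-base probability giving a column the requested
    information (uniform background, the other three bases equiprobable)."""

    def ic(p: float) -> float:
        q = (1.0 - p) / 3.0
        val = p * np.log2(4 * p)
        if q > 0:
            val += 3 * q * np.log2(4 * q)
        return val

    target = min(max(bits_per_column, 1e-6), 2.0 - 1e-9)
    return brentq(lambda p: ic(p) - target, 0.25 + 1e-9, 1.0 - 1e-12)


def make_planted_pwm(
    width: int,
    information_content: float,
    symmetry: str,
    rng: np.random.Generator,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> PWM:
    """A synthetic PWM of the requested width, symmetry and total IC.

    Built from a random consensus (made symmetric for palindromes) with a
    per-column consensus probability solved to hit the IC target.  The
    PWM's background should be the composition of the genomes the sites
    are planted into, so that planted-site and decoy scores mean the
    same thing to the generator and to a scanner that estimates its
    background from those genomes.
    """
    p = _consensus_prob_for_ic(information_content / width)
    if symmetry == "palindrome":
        half = [int(rng.integers(4)) for _ in range(width // 2)]
        mid = [int(rng.integers(4))] if width % 2 else []
        consensus = half + mid + [3 - b for b in reversed(half)]
    else:
        consensus = [int(rng.integers(4)) for _ in range(width)]
    counts = np.full((width, 4), (1.0 - p) / 3.0 * 1000)
    for i, b in enumerate(consensus):
        counts[i, b] = p * 1000
    if symmetry != "none":
        counts = project_symmetry(counts, symmetry)
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    return PWM(counts, pseudocount=pseudocount, background=bg, symmetry=symmetry)


def sample_site(
    pwm: PWM,
    rng: np.random.Generator,
    min_score: float | None = None,
    max_tries: int = 200,
) -> str:
    """Sample one site from a PWM, optionally conditioned on a score floor.

    Functional binding sites are not arbitrary draws from the frequency
    model: selection keeps only instances the TF actually binds, so
    planted sites are rejection-sampled until they reach ``min_score``
    (falling back to the best draw seen if the floor proves hard to hit).
    """
    freq = pwm.frequencies
    best_word, best_score = None, -np.inf
    for _ in range(max_tries if min_score is not None else 1):
        word = "".join(
            BASES[rng.choice(4, p=freq[i] / freq[i].sum())] for i in range(pwm.width)
        )
        if min_score is None:
            return word
        score = score_site(pwm, word)
        if score >= min_score:
            return word
        if score > best_score:
            best_word, best_score = word, score
    return best_word


def make_decoy(
    pwm: PWM, threshold: float, rng: np.random.Generator, max_tries: int = 400
) -> str | None:
    """A word scoring in [threshold - 2, threshold) bits under the PWM.

    Starts from a sampled site and random-walks the score toward a
    target drawn uniformly inside the band (so decoys spread over the
    whole band instead of hugging the threshold).
    """
    target = float(rng.uniform(threshold - 1.8, threshold - 0.2))
    word = list(sample_site(pwm, rng))
    score = score_site(pwm, "".join(word))
    for _ in range(max_tries):
        if score <= target and threshold - 2.0 <= score < threshold:
            return "".join(word)
        pos = int(rng.integers(pwm.width))
        base = BASES[rng.integers(4)]
        if base == word[pos]:
            continue
        trial = word.copy()
        trial[pos] = base
        trial_score = score_site(pwm, "".join(trial))
        moves_down = trial_score < score and trial_score >= threshold - 2.0
        moves_up = trial_score > score and trial_score < threshold
        if (score > target and moves_down) or (score < target and moves_up):
            word, score = trial, trial_score
    if threshold - 2.0 <= score < threshold:
        return "".join(word)
    return None


def mutate_protein(
    ancestor: str, identity: float, rng: np.random.Generator
) -> str:
    """Substitute residues so two independent copies have expected
    pairwise identity ``identity`` (per-copy rate q = 1 - sqrt(t))."""
    q = 1.0 - np.sqrt(identity)
    out = list(ancestor)
    for i in np.flatnonzero(rng.random(len(ancestor)) < q):
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, n, p=p))


# ---------------------------------------------------------------------------
# generation


@dataclass
class _Block:
    """One ancestral operon block: ordered families plus a strand."""

    index: int
    families: list[str]
    strand: str


def _layout_blocks(config: SyntheticConfig, rng: np.random.Generator) -> tuple[
    list[_Block], dict[str, str], dict[str, list[int]], dict[str, int]
]:
    """Assign families to operon blocks and pick regulon roles.

    Returns blocks, tf_family per regulon, member block indices per
    regulon, and the TF's own block per regulon.
    """
    fam_ids = [f"F{i + 1:04d}" for i in range(config.n_families)]
    blocks: list[_Block] = []
    i = 0
    sizes = np.arange(1, len(config.operon_size_probs) + 1)
    probs = np.asarray(config.operon_size_probs) / np.sum(config.operon_size_probs)
    reserved = {}  # regulon -> tf family (singleton blocks first)
    for spec in config.regulons:
        reserved[spec.name] = fam_ids[i]
        blocks.append(_Block(len(blocks), [fam_ids[i]], "+" if rng.random() < 0.5 else "-"))
        i += 1
    while i < config.n_families:
        size = int(rng.choice(sizes, p=probs))
        size = min(size, config.n_families - i)
        blocks.append(
            _Block(len(blocks), fam_ids[i : i + size], "+" if rng.random() < 0.5 else "-")
        )
        i += size

    tf_block = {spec.name: b for b, spec in zip(range(len(config.regulons)), config.regulons)}
    non_tf_blocks = list(range(len(config.regulons), len(blocks)))
    members: dict[str, list[int]] = {}
    cursor = 0
    prev_members: list[int] = []
    for spec in config.regulons:
        take = spec.n_member_operons
        shared = min(config.shared_targets, len(prev_members), take)
        chosen = prev_members[:shared]
        fresh = non_tf_blocks[cursor : cursor + take - shared]
        cursor += take - shared
        if len(fresh) + shared < take:
            raise ValueError("not enough operon blocks for regulon members")
        members[spec.name] = chosen + fresh
        prev_members = members[spec.name]
    # shuffle block order so regulon members are scattered along the replicon
    order = rng.permutation(len(blocks))
    pos = {int(b): i for i, b in enumerate(order)}
    blocks = [blocks[int(b)] for b in order]
    for j, blk in enumerate(blocks):
        blk.index = j
    members = {k: [pos[b] for b in v] for k, v in members.items()}
    tf_block = {k: pos[b] for k, b in tf_block.items()}
    return blocks, reserved, members, tf_block


def generate(config: SyntheticConfig, seed: int | None = None) -> tuple[GenomeSet, TruthTable]:
    """Generate a genome collection with planted regulons and full truth.

    Deterministic given (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    blocks, tf_family, member_blocks, tf_block = _layout_blocks(config, rng)

    # ancestral proteins and per-regulon PWMs
    ancestors = {}
    for blk in blocks:
        for fam in blk.families:
            ancestors[fam] = _random_protein(rng, *config.protein_length)
    mean_gc = float(np.mean(config.gc_range))
    genome_bg = np.array(
        [(1 - mean_gc) / 2, mean_gc / 2, mean_gc / 2, (1 - mean_gc) / 2]
    )
    pwms = {
        spec.name: make_planted_pwm(
            spec.width, spec.information_content, spec.symmetry, rng,
            background=genome_bg,
        )
        for spec in config.regulons
    }

    core_families = {fam for spec in config.regulons for fam in [tf_family[spec.name]]}
    for spec in config.regulons:
        for b in member_blocks[spec.name]:
            core_families.update(blocks[b].families)

    genome_ids: list[tuple[str, str]] = []
    n_total = 0
    for lineage, count in config.lineages.items():
        for _ in range(count):
            n_total += 1
            genome_ids.append((f"g{n_total:02d}", lineage))

    genomes: dict[str, Genome] = {}
    families: dict[str, list[GeneKey]] = {fam: [] for fam in ancestors}
    # per genome: block index -> (lead gene id, gap interval, strand, anchor)
    slot_info: dict[str, dict[int, dict]] = {}
    seqs: dict[str, list[str]] = {}

    for gid, lineage in genome_ids:
        gc = float(rng.uniform(*config.gc_range))
        present: dict[str, bool] = {}
        for blk in blocks:
            for fam in blk.families:
                present[fam] = fam in core_families or rng.random() < config.family_presence
        chunks: list[str] = []
        genes: list[Gene] = []
        pos = 1  # next free 1-based coordinate
        slots: dict = {}
        replicon = f"{gid}_chr"
        for blk in blocks:
            blk_fams = [f for f in blk.families if present[f]]
            if not blk_fams:
                continue
            gap = int(rng.integers(*config.inter_operon_gap))
            chunks.append(_random_dna(rng, gap, gc))
            gap_start, gap_end = pos, pos + gap - 1
            pos += gap
            if blk.strand == "-":
                blk_fams = list(reversed(blk_fams))
            block_genes = []
            for k, fam in enumerate(blk_fams):
                if k > 0:
                    intra = int(rng.integers(*config.intra_operon_gap))
                    chunks.append(_random_dna(rng, intra, gc))
                    pos += intra
                protein = mutate_protein(ancestors[fam], config.within_family_identity, rng)
                if config.terminal_truncation_prob and rng.random() < config.terminal_truncation_prob:
                    keep = int(len(protein) * rng.uniform(0.5, 0.9))
                    protein = protein[:keep]
                dna_len = 3 * len(protein) + 3
                chunks.append(_random_dna(rng, dna_len, gc))
                gene = Gene(
                    id=f"{gid}_{fam}",
                    replicon=replicon,
                    start=pos,
                    end=pos + dna_len - 1,
                    strand=blk.strand,
                    protein=protein,
                    is_tf=False,
                )
                pos += dna_len
                block_genes.append(gene)
                genes.append(gene)
                families[fam].append((gid, gene.id))
            # upstream slot: the gap before the block for + operons; the
            # gap *after* the block for - operons (resolved in a second
            # pass once the following gap is known)
            if blk.strand == "+":
                slots[blk.index] = {
                    "lead": block_genes[0],
                    "gap": (gap_start, gap_end),
                    "strand": "+",
                }
            slots.setdefault("_pending", []).append(
                (blk.index, blk.strand, block_genes, (gap_start, gap_end))
            )
        # trailing gap so the last minus-strand block has upstream space
        tail = int(rng.integers(*config.inter_operon_gap))
        chunks.append(_random_dna(rng, tail, gc))
        tail_interval = (pos, pos + tail - 1)
        pos += tail

        # second pass: attach the following gap to minus-strand blocks
        pending = slots.pop("_pending")
        for j, (bidx, strand, block_genes, gap_iv) in enumerate(pending):
            if strand == "+":
                continue
            nxt = pending[j + 1][3] if j + 1 < len(pending) else tail_interval
            slots[bidx] = {"lead": block_genes[-1], "gap": nxt, "strand": "-"}

        seqs[gid] = list("".join(chunks))
        slot_info[gid] = slots
        genome = Genome(id=gid, lineage=lineage, sequences={replicon: ""}, genes=[])
        genome.genes = genes  # sequences filled after site planting
        genomes[gid] = genome

    # mark TF genes
    tf_genes: dict[str, list[GeneKey]] = {spec.name: [] for spec in config.regulons}
    for spec in config.regulons:
        fam = tf_family[spec.name]
        for gid, gene_id in families[fam]:
            genomes[gid].gene(gene_id).is_tf = True
            genomes[gid].gene(gene_id).tf_family = spec.name
            tf_genes[spec.name].append((gid, gene_id))

    # ------------------------------------------------------------------
    # site planting
    occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}
    planted: list[dict] = []

    def _plant_word(gid: str, bidx: int, word: str, max_d: int = 70) -> tuple[int, int] | None:
        """Write a word into the upstream gap of a block; returns the
        distance d from the translation start and the genomic start."""
        slot = slot_info[gid].get(bidx)
        if slot is None:
            return None
        gap_start, gap_end = slot["gap"]
        gap = gap_end - gap_start + 1
        w = len(word)
        hi_d = min(gap // 2 - 2, max_d)
        lo_d = w + 3
        if hi_d < lo_d:
            return None
        lead = slot["lead"]
        taken = occupied.setdefault((gid, bidx), [])
        for _ in range(12):
            d = int(rng.integers(lo_d, hi_d + 1))
            if slot["strand"] == "+":
                gstart = lead.start - d  # 1-based start of the word
                placed = word
            else:
                gstart = lead.end + d - w + 1
                placed = reverse_complement(word)
            iv = (gstart, gstart + w - 1)
            if any(not (iv[1] < a or iv[0] > b) for a, b in taken):
                continue
            if iv[0] < gap_start or iv[1] > gap_end:
                continue
            seq = seqs[gid]
            seq[iv[0] - 1 : iv[1]] = list(placed)
            taken.append(iv)
            return d, gstart
        return None

    # planted sites are conditioned on reaching half the motif's total
    # information: a weaker word would not be a functional, selectable site
    member_sites: list[dict] = []
    floors = {name: 0.5 * pwm.information_content for name, pwm in pwms.items()}
    for spec in config.regulons:
        pwm = pwms[spec.name]
        for gid, _ in genome_ids:
            for bidx in member_blocks[spec.name]:
                if rng.random() >= spec.presence_prob:
                    continue
                word = sample_site(pwm, rng, min_score=floors[spec.name])
                res = _plant_word(gid, bidx, word)
                if res is None:
                    continue
                d, gstart = res
                member_sites.append(
                    dict(regulon=spec.name, genome=gid, block=bidx, d=d,
                         gstart=gstart, word=word, kind="member")
                )
        # autoregulation: a site upstream of the TF's own operon
        for gid, _ in genome_ids:
            if rng.random() >= spec.autoregulation_prob:
                continue
            word = sample_site(pwm, rng, min_score=floors[spec.name])
            res = _plant_word(gid, tf_block[spec.name], word)
            if res is not None:
                d, gstart = res
                member_sites.append(
                    dict(regulon=spec.name, genome=gid, block=tf_block[spec.name],
                         d=d, gstart=gstart, word=word, kind="auto")
                )
    # cascades: regulator A gains a site upstream of regulator B's operon
    for reg_a, reg_b in config.cascades:
        pwm = pwms[reg_a]
        for gid, _ in genome_ids:
            word = sample_site(pwm, rng, min_score=floors[reg_a])
            res = _plant_word(gid, tf_block[reg_b], word)
            if res is not None:
                d, gstart = res
                member_sites.append(
                    dict(regulon=reg_a, genome=gid, block=tf_block[reg_b],
                         d=d, gstart=gstart, word=word, kind="cascade")
                )

    # reference threshold per regulon = lowest planted-site score
    thresholds = {}
    for spec in config.regulons:
        scores = [
            score_site(pwms[spec.name], m["word"])
            for m in member_sites
            if m["regulon"] == spec.name
        ]
        thresholds[spec.name] = min(scores) if scores else np.nan

    decoy_sites: list[dict] = []
    decoyable = [
        spec.name
        for spec in config.regulons
        if np.isfinite(thresholds.get(spec.name, np.nan))
    ]
    if decoyable and config.decoy_rate > 0:
        for gid, _ in genome_ids:
            for bidx, slot in sorted(slot_info[gid].items()):
                n_decoys = int(rng.poisson(config.decoy_rate))
                for _ in range(n_decoys):
                    name = decoyable[int(rng.integers(len(decoyable)))]
                    word = make_decoy(pwms[name], thresholds[name], rng)
                    if word is None:
                        continue
                    res = _plant_word(gid, bidx, word)
                    if res is not None:
                        d, gstart = res
                        decoy_sites.append(
                            dict(regulon=name, genome=gid, block=bidx, d=d,
                                 gstart=gstart, word=word, kind="decoy")
                        )

    # ------------------------------------------------------------------
    # finalize sequences and compute region-local truth coordinates
    from .genomes import extract_upstream, predict_operons

    for gid, _ in genome_ids:
        replicon = f"{gid}_chr"
        genomes[gid].sequences[replicon] = "".join(seqs[gid])

    # region geometry per realized operon, for mapping planted words to
    # region-local coordinates; a site in the shared gap of divergently
    # transcribed operons lies in BOTH upstream regions and is truth for
    # both (a dyad-symmetric site in a shared promoter region is
    # accessible to either operon's scan)
    block_to_operon: dict[tuple[str, int], str] = {}
    region_geo: dict[str, dict[str, tuple[str, int, int]]] = {}  # gid -> op -> (strand, lo, hi)
    for gid, _ in genome_ids:
        genome = genomes[gid]
        operons = predict_operons(genome)
        lead_to_op = {op.lead_gene: op for op in operons}
        region_geo[gid] = {}
        for bidx, slot in slot_info[gid].items():
            op = lead_to_op[slot["lead"].id]
            block_to_operon[(gid, bidx)] = op.id
            region = extract_upstream(op, genome)
            lead = slot["lead"]
            if region.strand == "+":
                lo = lead.start - region.n_upstream
                hi = lo + len(region.sequence) - 1
            else:
                hi = lead.end + region.n_upstream
                lo = hi - len(region.sequence) + 1
            region_geo[gid][op.id] = (region.strand, lo, hi)

    sites: list[TruthSite] = []
    for m in member_sites:
        gid = m["genome"]
        w = len(m["word"])
        g_start = m["gstart"]
        g_end = g_start + w - 1
        genomic_word = "".join(seqs[gid][g_start - 1 : g_end])
        for op_id, (strand, lo, hi) in sorted(region_geo[gid].items()):
            if g_start < lo or g_end > hi:
                continue
            if strand == "+":
                offset = g_start - lo
                word = genomic_word
            else:
                offset = hi - g_end
                word = reverse_complement(genomic_word)
            sites.append(
                TruthSite(
                    regulon=m["regulon"],
                    genome=gid,
                    operon=op_id,
                    offset=offset,
                    strand="+",
                    sequence=word,
                    replicon=f"{gid}_chr",
                    genomic_start=g_start,
                    is_decoy=False,
                    score=score_site(pwms[m["regulon"]], word),
                )
            )
    for m in decoy_sites:
        gid, bidx = m["genome"], m["block"]
        op_id = block_to_operon[(gid, bidx)]
        strand, lo, hi = region_geo[gid][op_id]
        g_start = m["gstart"]
        g_end = g_start + len(m["word"]) - 1
        offset = g_start - lo if strand == "+" else hi - g_end
        genomic_word = "".join(seqs[gid][g_start - 1 : g_end])
        word = genomic_word if strand == "+" else reverse_complement(genomic_word)
        sites.append(
            TruthSite(
                regulon=m["regulon"],
                genome=gid,
                operon=op_id,
                offset=offset,
                strand="+",
                sequence=word,
                replicon=f"{gid}_chr",
                genomic_start=g_start,
                is_decoy=True,
                score=score_site(pwms[m["regulon"]], word),
            )
        )

    regulon_members: dict[str, dict[str, set[str]]] = {
        spec.name: {} for spec in config.regulons
    }
    for s in sites:
        if not s.is_decoy:
            regulon_members[s.regulon].setdefault(s.genome, set()).add(s.operon)

    autoregulation: dict[str, dict[str, bool]] = {s.name: {} for s in config.regulons}
    for spec in config.regulons:
        for gid, _ in genome_ids:
            own_op = block_to_operon.get((gid, tf_block[spec.name]))
            autoregulation[spec.name][gid] = own_op in regulon_members[spec.name].get(
                gid, set()
            )

    coregulated: list[tuple[str, str, tuple[str, ...]]] = []
    seen_ops: dict[tuple[str, str], set[str]] = {}
    for s in sites:
        if not s.is_decoy:
            seen_ops.setdefault((s.genome, s.operon), set()).add(s.regulon)
    for (gid, op), regs in sorted(seen_ops.items()):
        if len(regs) >= 2:
            coregulated.append((gid, op, tuple(sorted(regs))))

    truth = TruthTable(
        families={k: sorted(v) for k, v in families.items()},
        tf_genes={k: sorted(v) for k, v in tf_genes.items()},
        sites=sorted(sites, key=lambda s: (s.regulon, s.genome, s.operon, s.offset)),
        regulon_members=regulon_members,
        pwms=pwms,
        thresholds=thresholds,
        cascades=list(config.cascades),
        coregulated=coregulated,
        autoregulation=autoregulation,
    )
    return GenomeSet(genomes=genomes), truth


# ---------------------------------------------------------------------------
# emission


def emit(
    genome_set: GenomeSet,
    truth: TruthTable,
    out_dir: str | Path,
    config: SyntheticConfig | None = None,
) -> list[Path]:
    """Write per-genome FASTA/GFF3/protein FASTA, truth TSVs and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for gid in sorted(genome_set.genomes):
        genome = genome_set.genomes[gid]
        fna, gff, faa = out / f"{gid}.fna", out / f"{gid}.gff", out / f"{gid}.faa"
        write_genome(genome, gff, fna, faa)
        written += [fna, gff, faa]

    p = out / "ortholog_families.tsv"
    with open(p, "w") as fh:
        fh.write("family\tgenome\tgene\n")
        for fam in sorted(truth.families):
            for gid, gene in truth.families[fam]:
                fh.write(f"{fam}\t{gid}\t{gene}\n")
    written.append(p)

    p = out / "tf_genes.tsv"
    with open(p, "w") as fh:
        fh.write("regulon\tgenome\tgene\n")
        for reg in sorted(truth.tf_genes):
            for gid, gene in truth.tf_genes[reg]:
                fh.write(f"{reg}\t{gid}\t{gene}\n")
    written.append(p)

    p = out / "planted_sites.tsv"
    with open(p, "w") as fh:
        fh.write(
            "regulon\tgenome\toperon\toffset\tstrand\tsequence\treplicon\t"
            "genomic_start\tis_decoy\tscore\n"
        )
        for s in truth.sites:
            fh.write(
                f"{s.regulon}\t{s.genome}\t{s.operon}\t{s.offset}\t{s.strand}\t"
                f"{s.sequence}\t{s.replicon}\t{s.genomic_start}\t"
                f"{int(s.is_decoy)}\t{s.score:.4f}\n"
            )
    written.append(p)

    p = out / "regulon_members.tsv"
    with open(p, "w") as fh:
        fh.write("regulon\tgenome\toperon\n")
        for reg in sorted(truth.regulon_members):
            for gid in sorted(truth.regulon_members[reg]):
                for op in sorted(truth.regulon_members[reg][gid]):
                    fh.write(f"{reg}\t{gid}\t{op}\n")
    written.append(p)

    manifest = {
        "package": "regulonkit",
        "version": __version__,
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "genomes": sorted(genome_set.genomes),
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
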