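"""Generate a synthetic genome collection with planted regulons.

Builds ten single-replicon genomes in one lineage, plants three
palindromic regulons (18 bp, ~16 bits each) plus near-threshold decoys,
and writes FASTA/GFF3/truth tables to ./scratch/example_sim.
"""

from regulonkit import RegulonSpec, SyntheticConfig, emit, generate

config = SyntheticConfig(
    lineages={"lineage_a": 10},
    n_families=60,
    regulons=[RegulonSpec(name=f"R{i}") for i in (1, 2, 3)],
    decoy_rate=1.0,
    cascades=[("R1", "R2")],
    seed=42,
)
genome_set, truth = generate(config, seed=42)
files = emit(genome_set, truth, "scratch/example_sim", config)

n_sites = sum(1 for s in truth.sites if not s.is_decoy)
n_decoys = sum(1 for s in truth.sites if s.is_decoy)
print(f"genomes: {len(genome_set)}")
print(f"genes per genome: {len(next(iter(genome_set)).genes)}")
print(f"planted sites: {n_sites}  (true binding sites recorded in the truth table)")
print(f"decoy sites:   {n_decoys} (score just below the planted profiles' thresholds)")
print(f"files written: {len(files)}")
# The planted sites are what a reconstruction should recover; the decoys
# are what the cross-genome consistency check should reject.
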