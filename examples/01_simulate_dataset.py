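"""Generate a small ground-truthed dataset and look at what was planted.

A 500 kb genome with 80 genes; 40 promoters are bound, each carrying one
22-bp motif whose 3'-half strength is drawn from a strong/weak mixture (plus
a motifless fraction).  The truth tables record every site's half-scores and
per-condition occupancy, and every gene's true expression effect.
"""

from occuclass import SyntheticConfig, generate_genome

config = SyntheticConfig(
    genome_length=500_000,
    n_genes=80,
    n_bound_promoters=40,
    n_direct_down=15,
    n_indirect=10,
    n_silent=6,
    depth_ip=300_000,
    depth_input=300_000,
    seed=7,
)
dataset = generate_genome(config)
sites, genes = dataset.truth.sites, dataset.truth.genes

print(f"genome: {sum(len(s) for s in dataset.genome.values()):,} bp, "
      f"{len(dataset.tss)} genes, {len(sites)} bound promoters")
print("\nsite classes (strength of the motif's 3' half):")
print(sites.strength.value_counts().to_string())
print("\nmean occupancy by class (wild type vs mutant):")
print(sites.groupby("strength")[["occupancy_wt", "occupancy_mut"]].mean().round(3))
print(f"\nsites losing occupancy in the mutant (>=90% loss): {sites.lost.sum()}")
print("\ngene truth labels:")
print(genes.label.value_counts().to_string())

# Weak-3' sites keep wild-type binding but collapse in the mutant; that
# asymmetry is what the downstream peak categories should recover.
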