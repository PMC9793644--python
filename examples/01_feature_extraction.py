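"""Extract the 170-column feature matrix from a small simulated dataset.

Builds 40 circRNA-like and 40 lncRNA-like transcripts with their Alu
annotation, runs all six encoder groups, and prints class means of a few
features that carry planted signal.
"""

from circstack import SimulationConfig, assemble_features, simulate_dataset

records, alu, manifest = simulate_dataset(
    SimulationConfig(n_pos=40, n_neg=40, length_range=(200, 1000), seed=1)
)
matrix = assemble_features(records, alu)
print(f"feature matrix: {len(matrix.ids)} transcripts x {matrix.n_features} features")

pos = matrix.labels == 1
for name in ("orf_coverage", "alu_total", "kmer_CGC", "tandem_repeat_freq"):
    j = matrix.feature_names.index(name)
    print(
        f"{name:>20}: circRNA mean {matrix.values[pos, j].mean():8.3f}   "
        f"lncRNA mean {matrix.values[~pos, j].mean():8.3f}"
    )
print(
    "\ncircRNAs were simulated with planted ORFs, CpG-trinucleotide bias and\n"
    "Alu-enriched flanks, so those features separate the classes; the tandem\n"
    "density difference is small relative to background repeat content."
)
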