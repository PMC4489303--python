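"""Export: sparse LIBSVM lines, dense CSV/TSV tables, heat-map matrices.

Generates RevKmer vectors for two labelled sequences and shows the three
machine-learning-ready text formats plus the row-major grid behind a
heat-map visualization (data only; plot it with any matrix viewer).
"""

from pseqfeat import (
    Alphabet,
    ParameterSet,
    heatmap_matrix,
    read_fasta,
    run_mode,
    validate_alphabet,
    write_delimited,
    write_libsvm,
)

fasta = ">pos1\nACGTACGTTTGCAGGCCA\n>neg1\nTTTTAAAACCCCGGGGTT\n"
seqs = [validate_alphabet(s, Alphabet.DNA) for s in read_fasta(fasta)]
vectors = run_mode("RevKmer", seqs, ParameterSet(k=2))

print("--- LIBSVM (sparse, 1-based index:value, zeros omitted) ---")
print(write_libsvm(vectors, labels=["+1", "-1"]), end="")

print("--- CSV (dense, header + one row per sequence) ---")
print(write_delimited(vectors, labels=["+1", "-1"], delimiter=",",
                      ids=[s.id for s in seqs]), end="")

print("--- heat-map grid for the first vector (2 rows x 5 columns) ---")
grid = heatmap_matrix(vectors[0], ncols=5)
for row_labels, row_vals in zip(grid.labels, grid.values):
    cells = [f"{l or '--'}={v:.3f}" for l, v in zip(row_labels, row_vals)]
    print("  " + "  ".join(cells))
# Cell (r, c) holds feature r*ncols + c; the trailing NaN cells pad the
# ragged last row so the grid is rectangular.
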