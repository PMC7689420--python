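"""Load a screen table and classify every point against thresholds.

Builds a small synthetic screen export, reads it back through the IO
layer exactly as a user CSV would be read, and classifies each gene as
unchanged / decreased / increased against a |log2 FC| > 1.5 and
-log10 p > 2 cutoff.
"""

from volcanokit import Thresholds, classify_data, read_volcano
from volcanokit.synthetic import SyntheticSpec, make_synthetic, write_fixture

data, _ = make_synthetic(SyntheticSpec(n_points=300, seed=8))
path = write_fixture(data, "csv", "/tmp/example_screen.csv")

loaded = read_volcano(
    path.read_bytes(), path.name,
    x_col="log2_fold_change", y_col="minus_log10_p", name_col="gene",
)
print(f"loaded {len(loaded)} records, dropped {loaded.n_dropped}")

classify_data(loaded, Thresholds.symmetric(1.5, 2.0))
counts = {}
for r in loaded.records:
    counts[r.category] = counts.get(r.category, 0) + 1
print("classification:", counts)
# counts sum to the record total: every point gets exactly one category;
# 'increased'/'decreased' are the points beyond both dashed cutoffs.
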