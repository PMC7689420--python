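"""Rank hits by the four criteria and merge a manual gene selection.

The default ranking is the Manhattan distance |x| + |y| from the plot
origin; Euclidean distance, absolute fold change and significance are the
alternatives.  A manually searched gene (here GNAS) is appended to the
annotation table when it is not already among the top hits.
"""

from volcanokit import (
    RankingSpec,
    Thresholds,
    merge_annotations,
    select_by_name,
    top_hits,
)
from volcanokit.synthetic import SyntheticSpec, make_synthetic

data, _ = make_synthetic(
    SyntheticSpec(n_points=1000, seed=4, planted_names=["GNAS"])
)
t = Thresholds.symmetric(1.5, 2.0)

for criterion in ("manhattan", "euclidean", "fold_change", "significance"):
    table = top_hits(data, t, RankingSpec(criterion, "significant", 5))
    print(f"{criterion:>12}: " + ", ".join(
        f"{e.record.name}({e.score:.2f})" for e in table.entries
    ))

table = top_hits(data, t, RankingSpec(direction="decreased", n_top=10))
merged = merge_annotations(table, select_by_name(data, ["gnas"]))
print(f"\ndecreased top-10 plus manual GNAS -> {len(merged)} annotations; "
      f"last origin = {merged.entries[-1].origin}")
# scores are distances from (0,0): larger = stronger * more significant.
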