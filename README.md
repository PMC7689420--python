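# volcanokit

Create, explore, label and share volcano plots of genome- and
proteome-wide screens — RNA-seq differential expression, CRISPR
proliferation screens, interactome mass-spec — from Python or the shell.

A volcano plot is a scatter of effect size against statistical
significance: x is typically the log2 fold change (0 = no change) and y
is −log10 of a p- or q-value (larger = more significant). Points beyond
a user-set fold-change cutoff *and* significance cutoff are hits,
classified `increased` (x > fc_high, y > sig) or `decreased`
(x < fc_low, y > sig); everything else — including points exactly on a
cutoff — is `unchanged`. Hits are ranked by distance from the origin
(0, 0):

* **manhattan** (default): |x| + |y|
* **euclidean**: √(x² + y²)
* **fold_change**: |x|
* **significance**: y

and the top n (default 10) are labeled in the plot and listed in a hit
table, optionally together with manually searched gene names.

The complete plot state — column mapping, thresholds, ranking, layout,
colors, labels, and the remote data URL — serializes to a single
share-URL (see `docs/share-url-grammar.md`), so a plot plus its data
source can be reconstructed from one string and passed around.

## Worked example

```python
from volcanokit import (RankingSpec, Thresholds, export, merge_annotations,
                        render, select_by_name, top_hits)
from volcanokit.synthetic import SyntheticSpec, make_synthetic

data, _ = make_synthetic(SyntheticSpec(n_points=1000, seed=4,
                                       planted_names=["GNAS"]))
t = Thresholds.symmetric(1.5, 2.0)            # |log2 FC| > 1.5, -log10 p > 2
table = top_hits(data, t, RankingSpec("manhattan", "significant", 5))
for e in table.entries:
    print(f"{e.rank:>2}  {e.record.name:<10} score={e.score:.2f}")
```

prints

```
 1  gene_74    score=14.43
 2  GNAS       score=14.22
 3  gene_61    score=12.47
 4  gene_19    score=12.35
 5  gene_14    score=12.34
```

— the five points with the largest |x| + |y| among all significantly
changed genes; `GNAS` ranks second because its large fold change (8.09)
plus significance sums just below the top gene's combined distance.
Rendering and export:

```python
fig = render(data, t, table)
export(fig, "png", "volcano.png")    # 800x600 bitmap
export(fig, "html", "volcano.html")  # hover any dot for name, x, y
```

The same pipeline from the shell, ending with a share-URL that
reproduces the run:

```sh
volcanokit --in screen.csv --x log2_fold_change --y minus_log10_p \
  --name gene --fc-thresh 1.5 --sig-thresh 2 --direction significant \
  --select GNAS --out volcano.png --emit-share-url
```

writes `volcano.png` and `hits.csv` and prints a URL whose decode equals
the settings used. A share-URL produced elsewhere runs directly
(`--share-url "<url>"`), fetching the linked CSV — or with
`--offline-data local.csv` standing in for the remote file.

The `examples/` directory holds one short narrative script per
capability: loading/classification, ranking, the URL round-trip,
rendering/export, and the CLI workflow.

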