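#!/bin/sh
# End-to-end shell workflow: generate a fixture, plot it, and print a
# share-URL that reproduces the run's settings.
set -e

python - <<'PY'
from volcanokit.synthetic import SyntheticSpec, make_synthetic, write_fixture
data, _ = make_synthetic(SyntheticSpec(n_points=400, seed=21,
                                       planted_names=["GNAS"]))
write_fixture(data, "csv", "/tmp/screen.csv")
print("wrote /tmp/screen.csv")
PY

volcanokit --in /tmp/screen.csv \
  --x log2_fold_change --y minus_log10_p --name gene \
  --fc-thresh 1.5 --sig-thresh 2 --direction significant --n-top 10 \
  --select GNAS --out /tmp/volcano.png --emit-share-url

# Output: /tmp/volcano.png, /tmp/hits.csv, and a URL whose decode equals
# the settings used above.
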