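"""Deterministic screen-shaped synthetic data.

Real comparative screens (RNA-seq, CRISPR proliferation, interactome
mass-spec) produce tables where the vast majority of genes sit near zero
effect with low significance and a small minority are strong hits.  The
generator here emulates exactly that shape — nothing more — so every
pipeline stage can be exercised offline with a known ground truth:

* nulls: x ~ Normal(0, noise_scale); y ~ Exponential(1) truncated below
  ``sig_shape`` so no null crosses a hit's significance floor;
* hits:  |x| ~ effect_scale + Exponential(1), sign per direction;
         y ~ sig_shape + Exponential(1).

The same seed always yields byte-identical output.  No claim of
biological realism is made: values are already-summarized (x, y) pairs,
not counts or p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import VolcanoData, VolcanoRecord


@dataclass
class SyntheticSpec:
    """Shape parameters of one synthetic screen table.

    ``effect_scale`` is the minimum |x| of a true hit (log2 units);
    ``noise_scale`` the standard deviation of null x; ``sig_shape`` the
    floor of hit significance and ceiling of null significance, giving a
    clean separation usable as a classification ground truth.
    """

    n_points: int = 1000
    frac_increased: float = 0.05
    frac_decreased: float = 0.05
    effect_scale: float = 3.0
    noise_scale: float = 0.5
    sig_shape: float = 4.0
    seed: int = 0
    planted_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if min(self.frac_increased, self.frac_decreased) < 0 or (
            self.frac_increased + self.frac_decreased > 1
        ):
            raise ValueError(
                "frac_increased and frac_decreased must be non-negative "
                "and sum to at most 1"
            )


def _truncated_exponential(
    rng: np.random.Generator, n: int, upper: float
) -> np.ndarray:
    # inverse-CDF sampling of Exp(1) conditioned on [0, upper)
    u = rng.random(n)
    return -np.log1p(-u * (1.0 - math.exp(-upper)))


def make_synthetic(spec: SyntheticSpec) -> tuple[VolcanoData, list[str]]:
    """Generate a table plus the ground-truth category of every record.

    Returns ``(data, truth)`` where ``truth[i]`` is the intended category
    of ``data.records[i]``.  Planted names are assigned to the strongest
    (largest |x|) increased hits first, then decreased hits; remaining
    records get ``gene_<k>`` names.  Record order is shuffled so hits are
    interspersed as in a real export.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_points
    n_up = int(round(spec.frac_increased * n))
    n_down = int(round(spec.frac_decreased * n))
    n_null = n - n_up - n_down

    x_null = rng.normal(0.0, spec.noise_scale, n_null)
    y_null = _truncated_exponential(rng, n_null, spec.sig_shape)
    x_up = spec.effect_scale + rng.exponential(1.0, n_up)
    y_up = spec.sig_shape + rng.exponential(1.0, n_up)
    x_down = -(spec.effect_scale + rng.exponential(1.0, n_down))
    y_down = spec.sig_shape + rng.exponential(1.0, n_down)

    xs = np.concatenate([x_up, x_down, x_null])
    ys = np.concatenate([y_up, y_down, y_null])
    truth = ["increased"] * n_up + ["decreased"] * n_down + ["unchanged"] * n_null

    names = [""] * n
    planted = list(spec.planted_names)
    # strongest increased hits get the planted names first, then decreased
    order = sorted(range(n_up), key=lambda i: -abs(xs[i])) + sorted(
        range(n_up, n_up + n_down), key=lambda i: -abs(xs[i])
    )
    for idx, slot in enumerate(order[: len(planted)]):
        names[slot] = planted[idx]
    k = 1
    for i in range(n):
        if not names[i]:
            names[i] = f"gene_{k}"
            k += 1

    perm = rng.permutation(n)
    records = [
        VolcanoRecord(names[i], float(xs[i]), float(ys[i])) for i in perm
    ]
    shuffled_truth = [truth[i] for i in perm]
    data = VolcanoData(
        records,
        x_label="log2_fold_change",
        y_label="minus_log10_p",
        name_label="gene",
        source_descriptor=f"synthetic(seed={spec.seed})",
    )
    return data, shuffled_truth


def to_table_frame(data: VolcanoData) -> pd.DataFrame:
    """The generator's output as the 3-column table a screen would export."""
    return pd.DataFrame(
        {
            "gene": [r.name for r in data.records],
            "log2_fold_change": [r.x for r in data.records],
            "minus_log10_p": [r.y for r in data.records],
        }
    )


def write_fixture(
    data: VolcanoData,
    fmt: str,
    path,
    sheet: str = "data",
) -> Path:
    """Write a generated table as a CSV or XLSX fixture file.

    The file reads back through the IO layer with zero dropped rows and
    identical values (floats are written with full repr precision).
    """
    if not data.records:
        raise ValueError("cannot write an empty fixture")
    path = Path(path)
    frame = to_table_frame(data)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format=None)
    elif fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            frame.to_excel(xw, sheet_name=sheet, index=False)
    else:
        raise ValueError(f"unsupported fixture format {fmt!r}: csv or xlsx")
    return path
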