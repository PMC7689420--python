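import matplotlib

matplotlib.use("Agg")

import random

import pytest

from volcanokit.state import (
    CanSection,
    ColorSection,
    DataSection,
    LabelSection,
    LayoutSection,
    SharedState,
    VisSection,
)

# The two published example share-URLs (proteomics screen hosted on zenodo);
# used as exact decode vectors throughout the suite.
SHARE_URL_A = (
    "https://huygens.science.uva.nl:/VolcaNoseR/?data=5;;Difference_CSB_GFP;"
    "p_value_CSB_GFP;Gene_names&vis=4;0.8;1.5;2;increased&can=10;;;"
    "&layout=;;;;;log2;minus_log10;X;600;800"
    "&label=TRUE;GFP-CSB-WTvsGFP-NLS;TRUE;Enrichment(log2);"
    "Significance(-log10p-value);;24;24;18;6;"
    "&url=https://zenodo.org/record/3713174/files/"
    "CSV_1-GFP-CSB-WT_vs_GFP-NLS.csv"
)
SHARE_URL_B = (
    "https://huygens.science.uva.nl/VolcaNoseR/?data=5;;Difference_CSB_GFP;"
    "p_value_CSB_GFP;Gene_names&vis=4;0.8;-3,3;3;significant;manh&can=20;;;"
    "&layout=;;;;;X;600;800&color=3;none"
    "&label=TRUE;GFP-CSB-WT%20vs%20GFP-NLS;TRUE;Enrichment%20(log2);"
    "Significance%20(-log10%20p-value);;24;24;18;6;"
    "&url=https://zenodo.org/record/3713174/files/"
    "CSV_1-GFP-CSB-WT_vs_GFP-NLS.csv"
)


@pytest.fixture
def share_url_a():
    return SHARE_URL_A


@pytest.fixture
def share_url_b():
    return SHARE_URL_B


_TEXT_ALPHABET = (
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    " _-().,/"
)
_OPAQUE_ALPHABET = (
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-"
)


def random_state(rng: random.Random) -> SharedState:
    """A random but constructible SharedState for round-trip properties."""

    def text(max_len=12):
        return "".join(
            rng.choice(_TEXT_ALPHABET) for _ in range(rng.randrange(max_len))
        )

    def opaque(max_len=6):
        return "".join(
            rng.choice(_OPAQUE_ALPHABET) for _ in range(rng.randrange(max_len))
        )

    def num(lo, hi):
        return round(rng.uniform(lo, hi), 3)

    if rng.random() < 0.5:
        s = num(0.1, 5)
        fc = (-s, s)
    else:
        lo = num(-6, -0.1)
        hi = num(0.1, 6)
        fc = (lo, hi)
    with_scales = rng.random() < 0.5
    return SharedState(
        data_section=DataSection(
            source_mode=opaque(), sheet=text(), x_col=text(), y_col=text(),
            name_col=text(),
        ),
        vis_section=VisSection(
            dot_size=num(0.5, 10),
            alpha=num(0, 1),
            fc_threshold=fc,
            sig_threshold=num(0, 10),
            direction=rng.choice(["increased", "decreased", "significant"]),
            criterion=rng.choice([None, "manh", "eucl", "fc", "sig"]),
        ),
        can_section=CanSection(
            n_top=rng.randrange(0, 50),
            manual_names=[text(8) or "g" for _ in range(rng.randrange(0, 4))],
            opaque_tail=[opaque() for _ in range(rng.randrange(0, 4))],
        ),
        layout_section=LayoutSection(
            opaque_head=[opaque() for _ in range(5)],
            x_scale_tag="log2" if with_scales else None,
            y_scale_tag="minus_log10" if with_scales else None,
            rotation_tag=rng.choice(["X", "Y"]),
            height=rng.randrange(200, 1200),
            width=rng.randrange(200, 1200),
        ),
        color_section=(
            ColorSection(scheme_code=rng.randrange(1, 5), custom_spec=opaque())
            if rng.random() < 0.5
            else None
        ),
        label_section=LabelSection(
            show_title=rng.random() < 0.5,
            title=text(20),
            show_axis_labels=rng.random() < 0.5,
            x_label=text(20),
            y_label=text(20),
            opaque_mid=opaque(),
            font_sizes=tuple(rng.randrange(4, 40) for _ in range(4)),
            opaque_tail=[opaque() for _ in range(rng.randrange(0, 3))],
        ),
        url_section=(
            "https://example.org/records/1/files/screen.csv"
            if rng.random() < 0.5
            else None
        ),
        base_url="https://volcano.example/plot",
    )
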