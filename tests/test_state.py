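"""Share-URL codec: the two published URLs are exact decode vectors."""

import random

import pytest

from volcanokit.errors import NoDataSourceError, ShareUrlError
from volcanokit.state import (
    SharedState,
    decode_state,
    encode_state,
    normalize_criterion,
    state_to_run_config,
)

from conftest import random_state


class TestDecodeVectors:
    def test_first_published_url(self, share_url_a):
        s = decode_state(share_url_a)
        assert s.data_section.x_col == "Difference_CSB_GFP"
        assert s.data_section.y_col == "p_value_CSB_GFP"
        assert s.data_section.name_col == "Gene_names"
        assert s.vis_section.fc_threshold == (-1.5, 1.5)
        assert s.vis_section.sig_threshold == 2.0
        assert s.vis_section.direction == "increased"
        assert s.vis_section.criterion is None
        assert s.can_section.n_top == 10
        assert s.layout_section.x_scale_tag == "log2"
        assert s.layout_section.y_scale_tag == "minus_log10"
        assert (s.layout_section.height, s.layout_section.width) == (600, 800)
        assert s.color_section is None
        assert s.url_section == (
            "https://zenodo.org/record/3713174/files/"
            "CSV_1-GFP-CSB-WT_vs_GFP-NLS.csv"
        )

    def test_second_published_url(self, share_url_b):
        s = decode_state(share_url_b)
        assert s.vis_section.fc_threshold == (-3.0, 3.0)
        assert s.vis_section.sig_threshold == 3.0
        assert s.vis_section.direction == "significant"
        assert s.vis_section.criterion == "manh"
        assert s.can_section.n_top == 20
        assert s.color_section is not None
        assert s.color_section.scheme_code == 3
        assert s.label_section.title == "GFP-CSB-WT vs GFP-NLS"
        assert s.label_section.x_label == "Enrichment (log2)"
        assert s.label_section.font_sizes == (24, 24, 18, 6)

    def test_vis_only_url_defaults_everything_else(self):
        s = decode_state("https://x.example/app?vis=4;0.8;1;1;increased")
        assert s.vis_section.fc_threshold == (-1.0, 1.0)
        assert s.can_section.n_top == 10
        assert s.layout_section.height == 600
        assert s.color_section is None
        assert s.url_section is None

    def test_not_a_share_url(self):
        with pytest.raises(ShareUrlError, match="not a share URL"):
            decode_state("https://x.example/app?foo=bar")

    def test_malformed_threshold_names_the_field(self):
        with pytest.raises(ShareUrlError, match="vis.*fc_threshold"):
            decode_state("https://x.example/app?vis=4;0.8;abc;2;increased")


class TestRoundTrip:
    def test_published_urls_semantic_round_trip(self, share_url_a, share_url_b):
        for url in (share_url_a, share_url_b):
            once = decode_state(url)
            again = decode_state(encode_state(once))
            assert again == once

    def test_thousand_random_states_round_trip(self):
        rng = random.Random(20200325)
        for _ in range(1000):
            state = random_state(rng)
            assert decode_state(encode_state(state)) == state

    def test_opaque_fields_preserved_byte_identically(self, share_url_a,
                                                      share_url_b):
        # fields with unpinned semantics (mode code, layout head/rotation,
        # section tails) must survive decode -> encode without change
        for url in (share_url_a, share_url_b):
            encoded = encode_state(decode_state(url))
            assert "data=5;;" in encoded
            assert ";X;600;800" in encoded
            assert "can=" + url.split("can=")[1].split("&")[0] in encoded
            label_orig = url.split("label=")[1].split("&")[0]
            label_new = encoded.split("label=")[1].split("&")[0]
            # positions 5 (mid) and 10+ (tail) are opaque
            assert label_new.split(";")[5] == label_orig.split(";")[5]
            assert label_new.split(";")[10:] == label_orig.split(";")[10:]

    def test_opaque_tail_bytes_survive(self):
        url = ("https://x.example/app?can=7;;keep_me;and.me"
               "&layout=h1;h2;h3;h4;h5;X;300;400")
        encoded = encode_state(decode_state(url))
        assert "can=7;;keep_me;and.me" in encoded
        assert "layout=h1;h2;h3;h4;h5;X;300;400" in encoded

    def test_section_order_independence(self, share_url_b):
        base, query = share_url_b.split("?", 1)
        sections = query.split("&")
        reference = decode_state(share_url_b)
        rng = random.Random(4)
        for _ in range(10):
            perm = sections[:]
            rng.shuffle(perm)
            assert decode_state(base + "?" + "&".join(perm)) == reference

    def test_symmetric_threshold_emitted_as_scalar(self):
        state = SharedState()
        state.vis_section.fc_threshold = (-2.5, 2.5)
        assert ";2.5;" in encode_state(state)

    def test_default_state_encoding(self):
        url = encode_state(SharedState())
        assert "can=10" in url
        assert "increased" in url

    def test_space_percent_encoded(self):
        state = SharedState()
        state.label_section.title = "A B"
        assert "A%20B" in encode_state(state)

    def test_empty_base_url_rejected(self):
        with pytest.raises(ShareUrlError):
            encode_state(SharedState(), base_url="")


class TestRunConfig:
    def test_first_url_maps_to_default_manhattan_ranking(self, share_url_a):
        cfg = state_to_run_config(decode_state(share_url_a))
        assert cfg.ranking.criterion == "manhattan"
        assert cfg.ranking.direction == "increased"
        assert cfg.ranking.n_top == 10
        assert cfg.thresholds.fc_low == -1.5
        assert cfg.thresholds.sig == 2.0
        assert cfg.source == ("url", decode_state(share_url_a).url_section)

    def test_second_url_ranking_and_palette_fallback(self, share_url_b):
        with pytest.warns(UserWarning, match="scheme"):
            cfg = state_to_run_config(decode_state(share_url_b))
        assert cfg.ranking.criterion == "manhattan"
        assert cfg.ranking.direction == "significant"
        assert cfg.ranking.n_top == 20
        assert cfg.style.colors["unchanged"] == "grey"

    def test_unknown_criterion_token_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="eucl-variant-unknown"):
            assert normalize_criterion("eucl-variant-unknown") == "manhattan"

    @pytest.mark.parametrize(
        "token,expected",
        [
            (None, "manhattan"),
            ("manh", "manhattan"),
            ("eucl", "euclidean"),
            ("fc", "fold_change"),
            ("sig", "significance"),
        ],
    )
    def test_token_normalization(self, token, expected):
        assert normalize_criterion(token) == expected

    def test_state_without_data_source_rejected(self):
        state = SharedState()
        state.url_section = None
        with pytest.raises(NoDataSourceError):
            state_to_run_config(state)
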