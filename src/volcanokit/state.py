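"""Share-URL state codec.

Every plot setting — data source, visual style, candidate selection,
layout, colors, labels, and the remote data location — can be serialized
into a single URL so that the plot plus its underlying data can be
reconstructed from one string.  The query string is a mini-format of
semicolon-separated positional fields grouped into '&'-separated sections:

    <base>?data=<mode>;<sheet>;<xcol>;<ycol>;<namecol>
          &vis=<dot_size>;<alpha>;<fc>;<sig>;<direction>[;<criterion>]
          &can=<n_top>;<names>;;
          &layout=<5 opaque>[;<xscale>;<yscale>];<rot>;<height>;<width>
          &color=<scheme>;<custom>
          &label=<bool>;<title>;<bool>;<xlab>;<ylab>;<opaque>;<s1>;<s2>;<s3>;<s4>;
          &url=<remote data URL>

See docs/share-url-grammar.md for the field-by-field reference.  The
fold-change threshold field is a scalar s (meaning the symmetric pair
(-s, +s)) or an explicit "low,high" pair.  Text fields are
percent-encoded.  Positional fields whose semantics are not pinned down
(the data-section mode code, the five layout head fields, the rotation
token, section tails) are carried as opaque strings and re-emitted
byte-identically, so a decode/encode cycle never corrupts a URL produced
elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional
from urllib.parse import quote, unquote

from .errors import NoDataSourceError, ShareUrlError
from .hits import DIRECTIONS, RankingSpec, Thresholds
from .plotting import COLOR_SCHEMES, PlotStyle

SECTION_ORDER = ("data", "vis", "can", "layout", "color", "label", "url")

_QUOTE_SAFE = "()!*'-._~"


def _fmt_num(v: float) -> str:
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def _parse_num(token: str, section: str, name: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ShareUrlError(
            f"malformed {section} section: field {name!r} is not numeric "
            f"(got {token!r})"
        ) from None


def _fmt_bool(v: bool) -> str:
    return "TRUE" if v else "FALSE"


@dataclass
class DataSection:
    """Column mapping plus an opaque source-mode code (observed: "5")."""

    source_mode: str = "5"
    sheet: str = ""
    x_col: str = ""
    y_col: str = ""
    name_col: str = ""


@dataclass
class VisSection:
    dot_size: float = 4.0
    alpha: float = 0.8
    fc_threshold: tuple[float, float] = (-1.5, 1.5)
    sig_threshold: float = 2.0
    direction: str = "increased"
    criterion: Optional[str] = None  # raw token; absent in the 5-field form


@dataclass
class CanSection:
    n_top: int = 10
    manual_names: list[str] = field(default_factory=list)
    opaque_tail: list[str] = field(default_factory=lambda: ["", ""])


@dataclass
class LayoutSection:
    opaque_head: list[str] = field(default_factory=lambda: [""] * 5)
    x_scale_tag: Optional[str] = None  # e.g. "log2" (10-field variant only)
    y_scale_tag: Optional[str] = None  # e.g. "minus_log10"
    rotation_tag: str = "X"
    height: float = 600.0
    width: float = 800.0


@dataclass
class ColorSection:
    scheme_code: int = 1
    custom_spec: str = "none"


@dataclass
class LabelSection:
    show_title: bool = True
    title: str = ""
    show_axis_labels: bool = True
    x_label: str = ""
    y_label: str = ""
    opaque_mid: str = ""
    font_sizes: tuple[int, int, int, int] = (24, 24, 18, 6)
    opaque_tail: list[str] = field(default_factory=lambda: [""])


@dataclass
class SharedState:
    """The complete settings bundle a share URL round-trips."""

    data_section: DataSection = field(default_factory=DataSection)
    vis_section: VisSection = field(default_factory=VisSection)
    can_section: CanSection = field(default_factory=CanSection)
    layout_section: LayoutSection = field(default_factory=LayoutSection)
    color_section: Optional[ColorSection] = None
    label_section: LabelSection = field(default_factory=LabelSection)
    url_section: Optional[str] = None
    base_url: str = "https://volcano.example/plot"


# --------------------------------------------------------------------------
# decoding

def _split_sections(query: str) -> dict[str, str]:
    known = set(SECTION_ORDER)
    segments = query.split("&")
    sections: dict[str, str] = {}
    i = 0
    while i < len(segments):
        seg = segments[i]
        if "=" not in seg:
            i += 1
            continue
        key, value = seg.split("=", 1)
        if key == "url":
            # a data URL may itself contain '&'; swallow following segments
            # unless they start a recognized section
            j = i + 1
            while j < len(segments):
                nxt = segments[j]
                k = nxt.split("=", 1)[0] if "=" in nxt else None
                if k in known:
                    break
                value += "&" + nxt
                j += 1
            sections["url"] = value
            i = j
            continue
        if key in known:
            sections[key] = value
        i += 1
    return sections


def _decode_data(payload: str) -> DataSection:
    f = (payload.split(";") + [""] * 5)[:5]
    return DataSection(
        source_mode=f[0],
        sheet=unquote(f[1]),
        x_col=unquote(f[2]),
        y_col=unquote(f[3]),
        name_col=unquote(f[4]),
    )


def _decode_fc(token: str) -> tuple[float, float]:
    if "," in token:
        lo, hi = token.split(",", 1)
        return (
            _parse_num(lo, "vis", "fc_threshold.low"),
            _parse_num(hi, "vis", "fc_threshold.high"),
        )
    s = _parse_num(token, "vis", "fc_threshold")
    return (-abs(s), abs(s))


def _decode_vis(payload: str) -> VisSection:
    f = payload.split(";")
    if len(f) < 5:
        f = f + [""] * (5 - len(f))
    defaults = VisSection()
    return VisSection(
        dot_size=_parse_num(f[0], "vis", "dot_size") if f[0] else defaults.dot_size,
        alpha=_parse_num(f[1], "vis", "alpha") if f[1] else defaults.alpha,
        fc_threshold=_decode_fc(f[2]) if f[2] else defaults.fc_threshold,
        sig_threshold=(
            _parse_num(f[3], "vis", "sig_threshold") if f[3] else defaults.sig_threshold
        ),
        direction=f[4] or defaults.direction,
        criterion=f[5] if len(f) > 5 else None,
    )


def _decode_can(payload: str) -> CanSection:
    f = payload.split(";")
    n_top = int(_parse_num(f[0], "can", "n_top")) if f and f[0] else 10
    names = [unquote(n) for n in f[1].split(",") if n] if len(f) > 1 else []
    return CanSection(n_top=n_top, manual_names=names, opaque_tail=f[2:])


def _decode_layout(payload: str) -> LayoutSection:
    f = payload.split(";")
    if len(f) < 8:
        f = [""] * (8 - len(f)) + f  # lenient: pad the opaque head
    if len(f) >= 10:
        head, xs, ys, rot, h, w = f[:5], f[5], f[6], f[7], f[8], f[9]
        x_scale, y_scale = xs, ys
    else:
        head, rot, h, w = f[:5], f[5], f[6], f[7]
        x_scale = y_scale = None
    defaults = LayoutSection()
    return LayoutSection(
        opaque_head=head,
        x_scale_tag=x_scale,
        y_scale_tag=y_scale,
        rotation_tag=rot,
        height=_parse_num(h, "layout", "height") if h else defaults.height,
        width=_parse_num(w, "layout", "width") if w else defaults.width,
    )


def _decode_color(payload: str) -> ColorSection:
    f = (payload.split(";") + ["", ""])[:2]
    code = int(_parse_num(f[0], "color", "scheme_code")) if f[0] else 1
    return ColorSection(scheme_code=code, custom_spec=f[1])


def _decode_label(payload: str) -> LabelSection:
    f = payload.split(";")
    if len(f) < 10:
        f = f + [""] * (10 - len(f))
    defaults = LabelSection()
    sizes = []
    for i, tok in enumerate(f[6:10]):
        sizes.append(
            int(_parse_num(tok, "label", f"font_size_{i + 1}"))
            if tok
            else defaults.font_sizes[i]
        )
    return LabelSection(
        show_title=f[0].upper() != "FALSE",
        title=unquote(f[1]),
        show_axis_labels=f[2].upper() != "FALSE",
        x_label=unquote(f[3]),
        y_label=unquote(f[4]),
        opaque_mid=f[5],
        font_sizes=tuple(sizes),
        opaque_tail=f[10:],
    )


def decode_state(url: str) -> SharedState:
    """Reconstruct a :class:`SharedState` from a share URL.

    Missing optional sections yield defaults; both observed arity
    variants of the vis (5/6 fields) and layout (8/10 fields) sections
    are accepted; '&'-section order does not matter.
    """
    if "?" in url:
        base, query = url.split("?", 1)
    else:
        base, query = "", url
    sections = _split_sections(query)
    if not sections:
        raise ShareUrlError(
            "not a share URL: no recognized section among "
            + "/".join(SECTION_ORDER)
        )
    state = SharedState(base_url=base or SharedState.base_url)
    if "data" in sections:
        state.data_section = _decode_data(sections["data"])
    if "vis" in sections:
        state.vis_section = _decode_vis(sections["vis"])
    if "can" in sections:
        state.can_section = _decode_can(sections["can"])
    if "layout" in sections:
        state.layout_section = _decode_layout(sections["layout"])
    if "color" in sections:
        state.color_section = _decode_color(sections["color"])
    if "label" in sections:
        state.label_section = _decode_label(sections["label"])
    if "url" in sections:
        state.url_section = sections["url"]
    return state


# --------------------------------------------------------------------------
# encoding

def _q(text: str) -> str:
    return quote(text, safe=_QUOTE_SAFE)


def _encode_fc(fc: tuple[float, float]) -> str:
    lo, hi = fc
    if math.isclose(lo, -hi):
        return _fmt_num(hi)
    return f"{_fmt_num(lo)},{_fmt_num(hi)}"


def encode_state(state: SharedState, base_url: Optional[str] = None) -> str:
    """Serialize a state back into a share URL.

    Sections are emitted in the fixed order data, vis, can, layout,
    color, label, url; symmetric fold-change thresholds as a scalar;
    opaque fields verbatim.  The layout section is emitted with the
    axis-scale tags (10 fields) exactly when the state carries them,
    so either observed variant survives a decode/encode cycle.
    """
    base = base_url if base_url is not None else state.base_url
    if not base:
        raise ShareUrlError("base_url must be non-empty")
    d, v, c, lay, lab = (
        state.data_section,
        state.vis_section,
        state.can_section,
        state.layout_section,
        state.label_section,
    )
    parts: list[str] = []
    parts.append(
        "data=" + ";".join(
            [d.source_mode, _q(d.sheet), _q(d.x_col), _q(d.y_col), _q(d.name_col)]
        )
    )
    vis_fields = [
        _fmt_num(v.dot_size),
        _fmt_num(v.alpha),
        _encode_fc(v.fc_threshold),
        _fmt_num(v.sig_threshold),
        v.direction,
    ]
    if v.criterion is not None:
        vis_fields.append(v.criterion)
    parts.append("vis=" + ";".join(vis_fields))
    parts.append(
        "can=" + ";".join(
            [str(c.n_top), ",".join(_q(n) for n in c.manual_names)] + c.opaque_tail
        )
    )
    lay_fields = list(lay.opaque_head)
    if lay.x_scale_tag is not None or lay.y_scale_tag is not None:
        lay_fields += [lay.x_scale_tag or "", lay.y_scale_tag or ""]
    lay_fields += [lay.rotation_tag, _fmt_num(lay.height), _fmt_num(lay.width)]
    parts.append("layout=" + ";".join(lay_fields))
    if state.color_section is not None:
        col = state.color_section
        parts.append(f"color={col.scheme_code};{col.custom_spec}")
    lab_fields = [
        _fmt_bool(lab.show_title),
        _q(lab.title),
        _fmt_bool(lab.show_axis_labels),
        _q(lab.x_label),
        _q(lab.y_label),
        lab.opaque_mid,
        *[str(s) for s in lab.font_sizes],
        *lab.opaque_tail,
    ]
    parts.append("label=" + ";".join(lab_fields))
    if state.url_section is not None:
        parts.append("url=" + state.url_section)
    return base + "?" + "&".join(parts)


# --------------------------------------------------------------------------
# bridging to the pipeline

_CRITERION_TOKENS = {
    "manh": "manhattan",
    "manhattan": "manhattan",
    "eucl": "euclidean",
    "euclidean": "euclidean",
    "fc": "fold_change",
    "fold_change": "fold_change",
    "foldchange": "fold_change",
    "sig": "significance",
    "significance": "significance",
}


def normalize_criterion(token: Optional[str]) -> str:
    """Map a URL criterion token to a canonical criterion name.

    Unknown tokens fall back to the default (manhattan) with a warning.
    """
    if token is None or token == "":
        return "manhattan"
    canon = _CRITERION_TOKENS.get(token.strip().lower())
    if canon is None:
        warnings.warn(
            f"unknown ranking criterion token {token!r}; using manhattan",
            stacklevel=2,
        )
        return "manhattan"
    return canon


@dataclass
class RunConfig:
    """Everything the pipeline needs, extracted from a SharedState."""

    source: tuple[str, str]  # ("url", <url>) — the only resolvable mode
    sheet: Optional[str]
    x_col: str
    y_col: str
    name_col: Optional[str]
    thresholds: Thresholds
    ranking: RankingSpec
    style: PlotStyle
    manual_names: list[str]


def state_to_run_config(state: SharedState) -> RunConfig:
    """Deterministically map a decoded state onto pipeline inputs."""
    v, lay, lab = state.vis_section, state.layout_section, state.label_section
    if state.url_section:
        source = ("url", state.url_section)
    else:
        raise NoDataSourceError(
            "no data source: the state has no url section and the "
            f"source-mode code {state.data_section.source_mode!r} cannot be "
            "resolved outside the original app"
        )
    direction = v.direction
    if direction not in DIRECTIONS:
        warnings.warn(
            f"unknown direction token {direction!r}; using 'increased'",
            stacklevel=2,
        )
        direction = "increased"
    thresholds = Thresholds(v.fc_threshold[0], v.fc_threshold[1], v.sig_threshold)
    ranking = RankingSpec(
        criterion=normalize_criterion(v.criterion),
        direction=direction,
        n_top=state.can_section.n_top,
    )
    if state.color_section is None:
        colors = dict(COLOR_SCHEMES[1])
    elif state.color_section.scheme_code in COLOR_SCHEMES:
        colors = dict(COLOR_SCHEMES[state.color_section.scheme_code])
    else:
        warnings.warn(
            f"color scheme code {state.color_section.scheme_code} has no "
            "documented palette; using the default grey/red/blue",
            stacklevel=2,
        )
        colors = dict(COLOR_SCHEMES[1])
    style = PlotStyle(
        dot_size=v.dot_size,
        alpha=v.alpha,
        colors=colors,
        rotated=lay.rotation_tag.strip().upper() == "Y",
        title=lab.title if lab.show_title else "",
        x_label=lab.x_label if lab.show_axis_labels else "",
        y_label=lab.y_label if lab.show_axis_labels else "",
        font_sizes=lab.font_sizes,
        width=int(lay.width),
        height=int(lay.height),
    )
    return RunConfig(
        source=source,
        sheet=state.data_section.sheet or None,
        x_col=state.data_section.x_col,
        y_col=state.data_section.y_col,
        name_col=state.data_section.name_col or None,
        thresholds=thresholds,
        ranking=ranking,
        style=style,
        manual_names=list(state.can_section.manual_names),
    )
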