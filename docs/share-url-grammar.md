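# Share-URL grammar reference

A share-URL carries every plot setting plus the remote data location in
its query string, so one string reconstructs the plot and its data.
Sections are separated by `&`, fields within a section by `;`, and text
fields are percent-encoded (space → `%20`). Section order does not matter
on decode; the encoder emits the fixed order
`data, vis, can, layout, color, label, url`.

```
<base>?data=<mode>;<sheet>;<xcol>;<ycol>;<namecol>
      &vis=<dot_size>;<alpha>;<fc>;<sig>;<direction>[;<criterion>]
      &can=<n_top>;<name>,<name>,...;<opaque>;<opaque>
      &layout=<o1>;<o2>;<o3>;<o4>;<o5>[;<xscale>;<yscale>];<rot>;<height>;<width>
      &color=<scheme_code>;<custom_spec>          (optional section)
      &label=<bool>;<title>;<bool>;<xlab>;<ylab>;<opaque>;<s1>;<s2>;<s3>;<s4>[;<opaque>...]
      &url=<remote CSV URL>                       (optional section)
```

## Field semantics

| section | field | meaning | default |
|---|---|---|---|
| data | mode | source-mode code; **opaque** (observed: `5`) | `5` |
| data | sheet | workbook sheet name; empty = first sheet | empty |
| data | xcol / ycol / namecol | effect-size, significance and name columns | empty |
| vis | dot_size | marker size | `4` |
| vis | alpha | marker opacity in [0, 1] | `0.8` |
| vis | fc | fold-change cutoff: scalar `s` ≡ pair `(-s, +s)`, or explicit `low,high` | `1.5` |
| vis | sig | significance cutoff (−log10 p) | `2` |
| vis | direction | `increased` / `decreased` / `significant` | `increased` |
| vis | criterion | ranking token: `manh`, `eucl`, `fc`, `sig` (and long forms); field may be absent entirely (5-field variant) | absent → manhattan |
| can | n_top | number of top hits annotated | `10` |
| can | names | comma-separated manually selected names | empty |
| can | tail | **opaque** (observed: two empty fields) | `;;` |
| layout | o1..o5 | **opaque** head fields | empty |
| layout | xscale/yscale | axis-scale tags, present only in the 10-field variant (observed `log2;minus_log10`) | absent |
| layout | rot | rotation token; **opaque** (observed `X`; `Y` is read as rotated) | `X` |
| layout | height/width | canvas size in px (first value taken as height) | `600;800` |
| color | scheme_code | palette number: 1 = grey/red/blue, 2 = grey/blue/green; other codes round-trip but fall back to palette 1 with a warning | section absent → 1 |
| color | custom_spec | custom-palette token; **opaque** (observed `none`) | `none` |
| label | bool₁ / title | show title flag; title text | `TRUE`; empty |
| label | bool₂ / xlab / ylab | show axis-label flag; axis titles | `TRUE`; empty |
| label | opaque | **opaque** mid field | empty |
| label | s1..s4 | font sizes: title, axis title, tick label, point label (pt) | `24;24;18;6` |
| label | tail | **opaque** trailing fields | `;` |
| url | — | remote data CSV, stored verbatim (never percent-encoded) | absent |

Fields marked **opaque** have no pinned-down meaning; the codec carries
their bytes through a decode → encode cycle unchanged rather than
guessing semantics.

## Arity variants

Both observed variants decode:

* `vis` with 5 fields (no criterion token) or 6 fields;
* `layout` with 8 fields or 10 fields (the two extra fields being the
  axis-scale tags). The encoder emits the 10-field form exactly when the
  state carries scale tags, so either variant survives a round trip.

## Guarantees

* `decode(encode(state)) == state` for every constructible state.
* Opaque positional fields are byte-identical after decode → encode.
* Permuting `&`-sections does not change the decoded state.
* A symmetric threshold pair `(-s, s)` is emitted as the scalar `s`.
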