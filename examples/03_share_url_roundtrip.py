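"""Decode a published share-URL and re-encode it without losing anything.

A share-URL stores every plot setting plus the remote data location, so
the string alone reconstructs the plot.  This example decodes one of the
published proteomics-screen URLs, shows the settings it carries, and
demonstrates the semantic round-trip decode(encode(state)) == state.
"""

import warnings

from volcanokit import decode_state, encode_state, state_to_run_config

URL = (
    "https://huygens.science.uva.nl:/VolcaNoseR/?data=5;;Difference_CSB_GFP;"
    "p_value_CSB_GFP;Gene_names&vis=4;0.8;1.5;2;increased&can=10;;;"
    "&layout=;;;;;log2;minus_log10;X;600;800"
    "&label=TRUE;GFP-CSB-WTvsGFP-NLS;TRUE;Enrichment(log2);"
    "Significance(-log10p-value);;24;24;18;6;"
    "&url=https://zenodo.org/record/3713174/files/"
    "CSV_1-GFP-CSB-WT_vs_GFP-NLS.csv"
)

state = decode_state(URL)
print("x column:      ", state.data_section.x_col)
print("fc thresholds: ", state.vis_section.fc_threshold)
print("sig threshold: ", state.vis_section.sig_threshold)
print("direction:     ", state.vis_section.direction)
print("n_top:         ", state.can_section.n_top)
print("data source:   ", state.url_section)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cfg = state_to_run_config(state)
print("ranking:       ", cfg.ranking)

again = decode_state(encode_state(state))
print("round-trip ok: ", again == state)
# True: the regenerated URL decodes to exactly the same settings bundle,
# including fields whose semantics are carried opaquely.
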