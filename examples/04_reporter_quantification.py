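"""Dual-reporter quantification of -1 PRF.

Dual-luciferase: firefly luciferase sits downstream of the slippery
sequence, Renilla upstream; each replicate is normalized as
firefly/renilla and the readout is mean(test)/mean(control). A readout
below 1 means the test condition loses reading-frame maintenance
(more frameshifting).

Dual-GST: the -1 frameshift product runs as a dual-tagged band; percent
PRF is 100 * dual / (dual + single).
"""
from prfscan import (
    GstBands,
    LuciferasePair,
    compare_two_groups,
    gst_prf_percent,
    luciferase_readout,
)

ko = [(48, 100), (52, 104), (50, 98)]   # firefly, renilla per replicate
wt = [(98, 100), (104, 102), (101, 99)]
data = [
    LuciferasePair(firefly=f, renilla=r, condition="ko", replicate=i)
    for i, (f, r) in enumerate(ko)
] + [
    LuciferasePair(firefly=f, renilla=r, condition="wt", replicate=i)
    for i, (f, r) in enumerate(wt)
]

readout = luciferase_readout(data, "ko", "wt")
print(f"Relative firefly activity (ko / wt): {readout:.3f}")

t, p = compare_two_groups(
    [f / r for f, r in ko], [f / r for f, r in wt]
)
print(f"Two-sample t test on normalized ratios: t = {t:.2f}, p = {p:.2e}")

bands = GstBands(dual_intensity=1.0, single_intensity=3.0)
print(f"Dual-GST percent -1 PRF: {gst_prf_percent(bands):.1f}%")
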