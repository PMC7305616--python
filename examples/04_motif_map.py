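"""Positional motif map with sliding Fisher tests and CLIP proximity.

Generates two sets of splice-site-anchored sequences — one with A/U-rich
3-mers (AAU/UAA/AUU) planted at rate 0.5 in a window 180-220 nt into the
downstream intron, one pure background — plus synthetic crosslink tags at
the planted positions. Prints where the sliding-window Fisher test finds
significant enrichment and the fraction of events with proximal binding
evidence per set.
"""

import numpy as np

import gradpath as gp

data = gp.synth_sequences(n_events_per_set=200, planted_rate=0.5,
                          planted_window=(180, 220), seed=0)

tracks = gp.motif_frequency(data.enriched, smooth_width=20)
t = tracks["downstream_intron"]
lo, hi = data.truth["planted_window"]
print(f"smoothed motif frequency inside planted window ({lo}-{hi} nt): "
      f"{np.nanmean(t.smoothed[lo:hi]):.3f}")
print(f"smoothed motif frequency elsewhere:                    "
      f"{np.nanmean(t.smoothed[:150]):.3f}")

fisher = gp.window_fisher(data.enriched, data.background, window=20)
sig = fisher["downstream_intron"].query("significant")
print(f"\nsignificant 20-nt windows (two-tailed Fisher p < 0.05): {len(sig)}")
if len(sig):
    print(f"window centers span positions {int(sig['center'].min())}-"
          f"{int(sig['center'].max())} downstream of the 5' splice site")

sets = {"enriched": set(data.enriched.events),
        "background": set(data.background.events)}
frac, pairwise = gp.clip_proximity(data.tags, data.events, sets)
print("\ncrosslink-tag proximity (fraction of events bound within "
      "+/-300 nt or the exon):")
print(frac[["frac_upstream", "frac_exon", "frac_downstream", "frac_any"]]
      .to_string(float_format=lambda v: f"{v:.3f}"))
print(f"enriched vs background Fisher p = "
      f"{pairwise.loc['enriched', 'background']:.3g}")
print("\nSignificant windows concentrating around the planted span, and "
      "binding evidence restricted to the enriched set, are the signatures "
      "a real positional regulator would leave.")
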