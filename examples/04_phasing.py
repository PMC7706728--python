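"""Phase nucleosomal sequences to expose their shared 10-bp TT register.

Builds dyad-centered sequences carrying the same 10-bp TT comb at five
different phase offsets, then re-phases them by k-means clustering and
per-cluster cross-correlation lags.
"""

import numpy as np

from promarch import phase_sequences
from promarch.nucleosome import profile_psd_at_period

rng = np.random.default_rng(8)
template = list("".join(np.array(list("ACGT"))[rng.choice(4, 400, p=[.2, .3, .3, .2])]))
for p in range(3, 396, 10):
    template[p], template[p + 1] = "T", "T"
template = "".join(template)

seqs, planted = [], []
for lag, count in {-4: 6, -2: 7, 0: 10, 2: 7, 4: 6}.items():
    seqs += [template[-lag:] + template[:-lag]] * count
    planted += [lag] * count

res = phase_sequences(seqs, "TT", k=5, max_lag=5, seed=0)
recovered = -res.lags[res.labels]
print(f"{len(seqs)} sequences, 5 planted phase offsets in [-4, +4] bp")
print(f"lag recovery: {100 * np.mean(recovered == planted):.0f}% exact")
print(f"10-bp PSD of summed profile before phasing: "
      f"{profile_psd_at_period(res.unshifted_profile, 10):.3f}")
print(f"10-bp PSD of summed profile after phasing:  "
      f"{profile_psd_at_period(res.summed_profile, 10):.3f}")
# Out-of-phase combs cancel in the raw summed profile; after shifting
# each cluster by its lag the combs align and the 10-bp spectral power
# of the summed occurrence profile rises sharply.
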