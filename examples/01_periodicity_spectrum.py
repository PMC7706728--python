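"""Detect 10-bp WW periodicity in a promoter-like sequence set.

Generates 100 sequences with a planted 10-bp W comb (plus a shuffled
null) and prints the power spectral density at the 10-bp period.
"""

from promarch import get_periodicity
from promarch.simulate import gen_periodic_sequences, mononucleotide_shuffle

seqs, truth = gen_periodic_sequences(n=100, length=350, period=10,
                                     planted_fraction=1.0, jitter=0.1, seed=1)
res = get_periodicity(seqs, "WW")
null = get_periodicity(mononucleotide_shuffle(seqs, seed=2), "WW")

print(f"sequences: {len(seqs)} x 350 bp, {res.n_occurrences} WW occurrences, "
      f"{res.n_pairs} pairs within 300 bp")
print(f"PSD at 10 bp (planted):  {res.psd_at_period(10):.3e}")
print(f"PSD at 10 bp (shuffled): {null.psd_at_period(10):.3e}")
print(f"best period in 5-15 bp:  {max(range(5, 16), key=res.psd_at_period)} bp")
# The planted set scores orders of magnitude above its mononucleotide-
# shuffled null, and the spectrum peaks at the planted 10-bp period —
# the signature of rotational nucleosome-positioning sequence.
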