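"""Encode a protein sequence under all six composition descriptors.

Builds a short peptide and prints each descriptor's dimensionality and
its largest components — the fractions of residues (AAC, GAAC, CTDC),
overlapping dipeptides (DPC, GDPC), or adjacent class changes (CTDT).
"""

from patatinpred import SCHEMES, encode_sequence

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
print(f"sequence ({len(seq)} residues): {seq}\n")

for scheme in SCHEMES:
    vec = encode_sequence(seq, scheme)
    top = vec.sort_values(ascending=False).head(3)
    parts = ", ".join(f"{name}={value:.3f}" for name, value in top.items())
    print(f"{scheme:>5} ({len(vec):>3} dims, sum={vec.sum():.2f}): top {parts}")

print(
    "\nEach value is a frequency: e.g. DPC 'QI' is the count of the QI"
    "\ndipeptide divided by N-1 overlapping windows."
)
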