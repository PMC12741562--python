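"""Feature encodings on a single 41-nt RNA window.

Builds one window, runs a few of the twelve encodings, and prints the
values a practitioner would inspect: the accumulated-frequency vector at a
position (prefix base composition), the composition vectors, and the
matrix shapes the network consumes.
"""

from rnamodnet import encodings as enc

window = "GCCAUUCGAAUCGGAAGCCGUAGGCUAACGGUAUCCGGAUC"[:41]
print(f"window ({len(window)} nt): {window}")

# the worked example sequence: prefix GAUA has 2 A of 4 -> density 0.5
print("\nANF at position 4 of GAUAGGUG:", enc.anf_position("GAUAGGUG", 4))
# -> [0.5 0. 0.25 0.25]: cumulative A/C/G/U frequencies over the prefix

nac = enc.nac(window)
print("\nNAC (whole-window base frequencies):")
for name, v in zip(nac.feature_names, nac.values):
    print(f"  {name}: {v:.3f}")

print("\ndimensionalities for a 41-nt window:")
for scheme in sorted(enc.SCHEMES):
    v = enc.encode(window, scheme)
    v = v.flatten() if isinstance(v, enc.EncodedMatrix) else v
    print(f"  {scheme:8s} {len(v):4d} features")

m = enc.one_hot(window)
print(f"\none-hot matrix for the network: {m.values.shape}, "
      f"row sums all 1: {bool((m.values.sum(axis=1) == 1).all())}")
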