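"""Bench-side planning helpers: section counts and iRT peptide m/z values.

Before cutting, estimate how many sections a tissue will yield; during
LC-MS runs, compare measured retention-standard peptide m/z values against
their theoretical monoisotopic values.
"""

from slicenet import qc

print(f"3.5 mm tissue at 20 um: {qc.section_count(3.5, 20)} sections")
print(f"3.5 mm tissue at 30 um: {qc.section_count(3.5, 30)} sections")

for seq in qc.IRT_PEPTIDES[:4]:
    print(f"{seq:>16}  m/z (z=2) = {qc.irt_mz(seq, 2):.4f}")

# A drift between measured and theoretical m/z beyond instrument tolerance
# indicates a calibration problem before any biological interpretation.
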