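"""Bench-assay readouts: wound closure, calpain degradation, fluorescence.

Inputs are pre-measured areas and band/fluorescence intensities; the
functions apply the assays' normalization arithmetic.
"""

from eoefam import (
    corrected_total_fluorescence,
    protein_remaining_pct,
    total_protein_pct,
    wound_closure_pct,
)

print(f"wound closure, width 0.50 mm -> 0.12 mm at 8 h: {wound_closure_pct(0.50, 0.12):.0f}%")

wt_remaining = [protein_remaining_pct(b, a) for b, a in [(2100, 1550), (1980, 1400)]]
mut_remaining = protein_remaining_pct(2050, 820)
print(f"protein remaining after calpain-14 activation: wild-type {wt_remaining[0]:.0f}%, mutant {mut_remaining:.0f}%")
print(f"mutant total protein vs non-variant mean: {total_protein_pct(mut_remaining, wt_remaining):.0f}%")
print("(below 100% = the variant protein is degraded faster than wild type)")

ctf = corrected_total_fluorescence(integrated_density=58_000, area=1_400, mean_background=12.5)
print(f"corrected total fluorescence: {ctf.value:.0f} (low-signal flag: {ctf.low_signal})")
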