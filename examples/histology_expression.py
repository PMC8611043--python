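"""Histology score aggregation, disease-activity classes and qPCR expression.

A biopsy's eight EoEHSS features (each 0-6 = grade + stage) are summarized as
eosinophilic and structural group ratios; expression uses GAPDH-normalized
delta-CT with the 2^-ddCT fold-change transform.
"""

from eoefam import (
    HSSRecord,
    classify_activity,
    delta_ct,
    fold_change,
    hss_feature_total,
    hss_group_ratio,
)

totals = {
    "EI": hss_feature_total(2, 2),
    "EA": hss_feature_total(1, 1),
    "SL": hss_feature_total(1, 0),
    "SEA": hss_feature_total(2, 1),
    "BZH": hss_feature_total(3, 2),
    "DIS": hss_feature_total(3, 3),
    "DEC": hss_feature_total(1, 1),
    "LPF": None,  # no lamina propria in this biopsy: feature not evaluable
}
biopsy = HSSRecord("patient_1", totals, peak_eos=55)
print(f"eosinophilic group ratio: {hss_group_ratio(biopsy, 'eosinophilic'):.3f}")
print(f"structural group ratio:   {hss_group_ratio(biopsy, 'structural'):.3f} (LPF excluded)")
print(f"activity class at 55 eos/hpf: {classify_activity(55, has_eoe_history=True)}")

# TSLP expression in two groups of biopsies (CT cycles; lower dCT = higher expression)
familial = [delta_ct(goi, gapdh) for goi, gapdh in [(24.1, 18.0), (23.8, 18.4), (24.5, 18.2)]]
nonfamilial = [delta_ct(goi, gapdh) for goi, gapdh in [(25.2, 18.1), (25.0, 18.3), (25.6, 18.5)]]
rejected = delta_ct(24.0, 31.0)
print(f"sample with GAPDH CT 31 rejected by the <30 gate: {rejected is None}")
fc = fold_change(familial, nonfamilial)
print(f"fold change familial vs non-familial: {fc:.2f} (>1 means higher in familial)")
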