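"""Bench-assay calculators: comparative-Ct expression fold change,
ChIP-qPCR fold enrichment, densitometry normalization and tumor volume."""

from regnomics.assays import (
    chip_fold_enrichment,
    ddct_fold_change,
    densitometry_ratio,
)
from regnomics.synergy import tumor_volume

# qPCR: target amplifies 1.5 cycles earlier after treatment, actin stable
fold = ddct_fold_change(ct_target_treated=25.0, ct_ref_treated=18.0,
                        ct_target_ctrl=26.5, ct_ref_ctrl=18.0)
print(f"ddCt fold change: {fold:.3f}  (2^1.5; >1 means induction)")

# ChIP-qPCR: specific antibody 2 cycles earlier than IgG, inputs equal
enr = chip_fold_enrichment(ct_ab=22.0, ct_igg=24.0,
                           ct_input_ab=18.0, ct_input_igg=18.0)
print(f"ChIP fold enrichment over IgG: {enr:.1f}  (4 = strong binding)")

# immunoblot band at half the control's actin-normalized intensity
ratio = densitometry_ratio(band_intensity=2.5, actin_intensity=5.0,
                           control_ratio=1.0)
print(f"densitometry relative intensity: {ratio:.2f}")

# caliper measurement in mm -> mm^3
vol = tumor_volume(8.0, 6.0, 5.0)
print(f"tumor volume (8x6x5 mm): {vol:.0f} mm^3  (length x width x height / 2)")
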