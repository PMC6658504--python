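"""Small assay calculators: comparative-Ct (delta-delta-Ct) relative
expression, ChIP-qPCR fold enrichment versus IgG relative to input, and
densitometry normalization against actin."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CtMeasurement",
    "ddct_fold_change",
    "chip_fold_enrichment",
    "densitometry_ratio",
]


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR threshold-cycle reading."""

    target: str
    condition: str
    ct: float
    antibody: str = "none"  # specific | IgG | input | none

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")
        if self.antibody not in ("specific", "IgG", "input", "none"):
            raise ValueError(f"unknown antibody class {self.antibody!r}")


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float,
                     efficiency: float = 2.0) -> float:
    """Comparative-Ct fold change of a target gene against a housekeeping
    reference (actin by convention).

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control);
    fold = efficiency ** (-ddCt), with efficiency 2 for perfect doubling.
    """
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_ctrl - ct_ref_ctrl)
    return float(efficiency ** (-ddct))


def chip_fold_enrichment(ct_ab: float, ct_igg: float,
                         ct_input_ab: float, ct_input_igg: float,
                         efficiency: float = 2.0,
                         mode: str = "delta_ct") -> float:
    """ChIP-qPCR fold enrichment of the specific antibody over control IgG,
    relative to input.

    ``mode='delta_ct'`` (default) corrects each antibody by its own input
    Ct and exponentiates the IgG-vs-Ab difference:
    fold = 2 ** [(Ct_IgG - Ct_input,IgG) - (Ct_Ab - Ct_input,Ab)].
    ``mode='percent_input'`` instead forms each antibody's percent-input
    recovery and returns their ratio (identical when efficiency is shared).
    """
    if mode == "delta_ct":
        exponent = (ct_igg - ct_input_igg) - (ct_ab - ct_input_ab)
        return float(efficiency ** exponent)
    if mode == "percent_input":
        ab_recovery = efficiency ** (ct_input_ab - ct_ab)
        igg_recovery = efficiency ** (ct_input_igg - ct_igg)
        return float(ab_recovery / igg_recovery)
    raise ValueError("mode must be 'delta_ct' or 'percent_input'")


def densitometry_ratio(band_intensity: float, actin_intensity: float,
                       control_ratio: float) -> float:
    """Band intensity normalized to the actin loading control, relative to
    the control lane's band/actin ratio."""
    if actin_intensity <= 0:
        raise ValueError("actin intensity must be positive")
    if control_ratio <= 0:
        raise ValueError("control ratio must be positive")
    return (band_intensity / actin_intensity) / control_ratio
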