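"""Quantitative assay calculators used alongside the transcriptome pipeline.

Closed-form formulas for the wet-lab measurements that accompany pump
inhibition experiments: ratiometric fura-2 intracellular free calcium,
steady-state radiotracer cation content, ¹⁴C-urea-space intracellular water
volume, intracellular BAPTA concentration, and ΔΔCt relative qPCR folds.
Units are carried in argument names and docstrings; no automatic unit
conversion is performed beyond the stated µl/mg ↔ µM identity.
"""

from __future__ import annotations

import dataclasses

__all__ = [
    "FuraCalibration",
    "TracerMeasurement",
    "UreaSpace",
    "fura2_ca",
    "cation_content",
    "urea_space_volume",
    "bapta_content",
    "bapta_concentration",
    "ddct_fold",
]


@dataclasses.dataclass
class FuraCalibration:
    """Fura-2 calibration: dissociation constant and ratio limits.

    kd_nm defaults to 224 nM, the Ca²⁺–fura-2 dissociation constant at
    37 °C. rmin/rmax are the F340/F380 ratios at zero and saturating Ca²⁺.
    """

    kd_nm: float = 224.0
    rmin: float = 0.5
    rmax: float = 2.5

    def __post_init__(self) -> None:
        if self.kd_nm <= 0:
            raise ValueError("Kd must be positive")
        if not 0 < self.rmin < self.rmax:
            raise ValueError("need 0 < Rmin < Rmax")


@dataclasses.dataclass
class TracerMeasurement:
    """Steady-state tracer measurement for cation content.

    sample_cpm — sample radioactivity A (cpm); specific_cpm_per_nmol — the
    medium's specific radioactivity a (cpm/nmol); protein_mg — protein m.
    """

    sample_cpm: float
    specific_cpm_per_nmol: float
    protein_mg: float

    def __post_init__(self) -> None:
        if self.sample_cpm < 0:
            raise ValueError("sample radioactivity must be >= 0")
        if self.specific_cpm_per_nmol <= 0:
            raise ValueError("specific radioactivity must be > 0")
        if self.protein_mg <= 0:
            raise ValueError("protein content must be > 0")


@dataclasses.dataclass
class UreaSpace:
    """¹⁴C-urea distribution measurement for intracellular water volume.

    medium_volume_l — medium volume V₀ (litres) used for the medium count;
    lysate_dpm / medium_dpm — urea radioactivity in lysate (Aᵢ) and medium
    (A₀); protein_mg — lysate protein m.
    """

    medium_volume_l: float
    lysate_dpm: float
    medium_dpm: float
    protein_mg: float

    def __post_init__(self) -> None:
        if self.medium_volume_l <= 0 or self.medium_dpm <= 0 or self.protein_mg <= 0:
            raise ValueError("medium volume, medium counts and protein must be > 0")
        if self.lysate_dpm < 0:
            raise ValueError("lysate counts must be >= 0")


def fura2_ca(r: float, cal: FuraCalibration | None = None,
             fluorescence_scale: float = 1.0) -> float:
    """Intracellular free [Ca²⁺] (nM) from the fura-2 ratio R = F340/F380.

    [Ca²⁺]ᵢ = Kd · (R − Rmin) / (Rmax − R), optionally multiplied by the
    Sf/Sb fluorescence-scaling factor of the extended ratiometric equation
    (``fluorescence_scale``, default 1 — the bare-ratio form). Strictly
    increasing in R on [Rmin, Rmax); the calibration midpoint returns Kd.
    """
    cal = cal or FuraCalibration()
    if fluorescence_scale <= 0:
        raise ValueError("fluorescence scale factor must be > 0")
    if r < cal.rmin:
        raise ValueError(f"R={r} below calibration range (Rmin={cal.rmin})")
    if r >= cal.rmax:
        raise ValueError(f"R={r} at or above saturation (Rmax={cal.rmax})")
    return cal.kd_nm * fluorescence_scale * (r - cal.rmin) / (cal.rmax - r)


def cation_content(t: TracerMeasurement) -> float:
    """Intracellular cation content A/(a·m) in nmol per mg protein."""
    return t.sample_cpm / (t.specific_cpm_per_nmol * t.protein_mg)


def urea_space_volume(u: UreaSpace) -> float:
    """Intracellular water volume Vᵢ = V₀·Aᵢ/(A₀·m) in µl per mg protein.

    V₀ is supplied in litres; the result is converted to µl/mg.
    """
    litres_per_mg = u.medium_volume_l * u.lysate_dpm / (u.medium_dpm * u.protein_mg)
    return litres_per_mg * 1e6


def bapta_content(delta_a255: float, delta_a255_standard: float,
                  standard_pmol: float = 1000.0,
                  protein_mg: float = 1.0) -> float:
    """Intracellular BAPTA content in pmol per mg protein.

    Estimated from the EGTA-triggered A₂₅₅ increment of the lysate relative
    to that of an internal standard (default 0.001 µmol = 1000 pmol BAPTA),
    scaled per mg of lysate protein.
    """
    if delta_a255_standard <= 0:
        raise ValueError("standard absorbance increment must be > 0")
    if protein_mg <= 0:
        raise ValueError("protein content must be > 0")
    return delta_a255 / delta_a255_standard * standard_pmol / protein_mg


def bapta_concentration(content_pmol_per_mg: float,
                        vi_ul_per_mg: float) -> float:
    """Intracellular [BAPTA] in µM from content and water volume.

    pmol/mg divided by µl/mg is pmol/µl = µmol/l = µM, so the division is
    the whole conversion: 260 pmol/mg over 2 µl/mg gives 130 µM.
    """
    if vi_ul_per_mg <= 0:
        raise ValueError("intracellular water volume must be > 0")
    if content_pmol_per_mg < 0:
        raise ValueError("BAPTA content must be >= 0")
    return content_pmol_per_mg / vi_ul_per_mg


def ddct_fold(ct_gene_treated: float, ct_ref_treated: float,
              ct_gene_control: float, ct_ref_control: float) -> float:
    """Relative expression fold by the ΔΔCt method.

    ΔΔCt = (Ct_gene − Ct_ref)_treated − (Ct_gene − Ct_ref)_control;
    fold = 2^(−ΔΔCt). The reference gene (β₂-microglobulin in the assays
    this mirrors) normalizes input amounts.
    """
    for v in (ct_gene_treated, ct_ref_treated, ct_gene_control,
              ct_ref_control):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("Ct values must be finite")
    ddct = (ct_gene_treated - ct_ref_treated) - (
        ct_gene_control - ct_ref_control
    )
    return 2.0 ** (-ddct)
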