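"""Global volumetric and mass indices per subject.

Scalar companions to the per-vertex maps: cavity volumes at both phases,
stroke volume and ejection fraction, myocardial mass (free wall only, the
septum is excluded by its template label), and the BSA-indexed variants.
Ventricular mass index (VMI, Fulton's index) is the ratio of the RV mass
index to the LV mass index; LV mass enters as a scalar input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import SEPTUM, VentricularShell, cavity_volume, vertex_voronoi_areas

__all__ = ["MYOCARDIAL_DENSITY_G_PER_ML", "VolumetricIndices",
           "mosteller_bsa", "volumetric_indices"]

# standard CMR convention for myocardial tissue density
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class VolumetricIndices:
    rvedv: float     # mL
    rvesv: float     # mL
    sv: float        # mL
    rvef: float      # %
    rvm: float       # g, free wall only
    bsa: float       # m²
    rvedvi: float    # mL/m²
    rvsvi: float     # mL/m²
    rvmi: float      # g/m²
    vmi: float       # dimensionless

    def as_table_rows(self) -> dict[str, float]:
        """Row names matching the conventional baseline-characteristics table."""
        return {
            "RV end-diastolic volume (mL)": self.rvedv,
            "RV end-systolic volume (mL)": self.rvesv,
            "RV end-diastolic volume (indexed) (mL/m^2)": self.rvedvi,
            "RV stroke volume (mL)": self.sv,
            "RV stroke volume (indexed) (mL/m^2)": self.rvsvi,
            "RV ejection fraction (%)": self.rvef,
            "RV mass (g)": self.rvm,
            "RV mass (indexed) (g/m^2)": self.rvmi,
            "Ventricular mass index": self.vmi,
        }


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²) by the Mosteller formula sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def _myocardial_volume_ml(shell: VentricularShell, wt_values: np.ndarray) -> float:
    """Free-wall myocardial volume: epi-endo shell volume with the septal
    wall share removed.

    The septal share is estimated from the thickness-weighted mid-surface
    area of septum-labelled vertices, which is exact when the wall has uniform
    thickness and reduces to the full shell volume when no septum is labelled.
    """
    shell_vol = cavity_volume(shell.epi) - cavity_volume(shell.endo)
    if shell_vol < 0:
        raise ValueError("negative shell volume: check mesh orientation")
    septal = shell.region_labels == SEPTUM
    if not np.any(septal):
        return shell_vol
    mid = VentricularShell(shell.endo, shell.epi, shell.region_labels).endo
    areas = vertex_voronoi_areas(mid)
    wt_area = wt_values * areas
    total = wt_area.sum()
    septal_share = wt_area[septal].sum() / total if total > 0 else 0.0
    return shell_vol * (1.0 - septal_share)


def volumetric_indices(shell_ed: VentricularShell, shell_es: VentricularShell,
                       wt_ed: np.ndarray, bsa: float,
                       lv_mass_indexed: float | None = None) -> VolumetricIndices:
    """Cavity volumes, EF, free-wall mass and their BSA-indexed versions.

    ``wt_ed`` is the per-vertex end-diastolic wall thickness used to apportion
    the septal share of the myocardial shell. ``lv_mass_indexed`` (g/m²) is
    required for VMI; if absent VMI is reported as NaN.
    """
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    rvedv = cavity_volume(shell_ed.endo)
    rvesv = cavity_volume(shell_es.endo)
    if rvedv <= 0:
        raise ValueError("RVEDV is zero: ejection fraction undefined")
    sv = rvedv - rvesv
    rvef = 100.0 * sv / rvedv
    rvm = _myocardial_volume_ml(shell_ed, wt_ed) * MYOCARDIAL_DENSITY_G_PER_ML
    rvmi = rvm / bsa
    vmi = rvmi / lv_mass_indexed if lv_mass_indexed else float("nan")
    return VolumetricIndices(rvedv=rvedv, rvesv=rvesv, sv=sv, rvef=rvef,
                             rvm=rvm, bsa=bsa, rvedvi=rvedv / bsa,
                             rvsvi=sv / bsa, rvmi=rvmi, vmi=vmi)
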