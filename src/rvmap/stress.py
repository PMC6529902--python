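"""End-systolic wall-stress mapping.

Wall stress quantifies the load the cavity pressure places on the myocardium.
The map uses a thick-wall Laplace law that retains the first-order correction
for finite wall thickness, so it remains valid for the relatively thick,
hypertrophied right ventricle:

    stress_v = 0.133 * sPAP * R_v / (2 * WT_v) * (1 + WT_v / (2 * R_v))

with sPAP the invasively measured systolic pulmonary artery pressure (mmHg),
R_v the inner (endocardial) radius of curvature (mm) and WT_v the end-systolic
wall thickness (mm), evaluated at every template vertex. The factor 0.133
converts mmHg to kN/m². In the thin-wall limit WT/R -> 0 this reduces to the
Young-Laplace law sPAP*R/(2*WT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CurvatureField, SurfaceMesh, VentricularShell, VertexField, \
    compute_curvature, compute_wall_thickness, inner_radius

__all__ = ["MMHG_TO_KN_M2", "StressInputs", "StressField",
           "compute_wall_stress", "stress_from_shell"]

MMHG_TO_KN_M2 = 0.133


@dataclass
class StressInputs:
    """Scalar pressure plus per-vertex geometry feeding the stress formula."""

    spap: float                 # systolic pulmonary artery pressure, mmHg
    radius: VertexField         # inner radius of curvature, mm
    wall_thickness: VertexField  # end-systolic WT, mm
    degenerate_curvature: np.ndarray | None = None  # clamped-R vertices

    def __post_init__(self) -> None:
        if self.spap < 0:
            raise ValueError("sPAP must be non-negative")
        if len(self.radius) != len(self.wall_thickness):
            raise ValueError("R and WT must share the template vertex count")
        if np.any(self.radius.values[~self.radius.mask] <= 0):
            raise ValueError("inner radius of curvature must be positive")
        if np.any(self.wall_thickness.values[~self.wall_thickness.mask] < 0):
            raise ValueError("wall thickness must be non-negative")
        if self.degenerate_curvature is None:
            self.degenerate_curvature = np.zeros(len(self.radius), dtype=bool)


@dataclass
class StressField:
    stress: VertexField          # kN/m²
    mask: np.ndarray             # True where excluded (WT = 0 or clamped R)


def compute_wall_stress(inputs: StressInputs) -> StressField:
    """Per-vertex thick-wall Laplace stress in kN/m².

    Vertices with WT = 0 are masked rather than producing infinities, and
    vertices whose curvature hit the clamping floor are carried in the mask so
    downstream statistics can treat them as missing.
    """
    R = inputs.radius.values
    wt = inputs.wall_thickness.values
    zero_wt = wt <= 0
    mask = (zero_wt | inputs.degenerate_curvature
            | inputs.radius.mask | inputs.wall_thickness.mask)
    stress = np.zeros_like(R)
    ok = ~zero_wt
    stress[ok] = (MMHG_TO_KN_M2 * inputs.spap * R[ok] / (2.0 * wt[ok])
                  * (1.0 + wt[ok] / (2.0 * R[ok])))
    field_ = VertexField(stress, units="kN/m^2", name="wall_stress_ES",
                         mask=mask.copy())
    return StressField(stress=field_, mask=mask)


def stress_from_shell(shell_es: VentricularShell, spap: float,
                      curvature_floor: float = 0.01) -> StressField:
    """Full chain on an end-systolic shell: curvature -> R -> WT -> stress."""
    curv = compute_curvature(shell_es.endo)
    radius, clamped = inner_radius(curv, floor=curvature_floor)
    wt, _ = compute_wall_thickness(shell_es)
    return compute_wall_stress(StressInputs(spap, radius, wt,
                                            degenerate_curvature=clamped))
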