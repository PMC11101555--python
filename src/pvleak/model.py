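"""Top-level Model/Results interface tying the pipeline together.

``LeakageModel`` holds the gap geometry (a slice stack or a shell mesh)
together with fluid and hemodynamic parameters; ``fit()`` runs pressure
scaling (optional), the finite-element Reynolds solve and the
regurgitant-volume conversion, returning a ``LeakageResults`` object
with the estimates, diagnostics, a ``summary()`` table, and exporters
for the JSON report and the VTK flux field.

Example
-------
>>> from pvleak import LeakageModel, synthetic
>>> stack = synthetic.make_annular_die(10e-3, 11e-3, 30e-3)
>>> res = LeakageModel(stack).fit(scale_bc=False, dp=13.32e3)
>>> round(res.flow_rate_ml_s, 1)  # doctest: +SKIP
697.4
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .geometry import ShellMesh, SliceStack, build_midgap_mesh, leakage_volume
from .report import LeakageReport, classify_pvl, diastolic_duration, flow_to_rv
from .reynolds import (
    DEFAULT_EPS,
    FluidProperties,
    PressureSolution,
    solve_pressure,
)
from .scaling import HemodynamicContext, ScalingReport, scale_pressure
from .slicing import load_surface, slice_surfaces
from .vtu import write_vtu

__all__ = ["LeakageModel", "LeakageResults"]


class LeakageModel:
    """Thin-film paravalvular-leakage model on a mid-gap shell mesh.

    Parameters
    ----------
    geometry : SliceStack or ShellMesh
        The paravalvular gap.  A slice stack is lofted into the mid-gap
        shell mesh automatically; pressure scaling requires a stack.
    fluid : FluidProperties
        Blood viscosity and density.
    hemo : HemodynamicContext
        MAP, reference pressure, aortic area, discharge coefficient,
        heart rate and diastolic fraction.
    quadrature : {"centroid", "midedge"}
        Quadrature rule for the h³ element conductance.
    eps : float
        Lower clamp on the nodal gap (m) regularising contact regions.
    """

    def __init__(
        self,
        geometry: SliceStack | ShellMesh,
        fluid: FluidProperties | None = None,
        hemo: HemodynamicContext | None = None,
        quadrature: str = "centroid",
        eps: float = DEFAULT_EPS,
    ):
        if isinstance(geometry, SliceStack):
            self.stack: SliceStack | None = geometry
            self.mesh = build_midgap_mesh(geometry)
        elif isinstance(geometry, ShellMesh):
            self.stack = None
            self.mesh = geometry
        else:
            raise TypeError("geometry must be a SliceStack or a ShellMesh")
        self.fluid = fluid or FluidProperties()
        self.hemo = hemo or HemodynamicContext()
        self.quadrature = quadrature
        self.eps = eps

    @classmethod
    def from_surfaces(
        cls,
        stent_path,
        aorta_path,
        z_levels,
        n_theta: int = 256,
        axis_origin=(0.0, 0.0, 0.0),
        axis_direction=(0.0, 0.0, 1.0),
        **kwargs,
    ) -> "LeakageModel":
        """Build the model by slicing two STL surfaces."""
        stack = slice_surfaces(
            load_surface(stent_path),
            load_surface(aorta_path),
            z_levels=z_levels,
            n_theta=n_theta,
            axis_origin=axis_origin,
            axis_direction=axis_direction,
        )
        return cls(stack, **kwargs)

    def fit(
        self,
        scale_bc: bool = True,
        dp: float | None = None,
        solver: str = "direct",
    ) -> "LeakageResults":
        """Solve the model and return results.

        scale_bc : apply the orifice-consistent pressure scaling (needs
            a slice stack).  With ``scale_bc=False`` the raw pressure is
            applied directly — the setting used for die verification.
        dp : overriding pressure difference in Pa (default: the MAP).
        """
        scaling: ScalingReport | None = None
        if scale_bc:
            if self.stack is None:
                raise ValueError("pressure scaling requires a slice stack geometry")
            scaling = scale_pressure(
                self.stack, self.hemo, mu=self.fluid.mu, rho=self.fluid.rho
            )
            dp_applied = scaling.dp_applied
        else:
            dp_applied = self.hemo.map_pressure if dp is None else float(dp)
        sol = solve_pressure(
            self.mesh,
            self.fluid,
            p_inlet=self.hemo.p0 + dp_applied,
            p_outlet=self.hemo.p0,
            quadrature=self.quadrature,
            eps=self.eps,
            solver=solver,
        )
        return LeakageResults(model=self, solution=sol, scaling=scaling, dp_applied=dp_applied)


@dataclass(eq=False)
class LeakageResults:
    """Fitted leakage estimates, diagnostics and exporters."""

    model: LeakageModel
    solution: PressureSolution
    scaling: ScalingReport | None
    dp_applied: float
    _report: LeakageReport = field(default=None, repr=False)

    # -- primary estimates --------------------------------------------------

    @property
    def flow_rate(self) -> float:
        """Leakage flow rate, m³/s (positive: aorta → ventricle)."""
        return self.solution.Q

    @property
    def flow_rate_ml_s(self) -> float:
        return units.m3s_to_mls(self.flow_rate)

    @property
    def diastolic_duration_s(self) -> float:
        return diastolic_duration(self.model.hemo.heart_rate, self.model.hemo.diastolic_fraction)

    @property
    def regurgitant_volume_ml(self) -> float:
        return flow_to_rv(
            self.flow_rate_ml_s,
            self.model.hemo.heart_rate,
            self.model.hemo.diastolic_fraction,
        )

    @property
    def severity(self) -> str:
        return classify_pvl(self.regurgitant_volume_ml)

    # -- diagnostics --------------------------------------------------------

    @property
    def conservation_error(self) -> float:
        """Relative inlet/outlet flow mismatch."""
        scale = max(abs(self.solution.Q_in), abs(self.solution.Q_out), 1e-300)
        return abs(self.solution.Q_in - self.solution.Q_out) / scale

    def to_report(self) -> LeakageReport:
        hemo = self.model.hemo
        solver_info = {
            "Q_in_m3_s": self.solution.Q_in,
            "Q_out_m3_s": self.solution.Q_out,
            "conservation_error": self.conservation_error,
            "dp_applied_Pa": self.dp_applied,
            "n_nodes": self.model.mesh.n_points,
            "n_triangles": self.model.mesh.n_triangles,
            "quadrature": self.model.quadrature,
            "eps_m": self.model.eps,
        }
        inputs = {
            "map_pressure_mmHg": units.pa_to_mmhg(hemo.map_pressure),
            "mu_Pa_s": self.model.fluid.mu,
            "rho_kg_m3": self.model.fluid.rho,
            "heart_rate_bpm": hemo.heart_rate,
            "diastolic_fraction": hemo.diastolic_fraction,
            "aorta_area_m2": hemo.aorta_area,
            "discharge_coefficient": hemo.discharge_coefficient,
        }
        if self.model.stack is not None:
            inputs["leakage_volume_ml"] = units.m3_to_ml(leakage_volume(self.model.stack))
        return LeakageReport.from_flow_rate(
            self.flow_rate_ml_s,
            heart_rate=hemo.heart_rate,
            diastolic_fraction=hemo.diastolic_fraction,
            scaling=self.scaling.to_dict() if self.scaling else None,
            solver=solver_info,
            inputs=inputs,
        )

    def export_vtu(self, path):
        """Write the leakage-path flux field for ParaView."""
        q = self.solution.q_global
        return write_vtu(
            self.model.mesh,
            path,
            point_data={"p": self.solution.p, "h": self.model.mesh.h},
            cell_data={"q": q, "q_magnitude": np.linalg.norm(q, axis=1)},
        )

    def summary(self) -> str:
        """Plain-text summary table of the fitted leakage estimates."""
        lines = [
            "Paravalvular leakage model results",
            "=" * 50,
            f"{'mesh nodes':<32}{self.model.mesh.n_points:>18}",
            f"{'mesh triangles':<32}{self.model.mesh.n_triangles:>18}",
            f"{'applied pressure (mmHg)':<32}{units.pa_to_mmhg(self.dp_applied):>18.3f}",
            f"{'applied pressure (kPa)':<32}{self.dp_applied / 1e3:>18.3f}",
            f"{'scaled boundary condition':<32}{str(self.scaling is not None):>18}",
        ]
        if self.scaling is not None:
            lines += [
                f"{'scaling slice index':<32}{self.scaling.selected_slice_index:>18}",
                f"{'orifice area A2 (mm^2)':<32}{self.scaling.A2 * 1e6:>18.3f}",
                f"{'orifice flow Q_B (ml/s)':<32}{units.m3s_to_mls(self.scaling.Q_B):>18.2f}",
                f"{'volume factor f_V':<32}{self.scaling.f_V:>18.4f}",
            ]
        lines += [
            "-" * 50,
            f"{'flow rate Q (ml/s)':<32}{self.flow_rate_ml_s:>18.2f}",
            f"{'diastolic duration (s)':<32}{self.diastolic_duration_s:>18.3f}",
            f"{'regurgitant volume RV (ml)':<32}{self.regurgitant_volume_ml:>18.2f}",
            f"{'PVL severity':<32}{self.severity:>18}",
            f"{'flow conservation error':<32}{self.conservation_error:>18.2e}",
            "=" * 50,
        ]
        return "\n".join(lines)
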