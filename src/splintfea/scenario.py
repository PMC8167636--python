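"""End-to-end splint scenarios: load assembly, post-processing, safety.

Three design options mirror the clinical protocol:

* option 1 — no splint; each tooth carries its own measured occlusal force
  on its crown-top nodes.  With the periodontal outer surface fixed and no
  contact between teeth, every tooth is an independent substructure.
* option 2 — splint as manufactured; the (smaller) measured total force is
  applied to the splint's occlusal surface and redistributed to the teeth
  through the bonded splint-crown interfaces.
* option 3 — splint after corrective grinding; same mechanics as option 2
  with the post-correction measurement.  Grinding is represented purely by
  the changed measurement, not by altered splint geometry.

Post-processing reports per-region maxima of total displacement |u| and
element-constant von Mises stress (no nodal averaging — the averaging
choice changes maxima and is therefore pinned down here), classifies where
each stress maximum sits (root attachment vs crown contact), forms
between-option ratios, and checks physiological/material safety limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fea
from .geometry import Dentition, DentitionSpec, build_dentition
from .meshing import DentitionModel, interface_nodes, mesh_dentition
from .occlusal import OcclusalMeasurement, calibrate

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "SafetyThresholds",
    "SafetyReport",
    "RunResult",
    "build_scenario",
    "run_option",
    "summarize",
    "compare_options",
    "safety_check",
    "tooth_class",
]

#: FDI position digit -> anatomical class.
_CLASS_OF_POSITION = {1: "incisor", 2: "incisor", 3: "canine", 4: "premolar",
                      5: "premolar", 6: "molar", 7: "molar"}


def tooth_class(fdi: int) -> str:
    """Anatomical class (incisor/canine/premolar/molar) of an FDI code."""
    try:
        return _CLASS_OF_POSITION[fdi % 10]
    except KeyError:
        raise ValueError(f"unknown tooth class for FDI code {fdi}") from None


@dataclass(frozen=True)
class ScenarioConfig:
    """One design option bound to its occlusal measurement."""

    option: int
    measurement: OcclusalMeasurement
    dentition_spec: DentitionSpec = field(default_factory=DentitionSpec)
    load_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    cell_size_mm: float | None = None

    def __post_init__(self) -> None:
        if self.option not in (1, 2, 3):
            raise ValueError(f"option must be 1, 2 or 3, got {self.option}")

    @property
    def with_splint(self) -> bool:
        return self.option in (2, 3)


@dataclass(frozen=True)
class SafetyThresholds:
    """Physiological and material limits the solution is checked against.

    Units: mm for mobility, MPa for stresses.  The dentin comparison uses
    the conservative lower tensile bound by default; the PDL limits are the
    per-class allowables for the 20-49-year age group, taken at the lower
    end of the published bands.
    """

    mobility_limit_mm: float = 0.03
    dentin_tensile_min_MPa: float = 44.40
    dentin_tensile_max_MPa: float = 97.80
    dentin_compressive_MPa: float = 297.20
    pdl_limit_MPa: dict[str, float] = field(
        default_factory=lambda: {
            "incisor": 1.50,
            "canine": 1.60,
            "premolar": 1.40,
            "molar": 1.20,
        }
    )
    pmma_fracture_MPa: float = 32.00

    def __post_init__(self) -> None:
        vals = [self.mobility_limit_mm, self.dentin_tensile_min_MPa,
                self.dentin_tensile_max_MPa, self.dentin_compressive_MPa,
                self.pmma_fracture_MPa, *self.pdl_limit_MPa.values()]
        if any(v <= 0 for v in vals):
            raise ValueError("all safety thresholds must be positive")


@dataclass
class SafetyReport:
    """Per-check verdicts: safe iff observed < threshold (strict).

    margin = threshold / observed; boundary equality is reported unsafe
    with margin 1.0 (conservative convention).
    """

    checks: pd.DataFrame

    @property
    def all_safe(self) -> bool:
        return bool(self.checks["safe"].all())

    def to_dict(self) -> dict:
        return {"all_safe": self.all_safe, "checks": self.checks.to_dict("records")}


@dataclass
class RunResult:
    """Everything one scenario run produces."""

    config: ScenarioConfig
    model: DentitionModel
    load_case: fea.LoadCase
    solution: fea.SolutionFields
    summary: pd.DataFrame


def build_scenario(
    config: ScenarioConfig,
    dentition: Dentition | None = None,
    model: DentitionModel | None = None,
) -> tuple[DentitionModel, fea.LoadCase]:
    """Mesh the dentition for an option and assemble its load case.

    Option 1 places each tooth's calibrated force on its own occlusal node
    set; options 2/3 place the calibrated total on the splint's occlusal
    surface.  The outer PDL surface is fully fixed.  A pre-built dentition
    or mesh may be passed to avoid re-meshing across options.
    """
    if model is None:
        if dentition is None:
            dentition = build_dentition(config.dentition_spec, with_splint=config.with_splint)
        if config.with_splint and dentition.splint is None:
            raise ValueError(f"option {config.option} requires a splint region")
        model = mesh_dentition(dentition, cell_size_mm=config.cell_size_mm)
    if config.with_splint and "splint" not in model.region_names:
        raise ValueError(f"option {config.option} requires a splint region")

    dist = calibrate(config.measurement)
    direction = np.asarray(config.load_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    lc: fea.LoadCase | None = None
    if config.with_splint:
        lc = fea.apply_occlusal_pressure(
            model, "occlusal_splint", dist.total_force_N, direction
        )
    else:
        for fdi in model.fdi_codes:
            force = dist.per_tooth_N.get(fdi, 0.0)
            if force == 0.0:
                continue
            lc = fea.apply_occlusal_pressure(
                model, f"occlusal_{fdi}", force, direction, load_case=lc
            )
        if lc is None:
            raise ValueError("measurement loads none of the meshed teeth")
    lc.fixed_nodes = model.node_set("pdl_outer")
    return model, lc


def run_option(
    config: ScenarioConfig,
    dentition: Dentition | None = None,
    model: DentitionModel | None = None,
) -> RunResult:
    """Build, solve and summarize one design option (deterministic)."""
    model, lc = build_scenario(config, dentition=dentition, model=model)
    materials = fea.default_materials(model)
    log.info(
        "option %d: %d nodes, %d elements, %d regions, total load %.3f N",
        config.option, model.n_nodes, model.n_elements,
        len(model.region_names), float(np.abs(lc.nodal_forces).sum()),
    )
    solution = fea.solve_system(model, materials, lc)
    summary = summarize(solution, model)
    log.info(
        "option %d solved: residual %.2e, max |u| %.4g mm, max vM %.4g MPa",
        config.option, solution.residual,
        summary["max_displacement_mm"].max(), summary["max_von_mises_MPa"].max(),
    )
    return RunResult(config=config, model=model, load_case=lc, solution=solution, summary=summary)


def _max_stress_location(
    model: DentitionModel, region: str, element: int
) -> str:
    """Classify where a region's peak-stress element sits.

    "root_attachment" if it touches the tooth-PDL interface (the upper part
    of the root, where fixation begins), "crown_contact" if it touches the
    splint-crown interface, else "body".
    """
    nodes = set(model.elements[element])
    fdi = region.removeprefix("pdl_")
    if fdi.isdigit() and f"pdl_{fdi}" in model.region_names:
        root = interface_nodes(model, fdi, f"pdl_{fdi}")
        if nodes & set(root):
            return "root_attachment"
    if f"crown_outer_{fdi}" in model.node_sets:
        if nodes & set(model.node_sets[f"crown_outer_{fdi}"]):
            return "crown_contact"
    if region == "splint" and "splint_inner" in model.node_sets:
        if nodes & set(model.node_sets["splint_inner"]):
            return "crown_contact"
    return "body"


def summarize(solution: fea.SolutionFields, model: DentitionModel) -> pd.DataFrame:
    """Per-region maxima of |u| and von Mises, with peak-stress location.

    One row per region (each tooth, each PDL shell, the splint).  Maxima are
    taken over the region's nodes (displacement) and elements (stress);
    both are invariant to node or element reordering.
    """
    rows = []
    for name in model.region_names:
        elems = model.elements_of(name)
        region_nodes = np.unique(model.elements[elems])
        disp = solution.total_displacement[region_nodes]
        vm = solution.von_mises[elems]
        imax = int(elems[np.argmax(vm)]) if len(elems) else -1
        if name == "splint":
            kind, fdi = "splint", pd.NA
        elif name.startswith("pdl_"):
            kind, fdi = "pdl", int(name.removeprefix("pdl_"))
        else:
            kind, fdi = "tooth", int(name)
        rows.append(
            {
                "region": name,
                "kind": kind,
                "fdi": fdi,
                "max_displacement_mm": float(disp.max()) if len(disp) else 0.0,
                "max_von_mises_MPa": float(vm.max()) if len(vm) else 0.0,
                "max_stress_location": _max_stress_location(model, name, imax),
            }
        )
    return pd.DataFrame(rows)


def compare_options(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Per-region ratios (b over a) of the displacement and stress maxima.

    Zero denominators yield NaN ("undefined") rather than raising; the
    paper-style reading is "how many times larger option b's maximum is".
    """
    a = summary_a.set_index("region")
    b = summary_b.set_index("region")
    teeth_a = set(a.index[a["kind"] == "tooth"])
    teeth_b = set(b.index[b["kind"] == "tooth"])
    if teeth_a != teeth_b:
        raise ValueError("summaries cover different tooth sets")
    common = [r for r in a.index if r in set(b.index)]
    a, b = a.loc[common], b.loc[common]
    out = pd.DataFrame(index=a.index)
    out["kind"] = a["kind"]
    out["fdi"] = a["fdi"]
    for col in ("max_displacement_mm", "max_von_mises_MPa"):
        denom = a[col].to_numpy(dtype=float)
        num = b[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, num / denom, np.nan)
        out[f"ratio_{col.removeprefix('max_')}"] = ratio
    return out.reset_index()


def safety_check(
    summary: pd.DataFrame, thresholds: SafetyThresholds | None = None
) -> SafetyReport:
    """Compare per-region maxima against physiological/material limits.

    Teeth: mobility vs 0.03 mm and dentin stress vs the conservative lower
    tensile bound; PDL shells: class-specific allowable; splint: PMMA
    static fracture stress.
    """
    th = thresholds or SafetyThresholds()
    rows = []

    def add(region, quantity, observed, limit):
        rows.append(
            {
                "region": region,
                "quantity": quantity,
                "observed": float(observed),
                "threshold": float(limit),
                "safe": bool(observed < limit),
                "margin": float(limit / observed) if observed > 0 else float("inf"),
            }
        )

    for _, row in summary.iterrows():
        if row["kind"] == "tooth":
            add(row["region"], "displacement_mm", row["max_displacement_mm"], th.mobility_limit_mm)
            add(row["region"], "von_mises_MPa", row["max_von_mises_MPa"], th.dentin_tensile_min_MPa)
        elif row["kind"] == "pdl":
            limit = th.pdl_limit_MPa[tooth_class(int(row["fdi"]))]
            add(row["region"], "von_mises_MPa", row["max_von_mises_MPa"], limit)
        elif row["kind"] == "splint":
            add(row["region"], "von_mises_MPa", row["max_von_mises_MPa"], th.pmma_fracture_MPa)
    return SafetyReport(checks=pd.DataFrame(rows))


def scenario_for_option(
    option: int,
    measurements: dict[int, OcclusalMeasurement],
    spec: DentitionSpec | None = None,
    **kwargs,
) -> ScenarioConfig:
    """Convenience: option i paired with measurement i, as in the protocol."""
    cfg = ScenarioConfig(
        option=option,
        measurement=measurements[option],
        dentition_spec=spec or DentitionSpec(),
        **kwargs,
    )
    return cfg
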