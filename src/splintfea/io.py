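"""File formats and run bookkeeping.

Measurements travel as small CSV/JSON files (the packaged fixtures carry
the three clinical T-Scan acquisitions), summaries as CSV tables, surfaces
as binary STL through trimesh, and full solutions as legacy-ASCII VTK
unstructured grids for inspection in ParaView.  Every pipeline run can emit
a manifest recording the configuration hash, seed, package versions,
per-stage timings and the produced files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .geometry import DentitionSpec
from .meshing import DentitionModel, region_surface
from .occlusal import VALID_FDI, OcclusalMeasurement

__all__ = [
    "read_measurement_csv",
    "read_measurement_json",
    "write_measurement_csv",
    "load_packaged_measurement",
    "packaged_measurements",
    "write_summary_csv",
    "read_summary_csv",
    "export_stl",
    "import_stl",
    "export_region_stl",
    "write_vtk",
    "spec_to_yaml",
    "spec_from_yaml",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# occlusal measurements


def read_measurement_csv(path: str | Path) -> OcclusalMeasurement:
    """Parse a measurement CSV.

    Layout: comment header lines ``# key=value`` carrying at least
    ``raw_sum`` (and optionally ``measurement_id``), then a
    ``tooth_id,share_pct`` table.  Errors cite the offending line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    shares: dict[int, float] = {}
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if not header_seen:
                if parts[:2] != ["tooth_id", "share_pct"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'tooth_id,share_pct', got {line!r}"
                    )
                header_seen = True
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                tooth = int(parts[0])
                share = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if tooth not in VALID_FDI:
                raise ValueError(f"{path}:{lineno}: unknown FDI code {tooth}")
            if tooth in shares:
                raise ValueError(f"{path}:{lineno}: duplicated tooth ID {tooth}")
            shares[tooth] = share
    if "raw_sum" not in meta:
        raise ValueError(f"{path}: missing '# raw_sum=' header line")
    if not shares:
        raise ValueError(f"{path}: no tooth rows found")
    return OcclusalMeasurement(
        measurement_id=meta.get("measurement_id", path.stem),
        raw_sum=int(meta["raw_sum"]),
        shares=shares,
    )


def read_measurement_json(path: str | Path) -> OcclusalMeasurement:
    """JSON equivalent: {"measurement_id", "raw_sum", "shares": {fdi: pct}}."""
    data = json.loads(Path(path).read_text())
    return OcclusalMeasurement(
        measurement_id=data.get("measurement_id", Path(path).stem),
        raw_sum=int(data["raw_sum"]),
        shares={int(k): float(v) for k, v in data["shares"].items()},
    )


def write_measurement_csv(measurement: OcclusalMeasurement, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"# measurement_id={measurement.measurement_id}",
        f"# raw_sum={measurement.raw_sum}",
        "tooth_id,share_pct",
    ]
    for tooth in sorted(measurement.shares):
        share = measurement.shares[tooth]
        lines.append(f"{tooth},{share:g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def packaged_measurements() -> dict[int, OcclusalMeasurement]:
    """The three clinical acquisitions shipped with the package (1, 2, 3)."""
    return {i: load_packaged_measurement(i) for i in (1, 2, 3)}


def load_packaged_measurement(index: int) -> OcclusalMeasurement:
    if index not in (1, 2, 3):
        raise ValueError("packaged measurements are numbered 1, 2, 3")
    ref = resources.files("splintfea.data") / f"measurement{index}.csv"
    with resources.as_file(ref) as path:
        return read_measurement_csv(path)


# ---------------------------------------------------------------------------
# summary tables


def write_summary_csv(summaries: dict[int, pd.DataFrame], path: str | Path) -> Path:
    """Write per-(region, option) maxima; round-trips through read_summary_csv."""
    if not summaries:
        raise ValueError("no summaries to write")
    frames = []
    for option, df in sorted(summaries.items()):
        frame = df.copy()
        frame.insert(0, "option", int(option))
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_summary_csv(path: str | Path) -> dict[int, pd.DataFrame]:
    df = pd.read_csv(path, dtype={"fdi": "Int64"})
    return {
        int(opt): g.drop(columns="option").reset_index(drop=True)
        for opt, g in df.groupby("option")
    }


# ---------------------------------------------------------------------------
# surfaces and solution fields


def export_stl(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> Path:
    """Write a triangulated surface as binary STL (warn if non-watertight)."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not mesh.is_watertight:
        warnings.warn(f"surface written to {path} is not watertight", stacklevel=2)
    path = Path(path)
    mesh.export(path, file_type="stl")
    return path


def import_stl(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangulated surface")
    return mesh


def export_region_stl(model: DentitionModel, region: str, path: str | Path) -> Path:
    """Export one region's closed surface (including region interfaces)."""
    bf = region_surface(model, region)
    used, inverse = np.unique(bf.faces, return_inverse=True)
    return export_stl(model.nodes[used], inverse.reshape(-1, 3), path)


def write_vtk(
    model: DentitionModel,
    path: str | Path,
    point_vectors: dict[str, np.ndarray] | None = None,
    cell_scalars: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the tet mesh as a legacy-ASCII VTK unstructured grid.

    Point vector fields (e.g. displacement) and cell scalar fields (e.g.
    von Mises stress, region id) ride along for ParaView inspection.
    """
    path = Path(path)
    n, m = model.n_nodes, model.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "splintfea dentition model",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{c:.9g}" for c in p) for p in model.nodes]
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(i) for i in e) for e in model.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m  # VTK_TETRA

    if point_vectors:
        lines.append(f"POINT_DATA {n}")
        for name, data in point_vectors.items():
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{c:.9g}" for c in v) for v in np.asarray(data)]
    cell_scalars = dict(cell_scalars or {})
    cell_scalars.setdefault("region_id", model.element_region.astype(float))
    lines.append(f"CELL_DATA {m}")
    for name, data in cell_scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in np.asarray(data, dtype=float)]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# configuration and manifests


def spec_to_yaml(spec: DentitionSpec, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "n_teeth": spec.n_teeth,
        "arch_depth_ratio": spec.arch_depth_ratio,
        "crown_gap_mm": spec.crown_gap_mm,
        "pdl_thickness_mm": spec.pdl_thickness_mm,
        "splint_thickness_mm": spec.splint_thickness_mm,
        "dims_by_position": {int(k): list(v) for k, v in spec.dims_by_position.items()},
        "random_seed": spec.random_seed,
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def spec_from_yaml(path: str | Path) -> DentitionSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "dims_by_position" in data:
        data["dims_by_position"] = {
            int(k): tuple(v) for k, v in data["dims_by_position"].items()
        }
    return DentitionSpec(**data)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    versions: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def hash_config(config_bytes: bytes) -> str:
        return hashlib.sha256(config_bytes).hexdigest()

    @classmethod
    def create(cls, config_bytes: bytes, seed: int) -> "RunManifest":
        import scipy

        from . import __version__

        return cls(
            config_hash=cls.hash_config(config_bytes),
            seed=seed,
            versions={
                "splintfea": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        missing = [o for o in self.outputs if not Path(o).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path
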