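"""File I/O: image stacks, contours, meshes, stress fields, and configs.

Formats
-------
- image/mask stacks: NIfTI (.nii/.nii.gz via nibabel) or a directory of
  per-slice PNG files with a JSON sidecar {pixel_size_mm, slice_spacing_mm};
- contours: CSV with columns slice_index, point_index, x_px, y_px (plus a
  JSON variant carrying spacing metadata);
- meshes: STL / PLY through trimesh;
- stress fields: ASCII legacy VTK (.vtk) and XML VTU (.vtu) with per-cell
  arrays sigma11, sigma12, sigma22, principal_1, principal_2 in N/cm^2;
- configs / load cases: YAML.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .geometry import ContourStack, SurfaceMesh
from .nema import LoadCase, StressField
from .nurbs import SliceContour


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def save_volume_nifti(path, stack: np.ndarray, pixel_size_mm: float,
                      slice_spacing_mm: float) -> None:
    import nibabel as nib

    data = np.asarray(stack)
    # store as (x, y, z) with the slice axis last
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine=np.diag(
        [pixel_size_mm, pixel_size_mm, slice_spacing_mm, 1.0]))
    nib.save(img, str(path))


def load_volume_nifti(path):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    stack = np.transpose(data, (2, 1, 0))
    return stack, float(zooms[0]), float(zooms[2])


def save_volume_png_dir(dirpath, stack: np.ndarray, pixel_size_mm: float,
                        slice_spacing_mm: float) -> None:
    import imageio.v3 as iio

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    stack = np.asarray(stack, dtype=float)
    lo, hi = stack.min(), stack.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    for z, sl in enumerate(stack):
        iio.imwrite(dirpath / f"slice_{z:04d}.png",
                    ((sl - lo) * scale).astype(np.uint16))
    meta = {"pixel_size_mm": pixel_size_mm,
            "slice_spacing_mm": slice_spacing_mm,
            "n_slices": len(stack),
            "intensity_offset": float(lo),
            "intensity_scale": float(1.0 / scale)}
    (dirpath / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_volume_png_dir(dirpath):
    import imageio.v3 as iio

    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "metadata.json").read_text())
    slices = sorted(dirpath.glob("slice_*.png"))
    stack = np.stack([iio.imread(p).astype(float) for p in slices])
    stack = stack * meta.get("intensity_scale", 1.0) \
        + meta.get("intensity_offset", 0.0)
    return stack, meta["pixel_size_mm"], meta["slice_spacing_mm"]


def save_mask_stack(path, masks: np.ndarray, pixel_size_mm: float,
                    slice_spacing_mm: float) -> None:
    save_volume_nifti(path, np.asarray(masks, dtype=np.uint8),
                      pixel_size_mm, slice_spacing_mm)


def load_mask_stack(path):
    stack, px, dz = load_volume_nifti(path)
    return (stack > 0.5).astype(np.uint8), px, dz


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

def save_contours_csv(path, stack: ContourStack) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "point_index", "x_px", "y_px"])
        for z, contour in enumerate(stack.contours):
            for i, (x, y) in enumerate(contour.points):
                writer.writerow([z, i, f"{x:.6f}", f"{y:.6f}"])


def load_contours_csv(path, pixel_size_mm: float,
                      slice_spacing_mm: float) -> ContourStack:
    rows: dict[int, list[tuple[int, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(int(rec["slice_index"]), []).append(
                (int(rec["point_index"]), float(rec["x_px"]),
                 float(rec["y_px"])))
    contours = []
    for z in sorted(rows):
        pts = np.array([(x, y) for _, x, y in sorted(rows[z])])
        contours.append(SliceContour(points=pts, pixel_size=pixel_size_mm))
    return ContourStack(contours=contours, slice_spacing=slice_spacing_mm,
                        pixel_size=pixel_size_mm)


def save_contours_json(path, stack: ContourStack) -> None:
    payload = {
        "pixel_size_mm": stack.pixel_size,
        "slice_spacing_mm": stack.slice_spacing,
        "contours": [c.points.tolist() for c in stack.contours],
    }
    Path(path).write_text(json.dumps(payload))


def load_contours_json(path) -> ContourStack:
    payload = json.loads(Path(path).read_text())
    contours = [SliceContour(points=np.array(pts),
                             pixel_size=payload["pixel_size_mm"])
                for pts in payload["contours"]]
    return ContourStack(contours=contours,
                        slice_spacing=payload["slice_spacing_mm"],
                        pixel_size=payload["pixel_size_mm"])


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def save_mesh(path, mesh: SurfaceMesh) -> None:
    """STL or PLY by extension (geometry only; rings are recoverable as
    boundary loops)."""
    tm = mesh.as_trimesh()
    tm.export(str(path))


def load_mesh(path) -> SurfaceMesh:
    """Load STL/PLY and relabel the two boundary loops as proximal (lower
    mean axial coordinate) and distal rings."""
    tm = trimesh.load(str(path), force="mesh", process=False)
    tm.merge_vertices()  # STL stores a triangle soup
    mesh = SurfaceMesh(vertices=np.asarray(tm.vertices),
                       triangles=np.asarray(tm.faces))
    edges = np.sort(mesh.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2),
                    axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = uniq[counts == 1]
    if len(boundary_edges):
        import networkx as nx

        g = nx.Graph(boundary_edges.tolist())
        loops = [np.array(sorted(c), dtype=np.int64)
                 for c in nx.connected_components(g)]
        if len(loops) != 2:
            raise ValueError(
                f"expected an open tube with 2 boundary loops, found "
                f"{len(loops)}")
        loops.sort(key=lambda ring: mesh.vertices[ring][:, 2].mean())
        mesh.proximal_ring, mesh.distal_ring = loops
    return mesh


_STRESS_ARRAYS = ("sigma11", "sigma12", "sigma22",
                  "principal_1", "principal_2")


def _stress_cell_arrays(field: StressField) -> dict[str, np.ndarray]:
    return {
        "sigma11": field.sigma[:, 0],
        "sigma12": field.sigma[:, 1],
        "sigma22": field.sigma[:, 2],
        "principal_1": field.principal_1,
        "principal_2": field.principal_2,
    }


def save_stress_vtk(path, mesh: SurfaceMesh, field: StressField) -> None:
    """ASCII legacy VTK PolyData with per-cell stress scalars (N/cm^2)."""
    arrays = _stress_cell_arrays(field)
    lines = [
        "# vtk DataFile Version 3.0",
        "membrane wall stress (N/cm^2)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{c:.9g}" for c in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in mesh.triangles]
    lines.append(f"CELL_DATA {mesh.n_triangles}")
    for name, values in arrays.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")


def save_stress_vtu(path, mesh: SurfaceMesh, field: StressField) -> None:
    """ASCII XML VTU UnstructuredGrid with per-cell stress arrays."""
    arrays = _stress_cell_arrays(field)
    V, F = mesh.n_vertices, mesh.n_triangles
    pts = " ".join(f"{c:.9g}" for v in mesh.vertices for c in v)
    conn = " ".join(str(i) for t in mesh.triangles for i in t)
    offsets = " ".join(str(3 * (i + 1)) for i in range(F))
    types = " ".join("5" for _ in range(F))  # VTK_TRIANGLE
    cell_data = "\n".join(
        f'        <DataArray type="Float64" Name="{name}" '
        f'format="ascii"> {" ".join(f"{v:.9g}" for v in values)} '
        "</DataArray>"
        for name, values in arrays.items())
    Path(path).write_text(f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
  <UnstructuredGrid>
    <Piece NumberOfPoints="{V}" NumberOfCells="{F}">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">
          {pts}
        </DataArray>
      </Points>
      <Cells>
        <DataArray type="Int64" Name="connectivity" format="ascii">
          {conn}
        </DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">
          {offsets}
        </DataArray>
        <DataArray type="UInt8" Name="types" format="ascii">
          {types}
        </DataArray>
      </Cells>
      <CellData>
{cell_data}
      </CellData>
    </Piece>
  </UnstructuredGrid>
</VTKFile>
""")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def save_load_case(path, load: LoadCase) -> None:
    Path(path).write_text(yaml.safe_dump({
        "pressure_mmHg": load.pressure_mmHg,
        "thickness_mm": load.thickness_mm,
    }))


def load_load_case(path) -> LoadCase:
    data = yaml.safe_load(Path(path).read_text())
    return LoadCase(pressure_mmHg=float(data["pressure_mmHg"]),
                    thickness_mm=float(data["thickness_mm"]))


def save_yaml(path, payload: dict) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
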