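"""File interchange: NIfTI image stacks with JSON sidecars, outline CSVs,
legacy-VTK meshes and JSON run records."""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .geometry import TetMesh
from .synthetic import AxialOutlineStack, WaveField


def _affine(pixel_spacing: float, slice_spacing: float) -> np.ndarray:
    # array axes (slice, y, x) -> world (x, y, z) in mm for NIfTI convention
    aff = np.diag([pixel_spacing * 1e3, pixel_spacing * 1e3,
                   slice_spacing * 1e3, 1.0])
    return aff


def save_wavefield(path, wave: WaveField, slice_spacing: float = 0.01) -> None:
    """Write a wave stack as a real/imaginary NIfTI pair + JSON sidecar."""
    import nibabel as nib

    path = pathlib.Path(path)
    u = wave.complex_displacement
    vol = np.stack([u.real, u.imag], axis=-1)  # (ns, ny, nx, 2)
    img = nib.Nifti1Image(np.transpose(vol, (2, 1, 0, 3)),
                          _affine(wave.pixel_spacing, slice_spacing))
    nib.save(img, str(path.with_suffix(".nii")))
    sidecar = {"frequency_hz": wave.frequency,
               "pixel_spacing_m": wave.pixel_spacing,
               "slice_spacing_m": slice_spacing,
               "fov_m": wave.fov,
               "assumed_density_kg_m3": wave.assumed_density}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_wavefield(path) -> WaveField:
    import nibabel as nib

    path = pathlib.Path(path)
    img = nib.load(str(path.with_suffix(".nii")))
    data = np.asarray(img.dataobj)
    u = np.transpose(data[..., 0] + 1j * data[..., 1], (2, 1, 0))
    meta = json.loads(path.with_suffix(".json").read_text())
    return WaveField(complex_displacement=u, frequency=meta["frequency_hz"],
                     pixel_spacing=meta["pixel_spacing_m"],
                     fov=meta["fov_m"],
                     assumed_density=meta["assumed_density_kg_m3"])


def save_image_stack(path, values: np.ndarray, pixel_spacing: float,
                     slice_spacing: float, meta: dict | None = None) -> None:
    """Write a (n_slices, ny, nx) stack as NIfTI plus optional sidecar."""
    import nibabel as nib

    path = pathlib.Path(path)
    img = nib.Nifti1Image(np.transpose(np.asarray(values, float), (2, 1, 0)),
                          _affine(pixel_spacing, slice_spacing))
    nib.save(img, str(path.with_suffix(".nii")))
    if meta:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_image_stack(path) -> tuple[np.ndarray, dict]:
    import nibabel as nib

    path = pathlib.Path(path)
    img = nib.load(str(path.with_suffix(".nii")))
    values = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, meta


def save_outlines(path, stack: AxialOutlineStack) -> None:
    """CSV with columns slice_id, ring (outer|inner), vertex_id, x, y, z."""
    rows = []
    for ring_name, polys in (("outer", stack.outlines),
                             ("inner", stack.inner_outlines)):
        for k, poly in enumerate(polys):
            for j, (x, y) in enumerate(poly):
                rows.append((k, ring_name, j, x, y, stack.z[k]))
    pd.DataFrame(rows, columns=["slice_id", "ring", "vertex_id",
                                "x", "y", "z"]).to_csv(path, index=False)


def load_outlines(path) -> AxialOutlineStack:
    df = pd.read_csv(path)
    outer, inner, z = [], [], []
    for k, g in df[df.ring == "outer"].groupby("slice_id"):
        g = g.sort_values("vertex_id")
        outer.append(g[["x", "y"]].to_numpy())
        z.append(float(g.z.iloc[0]))
    for _, g in df[df.ring == "inner"].groupby("slice_id"):
        inner.append(g.sort_values("vertex_id")[["x", "y"]].to_numpy())
    return AxialOutlineStack(outlines=outer, inner_outlines=inner,
                             z=np.asarray(z))


def save_mesh_vtk(path, mesh: TetMesh,
                  point_data: dict[str, np.ndarray] | None = None,
                  cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with quadratic tetrahedra."""
    lines = ["# vtk DataFile Version 3.0", "lungmech mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    n_el = mesh.n_elements
    lines.append(f"CELLS {n_el} {n_el * 11}")
    for el in mesh.elements:
        lines.append("10 " + " ".join(str(i) for i in el))
    lines.append(f"CELL_TYPES {n_el}")
    lines.extend(["24"] * n_el)  # VTK_QUADRATIC_TETRA

    cell_data = dict(cell_data or {})
    cell_data.setdefault("domain", mesh.domain)
    lines.append(f"CELL_DATA {n_el}")
    for name, arr in cell_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in np.asarray(arr, float))
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.10g}" for v in np.asarray(arr, float))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
    # face labels travel in a JSON sidecar (legacy VTK has no face sets)
    sidecar = {name: faces.tolist()
               for name, faces in mesh.face_labels.items()}
    sidecar["n_vertices"] = mesh.n_vertices
    pathlib.Path(str(path) + ".labels.json").write_text(json.dumps(sidecar))


def load_mesh_vtk(path) -> tuple[TetMesh, dict[str, np.ndarray]]:
    """Read back a mesh written by :func:`save_mesh_vtk`."""
    tokens = pathlib.Path(path).read_text().split("\n")
    i = tokens.index("DATASET UNSTRUCTURED_GRID") + 1
    n_pts = int(tokens[i].split()[1])
    nodes = np.array([[float(v) for v in tokens[i + 1 + k].split()]
                      for k in range(n_pts)])
    i = i + 1 + n_pts
    n_el = int(tokens[i].split()[1])
    elements = np.array([[int(v) for v in tokens[i + 1 + k].split()[1:]]
                         for k in range(n_el)], dtype=np.int64)
    # scan for data sections
    point_data = {}
    domain = np.zeros(n_el, dtype=np.int8)
    j = i + 1 + n_el
    section = None
    while j < len(tokens):
        t = tokens[j]
        if t.startswith("CELL_DATA"):
            section = "cell"
        elif t.startswith("POINT_DATA"):
            section = "point"
        elif t.startswith("SCALARS"):
            name = t.split()[1]
            count = n_el if section == "cell" else n_pts
            vals = np.array([float(tokens[j + 2 + k]) for k in range(count)])
            if section == "cell" and name == "domain":
                domain = vals.astype(np.int8)
            elif section == "point":
                point_data[name] = vals
            j += count + 1
        j += 1

    labels_path = pathlib.Path(str(path) + ".labels.json")
    face_labels = {}
    n_vertices = int(elements[:, :4].max()) + 1
    if labels_path.exists():
        raw = json.loads(labels_path.read_text())
        n_vertices = raw.pop("n_vertices", n_vertices)
        face_labels = {k: np.asarray(v, dtype=np.int64)
                       for k, v in raw.items()}
    mesh = TetMesh(nodes=nodes, elements=elements, n_vertices=n_vertices,
                   domain=domain, face_labels=face_labels)
    return mesh, point_data
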