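"""First-principal strain and spatial strain-gradient analysis.

The deformation metric is the first principal strain eps_p1 — the largest
eigenvalue of the Green-Lagrange tensor, the peak local tensile strain — and
the spatial non-uniformity metric is the strain-gradient magnitude

    |grad eps_p1| = sqrt((d eps/dx)^2 + (d eps/dy)^2 + (d eps/dz)^2),

evaluated on a nodal field recovered from element values by volume-weighted
averaging (raw inter-element jumps would otherwise dominate the statistic).
Summaries are volume-weighted over inner-domain elements at end inspiration;
the outer buffer shell is excluded.
"""

from __future__ import annotations

import numpy as np

from .geometry import TetMesh
from .fem import tet10_shape


def principal_strain(strain_tensors: np.ndarray,
                     symmetry_tol: float = 1e-8) -> np.ndarray:
    """Largest eigenvalue of each (symmetric) strain tensor.

    Accepts an array (..., 3, 3); rejects tensors whose skew part exceeds
    ``symmetry_tol`` relative to their magnitude.
    """
    t = np.asarray(strain_tensors, dtype=float)
    skew = np.abs(t - np.swapaxes(t, -1, -2)).max()
    scale = max(np.abs(t).max(), 1.0e-300)
    if skew > symmetry_tol * max(scale, 1.0):
        raise ValueError("strain tensors are not symmetric")
    sym = 0.5 * (t + np.swapaxes(t, -1, -2))
    return np.linalg.eigvalsh(sym)[..., -1]


def element_to_nodal(mesh: TetMesh, element_values: np.ndarray) -> np.ndarray:
    """Volume-weighted recovery of a nodal field from per-element values."""
    vols = mesh.element_volumes()
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    w = np.repeat(vols[:, None], 10, axis=1).reshape(-1)
    idx = mesh.elements.reshape(-1)
    np.add.at(num, idx, w * np.repeat(element_values[:, None], 10,
                                      axis=1).reshape(-1))
    np.add.at(den, idx, w)
    out = np.zeros(mesh.n_nodes)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def strain_gradient(nodal_field: np.ndarray, mesh: TetMesh,
                    degenerate_rel_volume: float = 1e-12
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-element gradient magnitude of a continuous nodal field.

    The gradient uses the quadratic shape-function derivatives at the
    element centroid, so linear fields are reproduced exactly.  Degenerate
    elements (relative volume below the floor) are excluded; the second
    return value is their mask.
    """
    vols = mesh.element_volumes()
    excluded = vols <= degenerate_rel_volume * np.abs(vols).max()

    x = mesh.corner_coords()
    jac = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0],
                    x[:, 3] - x[:, 0]], axis=-1)
    if excluded.any():
        jac = jac.copy()
        jac[excluded] = np.eye(3)
    inv = np.linalg.inv(jac)
    _, dN = tet10_shape(np.array([[0.25, 0.25, 0.25]]))
    dndx = np.einsum("ak,eki->eai", dN[0], inv)
    vals = nodal_field[mesh.elements]
    grad = np.einsum("ea,eai->ei", vals, dndx)
    mag = np.linalg.norm(grad, axis=1)
    mag[excluded] = np.nan
    return mag, excluded


def weighted_quantile(values: np.ndarray, q: float | np.ndarray,
                      weights: np.ndarray | None = None) -> float | np.ndarray:
    """Quantile with optional weights.

    Unweighted input uses linear interpolation between order statistics
    (the fixed convention throughout the package); weighted input
    interpolates the normalised cumulative weight at bin midpoints.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        return np.quantile(values, q)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return np.interp(q, cw, v)


def segregate_by_roi(values: np.ndarray, labels: np.ndarray,
                     volumes: np.ndarray, bins: int = 50
                     ) -> dict[str, dict]:
    """Partition element values by ROI label with volume weights.

    Returns, per label, the value list, weights, volume-weighted median/IQR
    and a histogram (volume-weighted densities).  Empty labels are reported
    as missing.  Label volumes partition the labelled volume exactly.
    """
    values = np.asarray(values, dtype=float)
    out = {}
    for name in np.unique(labels):
        sel = (labels == name) & np.isfinite(values)
        if not sel.any():
            out[str(name)] = {"missing": True}
            continue
        v, w = values[sel], volumes[sel]
        med = weighted_quantile(v, 0.5, w)
        q1, q3 = weighted_quantile(v, [0.25, 0.75], w)
        hist, edges = np.histogram(v, bins=bins, weights=w, density=True)
        out[str(name)] = {
            "missing": False, "values": v, "weights": w,
            "median": float(med), "iqr": float(q3 - q1),
            "volume": float(w.sum()),
            "histogram": hist, "bin_edges": edges,
        }
    return out


def label_elements_by_inclusion(mesh: TetMesh,
                                center: tuple[float, float, float] | None,
                                radius: float = 0.0) -> np.ndarray:
    """ROI labels per element: consolidated (inside the inclusion sphere),
    non-consolidated (rest of the inner domain), none (outer shell)."""
    labels = np.where(mesh.domain == 0, "non-consolidated", "none").astype(object)
    if center is not None and radius > 0:
        cen = mesh.element_centroids()
        inside = np.linalg.norm(cen - np.asarray(center), axis=1) <= radius
        labels[inside & (mesh.domain == 0)] = "consolidated"
    return labels
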