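"""Synthetic phantoms for the MRE/FEM lung pipeline.

Every downstream stage (wave inversion, density fitting, lofting, meshing,
inflation simulation) is exercised on data produced here, so the generators
emulate the statistical and physical structure the analysis assumes:

* piecewise-smooth heterogeneous shear-stiffness fields (log-normal marginal,
  squared-exponential spatial correlation), optionally with a stiff
  "consolidated" spherical inclusion as seen in cystic fibrosis;
* traveling 50 Hz shear waves over those fields, sampled at equally spaced
  phase offsets within one vibration period;
* multi-echo gradient-echo magnitude images with mono-exponential T2* decay
  and a constant-signal reference water-phantom region;
* stacked axial lung outlines (outer wall plus inward-offset inner outline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Inclusion:
    """Spherical stiff inclusion (consolidated region) in field coordinates."""

    center: tuple[float, float, float]  # (x, y, z) in m
    radius: float                       # m
    modulus: float                      # Pa


@dataclass(frozen=True)
class StiffnessFieldSpec:
    """Recipe for a heterogeneous per-slice shear-stiffness field.

    ``grid_shape`` is (n_slices, ny, nx).  The pixel grid is centred on the
    origin in-plane; slice k sits at z = k * slice_spacing.
    """

    grid_shape: tuple[int, int, int]
    pixel_spacing: float            # m, in-plane (isotropic)
    slice_spacing: float            # m
    base_modulus: float             # Pa
    heterogeneity_cv: float = 0.0   # coefficient of variation of the field
    correlation_length: float = 0.03  # m, squared-exponential kernel
    inclusion: Inclusion | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_modulus <= 0:
            raise ValueError("base_modulus must be positive")
        if self.heterogeneity_cv < 0:
            raise ValueError("heterogeneity_cv must be >= 0")
        if self.pixel_spacing <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.inclusion is not None and self.inclusion.radius < 0:
            raise ValueError("inclusion radius must be >= 0")


@dataclass
class StiffnessField:
    """Generated stiffness maps plus the label map of the inclusion ROI."""

    values: np.ndarray        # (n_slices, ny, nx) Pa
    roi_labels: np.ndarray    # int, 0 = background, 1 = inclusion
    spec: StiffnessFieldSpec

    @property
    def slice_z(self) -> np.ndarray:
        n = self.values.shape[0]
        return np.arange(n) * self.spec.slice_spacing

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (x along axis 2, y along axis 1), centred."""
        _, ny, nx = self.values.shape
        dx = self.spec.pixel_spacing
        x = (np.arange(nx) - (nx - 1) / 2.0) * dx
        y = (np.arange(ny) - (ny - 1) / 2.0) * dx
        return x, y


@dataclass
class WaveField:
    """Per-slice complex harmonic displacement images.

    The physical displacement is u(x, t) = Re[U(x) exp(i omega t)] with
    omega = 2 pi frequency.
    """

    complex_displacement: np.ndarray  # (n_slices, ny, nx) complex, m
    frequency: float                  # Hz
    pixel_spacing: float              # m
    fov: float                        # m (in-plane, square)
    assumed_density: float            # kg/m^3 used when synthesizing

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not np.all(np.isfinite(self.complex_displacement)):
            raise ValueError("wave field contains non-finite values")


@dataclass
class MultiTEScan:
    """Multi-echo magnitude images with a reference phantom region."""

    magnitude_images: np.ndarray   # (n_echoes, ny, nx), signal units
    echo_times: np.ndarray         # ms, strictly increasing
    phantom_roi: np.ndarray        # bool mask of the reference phantom
    tr_correction_CR: float = 1.873

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echo_times.size < 2:
            raise ValueError("need at least two echo times")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(self.magnitude_images < 0):
            raise ValueError("magnitude images must be non-negative")


@dataclass
class AxialOutlineStack:
    """Closed planar lung outlines (outer and inner) stacked along z."""

    outlines: list[np.ndarray]        # each (n_vertices, 2) in m, closed implied
    inner_outlines: list[np.ndarray]  # same structure, strictly inside
    z: np.ndarray                     # m, strictly increasing

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.outlines) < 2:
            raise ValueError("need at least two slices")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z positions must be strictly increasing")
        if len(self.inner_outlines) != len(self.outlines):
            raise ValueError("inner and outer outline counts differ")


# --------------------------------------------------------------------------
# stiffness field
# --------------------------------------------------------------------------

def generate_stiffness_field(spec: StiffnessFieldSpec) -> StiffnessField:
    """Sample a log-normal Gaussian-random-field stiffness map.

    log G carries a zero-mean correlated Gaussian perturbation scaled so the
    coefficient of variation of G matches ``spec.heterogeneity_cv``; the
    median of the field equals ``base_modulus`` up to the log-normal mean
    correction.  An optional stiff inclusion multiplies the field by
    ``inclusion.modulus / base_modulus`` inside a sphere, with the edge
    smoothed over one correlation length.
    """
    n_slices, ny, nx = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    log_g = np.full(spec.grid_shape, np.log(spec.base_modulus))
    if spec.heterogeneity_cv > 0:
        sigma_px = spec.correlation_length / spec.pixel_spacing / np.sqrt(2.0)
        sigma_sl = spec.correlation_length / spec.slice_spacing / np.sqrt(2.0)
        noise = rng.standard_normal(spec.grid_shape)
        z = ndimage.gaussian_filter(noise, sigma=(sigma_sl, sigma_px, sigma_px),
                                    mode="wrap")
        z = (z - z.mean()) / z.std()
        s = np.sqrt(np.log1p(spec.heterogeneity_cv ** 2))
        log_g += s * z - 0.5 * s ** 2

    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    if spec.inclusion is not None and spec.inclusion.radius > 0:
        inc = spec.inclusion
        dx = spec.pixel_spacing
        x = (np.arange(nx) - (nx - 1) / 2.0) * dx
        y = (np.arange(ny) - (ny - 1) / 2.0) * dx
        z_sl = np.arange(n_slices) * spec.slice_spacing
        r = np.sqrt((x[None, None, :] - inc.center[0]) ** 2
                    + (y[None, :, None] - inc.center[1]) ** 2
                    + (z_sl[:, None, None] - inc.center[2]) ** 2)
        # smoothstep from 1 inside to 0 outside over one correlation length,
        # capped at half the radius so small inclusions keep a full-contrast
        # core
        ell = max(min(spec.correlation_length, inc.radius / 2.0), dx)
        t = np.clip((r - (inc.radius - ell / 2.0)) / ell, 0.0, 1.0)
        w = 1.0 - t * t * (3.0 - 2.0 * t)
        # consolidated tissue is dense and homogeneous: the inclusion damps
        # the background heterogeneity as it imposes its own modulus
        log_g = ((1.0 - w) * log_g
                 + w * (np.log(spec.base_modulus)
                        + np.log(inc.modulus / spec.base_modulus)))
        # the ROI marks fully consolidated tissue (the dense core seen on
        # magnitude images); the smoothed rim is only partially consolidated
        labels[r <= inc.radius - ell / 2.0] = 1

    return StiffnessField(values=np.exp(log_g), roi_labels=labels, spec=spec)


def consolidated_core_radius(spec: StiffnessFieldSpec) -> float:
    """Radius of the fully consolidated core the ROI labels mark."""
    if spec.inclusion is None:
        return 0.0
    ell = max(min(spec.correlation_length, spec.inclusion.radius / 2.0),
              spec.pixel_spacing)
    return spec.inclusion.radius - ell / 2.0


# --------------------------------------------------------------------------
# harmonic shear waves
# --------------------------------------------------------------------------

_COMPASS = {
    (1, 0), (0, 1), (-1, 0), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1),
}


def _discrete_wavenumber(g: np.ndarray, rho: float, omega: float,
                         dx: float, diagonal: bool) -> np.ndarray:
    """Wavenumber of the plane wave satisfying the discrete 5-point
    Helmholtz relation rho omega^2 u = -G lap_h u for local modulus G.

    This is the dispersion-corrected analogue of k = omega sqrt(rho/G); the
    correction is O((k dx)^2) and keeps the synthesized field consistent
    with the finite-difference operator the inversion applies.
    """
    arg = rho * omega ** 2 * dx ** 2 / ((4.0 if diagonal else 2.0) * g)
    if np.any(arg >= 2):
        raise ValueError("wavelength under-resolved by the pixel grid")
    if diagonal:
        return np.sqrt(2.0) * np.arccos(1.0 - arg) / dx
    return np.arccos(1.0 - arg) / dx


def _ray_phase(slowness: np.ndarray, direction: tuple[int, int],
               dx: float, omega: float) -> np.ndarray:
    """Accumulated phase omega * integral of slowness along straight rays.

    ``direction`` is one of the 8 compass steps (dx_step, dy_step) in pixel
    units; rays then coincide with grid rows, columns or diagonals, and the
    line integral is an exact trapezoidal cumulative sum along each ray.
    """
    sx, sy = direction
    s = slowness
    flip_x = sx < 0
    flip_y = sy < 0
    if flip_x:
        s = s[:, ::-1]
    if flip_y:
        s = s[::-1, :]
    ax, ay = abs(sx), abs(sy)

    if ax and ay:  # diagonal, step length sqrt(2) dx
        step = np.sqrt(2.0) * dx
        phi = np.zeros_like(s)
        ny, nx = s.shape
        for off in range(-(ny - 1), nx):
            d = np.diagonal(s, offset=off)
            inc = np.concatenate(([0.0], 0.5 * (d[:-1] + d[1:]) * step))
            vals = np.cumsum(inc)
            iy = np.arange(len(d)) + max(-off, 0)
            ix = np.arange(len(d)) + max(off, 0)
            phi[iy, ix] = vals
    else:
        axis = 1 if ax else 0
        step = dx
        s_m = np.moveaxis(s, axis, -1)
        inc = np.concatenate(
            [np.zeros(s_m.shape[:-1] + (1,)),
             0.5 * (s_m[..., :-1] + s_m[..., 1:]) * step], axis=-1)
        phi = np.moveaxis(np.cumsum(inc, axis=-1), -1, axis)

    if flip_x:
        phi = phi[:, ::-1]
    if flip_y:
        phi = phi[::-1, :]
    return omega * phi


def _solve_helmholtz_slice(g: np.ndarray, rho: float, omega: float,
                           dx: float, u_inc: np.ndarray) -> np.ndarray:
    """Solve rho omega^2 u + div(G grad u) = 0 on one slice.

    Flux-form 5-point finite differences with half-edge moduli; the
    incident wave is imposed as a Dirichlet condition on every boundary
    pixel (the directional filter downstream is responsible for separating
    any boundary-induced reflections, as it is for in vivo reflections).
    """
    import scipy.sparse as sp
    from scipy.sparse.linalg import splu

    ny, nx = g.shape
    idx = np.arange(ny * nx).reshape(ny, nx)
    interior = np.zeros((ny, nx), dtype=bool)
    interior[1:-1, 1:-1] = True

    gx = 0.5 * (g[:, 1:] + g[:, :-1])   # between (i,j) and (i,j+1)
    gy = 0.5 * (g[1:, :] + g[:-1, :])

    ii, jj = np.nonzero(interior)
    rows, cols, vals = [], [], []
    center = idx[ii, jj]
    diag = (rho * omega ** 2
            - (gx[ii, jj - 1] + gx[ii, jj] + gy[ii - 1, jj] + gy[ii, jj])
            / dx ** 2)
    for r, c, v in ((center, center, diag),
                    (center, idx[ii, jj + 1], gx[ii, jj] / dx ** 2),
                    (center, idx[ii, jj - 1], gx[ii, jj - 1] / dx ** 2),
                    (center, idx[ii + 1, jj], gy[ii, jj] / dx ** 2),
                    (center, idx[ii - 1, jj], gy[ii - 1, jj] / dx ** 2)):
        rows.append(r)
        cols.append(c)
        vals.append(np.broadcast_to(v, r.shape).astype(complex))
    bi, bj = np.nonzero(~interior)
    rows.append(idx[bi, bj])
    cols.append(idx[bi, bj])
    vals.append(np.ones(bi.size, dtype=complex))

    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(ny * nx, ny * nx)).tocsc()
    rhs = np.zeros(ny * nx, dtype=complex)
    rhs[idx[bi, bj]] = u_inc[bi, bj]
    return splu(A).solve(rhs).reshape(ny, nx)


def synthesize_wavefield(stiffness: StiffnessField | np.ndarray,
                         frequency: float,
                         density: float,
                         directions: Sequence[tuple[int, int]] = ((1, 0),),
                         noise_sd: float = 0.0,
                         snr_db: float | None = None,
                         amplitude: float = 1e-5,
                         pixel_spacing: float | None = None,
                         method: str = "helmholtz",
                         relative_signal: np.ndarray | None = None,
                         seed: int = 0) -> WaveField:
    """Forward-model traveling shear waves over a stiffness field.

    The default ``helmholtz`` method solves the heterogeneous scalar wave
    equation div(G grad u) + rho omega^2 u = 0 per slice with the incident
    plane wave of each requested compass direction imposed on the boundary,
    so the field satisfies rho omega^2 u = -G laplacian(u) exactly (in the
    discrete sense) wherever G is locally constant, with local wavelength
    sqrt(G/rho)/f up to the finite-difference dispersion correction.  The
    cheaper ``ray`` method accumulates eikonal phase along straight rays
    and ignores diffraction.  Waves from the requested directions
    superpose; complex Gaussian noise is added either at a fixed standard
    deviation or at a target SNR in dB (``snr_db`` wins when both are
    given, mirroring the 20 dB default study condition).
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    if isinstance(stiffness, StiffnessField):
        g = stiffness.values
        dx = stiffness.spec.pixel_spacing
    else:
        g = np.asarray(stiffness, dtype=float)
        if g.ndim == 2:
            g = g[None]
        if pixel_spacing is None:
            raise ValueError("pixel_spacing required for raw arrays")
        dx = pixel_spacing
    if np.any(g <= 0):
        raise ValueError("stiffness must be positive")
    for d in directions:
        if (int(np.sign(d[0])), int(np.sign(d[1]))) not in _COMPASS:
            raise ValueError(f"direction {d} is not one of the 8 compass steps")

    omega = 2 * np.pi * frequency
    amp = amplitude / len(directions)
    u = np.zeros_like(g, dtype=complex)
    for d in directions:
        d = (int(np.sign(d[0])), int(np.sign(d[1])))
        diagonal = d[0] != 0 and d[1] != 0
        for k in range(g.shape[0]):
            # dispersion-corrected slowness keeps the incident phase
            # consistent with the discrete operator
            s_eff = _discrete_wavenumber(g[k], density, omega, dx,
                                         diagonal) / omega
            u_inc = amp * np.exp(-1j * _ray_phase(s_eff, d, dx, omega))
            if method == "helmholtz":
                u[k] += _solve_helmholtz_slice(g[k], density, omega, dx,
                                               u_inc)
            elif method == "ray":
                u[k] += u_inc
            else:
                raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    if snr_db is not None:
        rms = np.sqrt(np.mean(np.abs(u) ** 2))
        noise_sd = rms * 10.0 ** (-snr_db / 20.0)
    if np.any(noise_sd > 0):
        sd = np.asarray(noise_sd, dtype=float)
        if relative_signal is not None:
            # phase-derived displacement noise scales inversely with the
            # magnitude-image signal (dense tissue yields quieter waves)
            sd = sd / np.asarray(relative_signal, dtype=float)
        u = u + sd / np.sqrt(2.0) * (
            rng.standard_normal(u.shape) + 1j * rng.standard_normal(u.shape))

    nx = g.shape[-1]
    return WaveField(complex_displacement=u, frequency=frequency,
                     pixel_spacing=dx, fov=nx * dx, assumed_density=density)


def sample_phase_offsets(wave: WaveField, n_offsets: int = 4) -> np.ndarray:
    """Real displacement snapshots at ``n_offsets`` equally spaced phases.

    Returns an array of shape (n_offsets,) + wave shape with
    u_k = Re[U exp(2 pi i k / n_offsets)], mirroring the 4 phase offsets of
    the MRE acquisition.
    """
    if n_offsets < 3:
        raise ValueError("need at least 3 phase offsets")
    u = wave.complex_displacement
    phases = np.exp(2j * np.pi * np.arange(n_offsets) / n_offsets)
    return np.real(u[None] * phases[(slice(None),) + (None,) * u.ndim])


# --------------------------------------------------------------------------
# multi-echo density scan
# --------------------------------------------------------------------------

def synthesize_density_scan(i0_map: np.ndarray,
                            t2star_map_ms: np.ndarray | float,
                            echo_times_ms: Sequence[float],
                            phantom_signal: float,
                            cr: float = 1.873,
                            phantom_roi: np.ndarray | None = None,
                            noise_sd: float = 0.0,
                            noise_model: str = "rician",
                            seed: int = 0) -> MultiTEScan:
    """Mono-exponential multi-TE magnitude images, S = I0 exp(-TE/T2*).

    The phantom ROI (default: an 8x8 block in the image corner) carries the
    constant phantom signal at every echo — the doped-water reference has a
    long decay constant relative to the sampled TEs.
    """
    echo_times = np.asarray(echo_times_ms, dtype=float)
    if echo_times.size == 0:
        raise ValueError("echo time list is empty")
    i0 = np.asarray(i0_map, dtype=float)
    t2 = np.broadcast_to(np.asarray(t2star_map_ms, dtype=float), i0.shape)
    if np.any(t2 <= 0):
        raise ValueError("T2* must be positive")
    if np.any(i0 < 0):
        raise ValueError("I0 must be non-negative")

    if phantom_roi is None:
        phantom_roi = np.zeros(i0.shape, dtype=bool)
        phantom_roi[1:9, 1:9] = True

    images = i0[None] * np.exp(-echo_times[:, None, None] / t2[None])
    images = np.where(phantom_roi[None], phantom_signal, images)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            images = np.abs(images + noise_sd * rng.standard_normal(images.shape)
                            + 1j * noise_sd * rng.standard_normal(images.shape))
        elif noise_model == "gaussian":
            images = np.clip(
                images + noise_sd * rng.standard_normal(images.shape), 0, None)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")

    return MultiTEScan(magnitude_images=images, echo_times=echo_times,
                       phantom_roi=phantom_roi, tr_correction_CR=cr)


# --------------------------------------------------------------------------
# axial lung outlines
# --------------------------------------------------------------------------

def generate_lung_outlines(n_slices: int = 5,
                           base_radius: float = 0.05,
                           inner_offset: float = 0.005,
                           slice_spacing: float = 0.01,
                           center: tuple[float, float] = (0.0, 0.0),
                           z0: float = 0.0,
                           irregularity: float = 0.08,
                           taper: float = 0.1,
                           n_vertices: int = 64,
                           seed: int = 0) -> AxialOutlineStack:
    """Star-shaped axial outlines with a uniform inward-offset inner outline.

    The boundary radius r(theta, z) carries a few low-order Fourier modes
    (amplitude ``irregularity``) that drift smoothly along z, plus a mild
    parabolic taper toward the apical and basal slices — a cartoon of the
    lung-section outlines traced on axial scans.  The inner outline, standing
    in for the cropped MRE stiffness map, is the radial offset
    r(theta, z) - inner_offset.
    """
    if n_slices < 2:
        raise ValueError("need at least two slices")
    if inner_offset < 0:
        raise ValueError("inner_offset must be >= 0")
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    z = z0 + slice_spacing * np.arange(n_slices)
    zc = z.mean()
    half = max((z[-1] - z[0]) / 2.0, slice_spacing)

    modes = [2, 3, 4, 5]
    amp0 = rng.uniform(0.3, 1.0, len(modes)) * irregularity / np.arange(2, 6)
    phase0 = rng.uniform(0, 2 * np.pi, len(modes))
    drift = rng.uniform(-0.5, 0.5, len(modes)) * np.pi

    outer, inner = [], []
    for k in range(n_slices):
        s = (z[k] - zc) / half
        r = np.full(n_vertices, base_radius * (1.0 - taper * s ** 2))
        for m, a, p, dph in zip(modes, amp0, phase0, drift):
            r += base_radius * a * np.cos(m * theta + p + dph * s)
        if np.min(r) - inner_offset <= 0.1 * base_radius:
            raise ValueError("inner offset exceeds the local outline radius")
        pts = np.column_stack([center[0] + r * np.cos(theta),
                               center[1] + r * np.sin(theta)])
        pts_in = np.column_stack([center[0] + (r - inner_offset) * np.cos(theta),
                                  center[1] + (r - inner_offset) * np.sin(theta)])
        outer.append(pts)
        inner.append(pts_in)

    return AxialOutlineStack(outlines=outer, inner_outlines=inner, z=z)
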