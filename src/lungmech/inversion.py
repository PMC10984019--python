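"""Shear-stiffness recovery from harmonic wave images.

Pipeline: extract the first temporal harmonic from phase-offset snapshots,
separate propagation directions with a radial-Butterworth / angular-window
bandpass in the 2D Fourier domain, invert the local Helmholtz relation
rho omega^2 u = -G laplacian(u) per direction, combine directions by
amplitude-squared weighting, then median-filter and trim above the 95th
percentile before summarising median/IQR per region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DirectionalFilterSpec:
    """Radial bandpass (in waves per field of view) plus angular windows.

    ``n_directions`` smooth angular windows, centred on equally spaced
    directions, partition the forward half-planes: the truncated
    cos^angular_exponent windows are normalised to sum to one wherever any is
    non-zero, so the bank conserves in-band energy and a pure plane wave
    lands dominantly in one bin.
    """

    n_directions: int = 8
    butterworth_order: int = 4
    band: tuple[float, float] = (2.0, 40.0)  # waves per FOV
    angular_exponent: int = 16

    def __post_init__(self) -> None:
        if self.n_directions < 1:
            raise ValueError("need at least one direction")
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise ValueError("band must satisfy 0 <= low < high")


@dataclass
class StiffnessMap:
    """Per-pixel shear stiffness with a validity mask.

    ``roi`` is the lung region the summaries are restricted to;
    ``roi_labels`` optionally marks consolidated (1) vs non-consolidated (0)
    pixels inside the ROI.
    """

    stiffness: np.ndarray           # (n_slices, ny, nx) Pa
    validity_mask: np.ndarray       # bool, pixels carrying a usable estimate
    pixel_spacing: float            # m
    assumed_density: float          # kg/m^3 used in the inversion
    roi: np.ndarray | None = None   # bool lung mask
    roi_labels: np.ndarray | None = None
    density_corrected: bool = False

    def valid_in_roi(self) -> np.ndarray:
        mask = self.validity_mask
        if self.roi is not None:
            mask = mask & self.roi
        return mask


def extract_harmonic(phase_offset_images: np.ndarray,
                     n_offsets: int | None = None) -> np.ndarray:
    """First temporal Fourier harmonic of equally spaced phase offsets.

    For samples u_k = Re[U exp(2 pi i k / N)] the 2/N-scaled DFT returns U
    exactly for any N >= 3 (below that the harmonic is under-determined).
    """
    images = np.asarray(phase_offset_images, dtype=float)
    n = images.shape[0] if n_offsets is None else n_offsets
    if n < 3:
        raise ValueError("need at least 3 phase offsets")
    if images.shape[0] != n:
        raise ValueError("n_offsets does not match the image stack")
    k = np.arange(n)
    w = np.exp(-2j * np.pi * k / n)
    return (2.0 / n) * np.tensordot(w, images, axes=(0, 0))


def _filter_bank(shape: tuple[int, int],
                 spec: DirectionalFilterSpec) -> list[np.ndarray]:
    ny, nx = shape
    kx = np.fft.fftfreq(nx, d=1.0 / nx)          # cycles per FOV
    ky = np.fft.fftfreq(ny, d=1.0 / ny)
    kxg, kyg = np.meshgrid(kx, ky)
    kap = np.hypot(kxg, kyg)

    lo, hi = spec.band
    n2 = 2 * spec.butterworth_order
    # algebraically equivalent to 1/sqrt(1+(lo/k)^2n) but finite at k = 0
    hp = kap ** spec.butterworth_order / np.sqrt(kap ** n2 + lo ** n2)
    lp = 1.0 / np.sqrt(1.0 + (kap / hi) ** n2)
    radial = hp * lp

    # under the exp(+i omega t) temporal convention a wave propagating along
    # +d has its spatial spectrum at -k d, hence the sign flip
    theta = np.arctan2(-kyg, -kxg)
    windows = []
    for d in range(spec.n_directions):
        th_d = 2 * np.pi * d / spec.n_directions
        c = np.cos(theta - th_d)
        windows.append(np.where(c > 0, c, 0.0) ** spec.angular_exponent)
    total = np.sum(windows, axis=0)
    safe = np.where(total > 0, total, 1.0)
    return [radial * w / safe for w in windows]


def directional_filter(wave_image: np.ndarray,
                       spec: DirectionalFilterSpec = DirectionalFilterSpec(),
                       ) -> list[np.ndarray]:
    """Split a complex wave image into directional components.

    Accepts a single slice (ny, nx) or a stack (n_slices, ny, nx); the 2D
    FFT acts on the trailing two axes.  The outputs sum to the bandpassed
    input, and a pure in-band plane wave is routed almost entirely into the
    bin whose centre direction is nearest its propagation direction.
    """
    u = np.asarray(wave_image, dtype=complex)
    spectrum = np.fft.fft2(u, axes=(-2, -1))
    bank = _filter_bank(u.shape[-2:], spec)
    return [np.fft.ifft2(spectrum * h, axes=(-2, -1)) for h in bank]


def direct_inversion_2d(filtered_images: list[np.ndarray] | np.ndarray,
                        frequency: float,
                        assumed_density: float,
                        pixel_spacing: float,
                        roi: np.ndarray | None = None,
                        amplitude_floor: float = 0.02,
                        laplacian_floor: float = 1e-6) -> StiffnessMap:
    """2D algebraic (direct) Helmholtz inversion, slice by slice.

    Per directional component d, G_d = -rho omega^2 Re(u_d conj(lap u_d)) /
    |lap u_d|^2 with a 5-point finite-difference Laplacian; the combined map
    is the amplitude^2-weighted average over directions.  Pixel-direction
    pairs whose Laplacian magnitude or amplitude fall below the relative
    floors are dropped; a pixel with no surviving direction (or a
    non-positive combined estimate) is marked invalid rather than zero.
    """
    if assumed_density <= 0:
        raise ValueError("density must be positive")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if isinstance(filtered_images, np.ndarray):
        filtered_images = [filtered_images]
    if len(filtered_images) == 0:
        raise ValueError("need at least one directional image")

    omega = 2 * np.pi * frequency
    stack0 = np.asarray(filtered_images[0], dtype=complex)
    squeeze = stack0.ndim == 2

    num = np.zeros(stack0.shape if not squeeze else (1,) + stack0.shape)
    den = np.zeros_like(num)
    for comp in filtered_images:
        u = np.asarray(comp, dtype=complex)
        if squeeze:
            u = u[None]
        lap = np.empty_like(u)
        for k in range(u.shape[0]):
            lap[k] = (ndimage.laplace(u[k].real, mode="nearest")
                      + 1j * ndimage.laplace(u[k].imag, mode="nearest"))
        lap /= pixel_spacing ** 2

        lap_mag = np.abs(lap)
        amp = np.abs(u)
        valid = np.ones(u.shape, dtype=bool)
        for k in range(u.shape[0]):
            valid[k] &= lap_mag[k] >= laplacian_floor * lap_mag[k].max()
            valid[k] &= amp[k] >= amplitude_floor * amp[k].max()

        with np.errstate(invalid="ignore", divide="ignore"):
            g_d = -assumed_density * omega ** 2 * np.real(
                u * np.conj(lap)) / lap_mag ** 2
        w = np.where(valid, amp ** 2, 0.0)
        num += np.where(valid, w * np.nan_to_num(g_d), 0.0)
        den += w

    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / den
    valid_px = (den > 0) & np.isfinite(g) & (g > 0)
    g = np.where(valid_px, g, np.nan)

    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if squeeze and roi.ndim == 2:
            roi = roi[None]

    return StiffnessMap(stiffness=g if not squeeze else g,
                        validity_mask=valid_px,
                        pixel_spacing=pixel_spacing,
                        assumed_density=assumed_density,
                        roi=roi)


def _nanmedian3x3(image: np.ndarray) -> np.ndarray:
    """3x3 median ignoring NaNs; edge pixels use the neighbours available."""
    padded = np.pad(image, 1, mode="constant", constant_values=np.nan)
    stack = [padded[1 + dy:padded.shape[0] - 1 + dy,
                    1 + dx:padded.shape[1] - 1 + dx]
             for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(np.stack(stack), axis=0)


def postprocess_stiffness(stiff_map: StiffnessMap,
                          trim_quantile: float = 95.0,
                          median_filter: bool = True) -> StiffnessMap:
    """Median filter (3x3, within the ROI) then trim the top tail.

    Pixels above the ``trim_quantile``-th percentile of valid ROI values
    (pooled over all slices, i.e. per lung; linear-interpolation quantile)
    are removed from the validity mask.  Postprocessing never adds pixels
    to the mask.  ``median_filter=False`` applies the trim alone.
    """
    mask = stiff_map.valid_in_roi()
    if not mask.any():
        raise ValueError("empty ROI: nothing to postprocess")

    values = np.where(mask, stiff_map.stiffness, np.nan)
    if median_filter:
        filtered = np.empty_like(values)
        for k in range(values.shape[0]):
            filtered[k] = _nanmedian3x3(values[k])
        filtered = np.where(mask, filtered, np.nan)
    else:
        filtered = values

    pooled = filtered[mask & np.isfinite(filtered)]
    q = np.percentile(pooled, trim_quantile)  # linear-interpolation quantile
    keep = mask & np.isfinite(filtered) & (filtered <= q)

    return replace(stiff_map, stiffness=np.where(keep, filtered, np.nan),
                   validity_mask=keep)


def density_correct(stiff_map: StiffnessMap,
                    mean_lung_density: float) -> StiffnessMap:
    """Rescale stiffness to the measured lung density (g/cm^3).

    The Helmholtz inversion is linear in the assumed density, so
    G_corr = G_uncorr * LD / rho_assumed with both densities in the same
    units (LD in g/cm^3 is converted to kg/m^3).
    """
    if mean_lung_density <= 0:
        raise ValueError("lung density must be positive")
    if stiff_map.density_corrected:
        raise ValueError("map is already density-corrected")
    factor = mean_lung_density * 1000.0 / stiff_map.assumed_density
    return replace(stiff_map, stiffness=stiff_map.stiffness * factor,
                   density_corrected=True)


@dataclass(frozen=True)
class RegionSummary:
    median: float
    iqr: float
    n_pixels: int
    missing: bool = False


def summarize_stiffness(stiff_map: StiffnessMap,
                        rim: int = 2) -> dict[str, RegionSummary]:
    """Median and IQR of valid pixels, whole-lung and per ROI label.

    A ``rim``-pixel band at the ROI boundary is excluded (inversion edge
    effects).  Quantiles use linear interpolation between order statistics
    so the IQR is reproducible.  Absent labels are reported as missing.
    """
    mask = stiff_map.valid_in_roi()
    if rim > 0 and stiff_map.roi is not None:
        eroded = np.stack([ndimage.binary_erosion(stiff_map.roi[k], iterations=rim)
                           for k in range(stiff_map.roi.shape[0])])
        mask = mask & eroded

    def _summary(m: np.ndarray) -> RegionSummary:
        vals = stiff_map.stiffness[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return RegionSummary(np.nan, np.nan, 0, missing=True)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return RegionSummary(float(med), float(q3 - q1), int(vals.size))

    out = {"whole": _summary(mask)}
    if stiff_map.roi_labels is not None:
        labels = stiff_map.roi_labels
        out["consolidated"] = _summary(mask & (labels == 1))
        out["non-consolidated"] = _summary(mask & (labels == 0))
    return out


def invert_wavefield(wave, spec: DirectionalFilterSpec = DirectionalFilterSpec(),
                     assumed_density: float = 1000.0,
                     roi: np.ndarray | None = None,
                     roi_labels: np.ndarray | None = None) -> StiffnessMap:
    """Convenience front end: directional filter + direct inversion.

    ``assumed_density`` is the inversion's working density (water by
    default); the resulting map is meant to be rescaled afterwards with the
    measured mean lung density via :func:`density_correct`.
    """
    comps = directional_filter(wave.complex_displacement, spec)
    out = direct_inversion_2d(comps, wave.frequency, assumed_density,
                              wave.pixel_spacing, roi=roi)
    out.roi_labels = roi_labels
    return out
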