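"""Lung density from multi-echo gradient-echo magnitude images.

The lung signal decays mono-exponentially with echo time,
S(TE) = I0 exp(-TE / T2*); extrapolating to TE = 0 gives the air-free-signal
equivalent I0, which is referenced to a Gadolinium-doped water phantom to
yield an absolute density: LD = I0 / (CR * I_ph) in g/cm^3, with CR the
correction ratio for the phantom's incomplete recovery at the short TR of the
acquisition (CR = 1.873 for the reference protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import MultiTEScan

DEFAULT_CR = 1.873


@dataclass
class T2StarFit:
    I0_map: np.ndarray       # signal units, TE -> 0 extrapolation
    T2star_map: np.ndarray   # ms; inf where no decay was observed
    fit_mask: np.ndarray     # pixels with a usable fit
    no_decay: np.ndarray     # flagged pixels with non-negative log-slope


@dataclass
class DensityResult:
    I0_map: np.ndarray
    T2star_map: np.ndarray
    LD_map: np.ndarray       # g/cm^3
    mean_LD: float           # g/cm^3 over the lung mask
    CR: float


def fit_t2star(scan: MultiTEScan,
               mask: np.ndarray | None = None,
               echoes: slice | None = None) -> T2StarFit:
    """Per-pixel log-linear least-squares fit of the echo-time decay.

    With exactly two echoes this reduces to the exact two-point solution.
    Pixels with a non-positive signal at any used echo are flagged unfit;
    pixels with no measurable decay (slope >= 0) keep I0 from the intercept
    and report T2* = inf with the ``no_decay`` flag set.  ``echoes`` can
    restrict the fit to a subset (e.g. the two shortest echoes at TLC).
    """
    te = scan.echo_times
    images = scan.magnitude_images
    if echoes is not None:
        te = te[echoes]
        images = images[echoes]
    if te.size < 2:
        raise ValueError("need at least two echoes to fit")

    positive = np.all(images > 0, axis=0)
    if mask is not None:
        positive = positive & mask

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(images > 0, np.log(np.maximum(images, 1e-300)), np.nan)
    te_c = te - te.mean()
    denom = np.sum(te_c ** 2)
    slope = np.tensordot(te_c, logs, axes=(0, 0)) / denom
    intercept = np.nanmean(logs, axis=0) - slope * te.mean()

    i0 = np.where(positive, np.exp(intercept), np.nan)
    no_decay = positive & (slope >= 0)
    with np.errstate(divide="ignore"):
        t2 = np.where(positive & (slope < 0), -1.0 / slope, np.inf)
    t2 = np.where(positive, t2, np.nan)

    return T2StarFit(I0_map=i0, T2star_map=t2, fit_mask=positive,
                     no_decay=no_decay)


def measure_phantom_signal(scan: MultiTEScan) -> float:
    """Mean signal of the reference phantom ROI, pooled over echoes."""
    if not scan.phantom_roi.any():
        raise ValueError("phantom ROI is empty")
    return float(scan.magnitude_images[:, scan.phantom_roi].mean())


def compute_lung_density(i0_map: np.ndarray,
                         phantom_signal: float,
                         cr: float = DEFAULT_CR,
                         t2star_map: np.ndarray | None = None,
                         lung_mask: np.ndarray | None = None) -> DensityResult:
    """LD = I0 / (CR * I_ph), relative to water at 1 g/cm^3.

    ``mean_LD`` averages over finite pixels of the lung mask (all pixels by
    default).  LD is linear in I0 and inversely linear in I_ph, so scaling
    both signals by a common factor leaves the density unchanged.
    """
    if phantom_signal <= 0:
        raise ValueError("phantom signal must be positive")
    if cr <= 0:
        raise ValueError("CR must be positive")
    i0 = np.asarray(i0_map, dtype=float)
    ld = i0 / (cr * phantom_signal)
    sel = np.isfinite(ld)
    if lung_mask is not None:
        sel = sel & lung_mask
    if not sel.any():
        raise ValueError("no valid pixels for mean lung density")
    t2 = t2star_map if t2star_map is not None else np.full_like(i0, np.nan)
    return DensityResult(I0_map=i0, T2star_map=t2, LD_map=ld,
                         mean_LD=float(ld[sel].mean()), CR=cr)


def density_from_scan(scan: MultiTEScan,
                      lung_mask: np.ndarray | None = None,
                      echoes: slice | None = None) -> DensityResult:
    """Full density pipeline: T2* fit, phantom reference, LD map."""
    fit = fit_t2star(scan, echoes=echoes)
    i_ph = measure_phantom_signal(scan)
    if lung_mask is None:
        lung_mask = fit.fit_mask & ~scan.phantom_roi
    else:
        lung_mask = lung_mask & fit.fit_mask & ~scan.phantom_roi
    return compute_lung_density(fit.I0_map, i_ph, cr=scan.tr_correction_CR,
                                t2star_map=fit.T2star_map, lung_mask=lung_mask)
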