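"""Minimal bleaching-analysis localization.

Densely labelled combed molecules put many fluorophores within one
diffraction-limited spot, so a single image cannot resolve them.  Recording
a movie until the dyes photobleach does: when one fluorophore bleaches in a
single step, the difference between the frames just before and just after
the step contains that fluorophore alone, and its position can be fitted
with super-resolution precision (~sigma/sqrt(N) for N photons).

This module provides the forward model (a movie renderer used as the
fixture generator), the consecutive-frame differencing, 2D Gaussian spot
fitting, and the projection of the 2D localizations onto the best-fit
molecule backbone, which yields the 1D nm-space trace consumed by the
aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .simulate import stage_rng
from .traces import MoleculeTrace

__all__ = [
    "ImageStack",
    "Localization2D",
    "RenderParams",
    "render_movie",
    "bleaching_difference",
    "localize_spots",
    "project_onto_backbone",
    "trace_from_stack",
    "write_tiff",
    "read_tiff",
]

logger = logging.getLogger(__name__)


@dataclass
class ImageStack:
    """A movie: T x H x W non-negative intensities plus imaging geometry."""

    frames: np.ndarray
    pixel_size_nm: float
    psf_sigma_px: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class Localization2D:
    x_nm: float
    y_nm: float
    frame: int
    photons: float
    precision_nm: float


@dataclass(frozen=True)
class RenderParams:
    """Imaging model for the movie renderer.

    Photon rates are per frame and per fluorophore; background is photons
    per pixel per frame.  ``bleach_prob`` is the per-frame single-step
    bleaching probability (geometric bleach times); 0 disables bleaching.
    """

    n_frames: int = 60
    pixel_size_nm: float = 100.0
    psf_sigma_px: float = 1.3
    photons_per_frame: float = 2000.0
    bleach_prob: float = 0.08
    background: float = 2.0
    margin_px: int = 6
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.n_frames < 2:
            raise ValueError("bleaching analysis needs >= 2 frames")
        if not 0 <= self.bleach_prob < 1:
            raise ValueError("bleach_prob must be in [0, 1)")


def _gaussian_spot(h: int, w: int, x_px: float, y_px: float, sigma: float, photons: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.exp(-((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2 * sigma**2))
    return photons * g / (2 * np.pi * sigma**2)


def render_movie(
    trace: MoleculeTrace,
    params: RenderParams | None = None,
    seed: int = 0,
    field_shape: tuple[int, int] | None = None,
    bleach_frames: Sequence[int] | None = None,
) -> tuple[ImageStack, list[dict]]:
    """Render a bleaching movie of one combed molecule.

    The molecule is laid along a horizontal line through the field centre.
    Each label emits at a constant photon rate until its geometric
    single-step bleaching time, under Poisson shot noise and a constant
    background.  Returns the stack and per-label ground truth
    (x_nm, y_nm, bleach frame).
    """
    params = params or RenderParams()
    rng = stage_rng(seed, "render")
    mol_px = trace.length_nm / params.pixel_size_nm
    w = int(np.ceil(mol_px)) + 2 * params.margin_px
    h = 2 * params.margin_px + 1
    if field_shape is not None:
        fh, fw = field_shape
        if fw < w or fh < h:
            raise ValueError(
                f"field {field_shape} too small for molecule needing {h}x{w} px"
            )
        h, w = fh, fw
    y0 = h / 2.0
    x_px = params.margin_px + trace.positions_nm / params.pixel_size_nm

    if bleach_frames is not None:
        bleach = np.asarray(bleach_frames, dtype=int)
        if bleach.size != trace.n_labels:
            raise ValueError("one bleach frame per label required")
    elif params.bleach_prob > 0:
        bleach = rng.geometric(params.bleach_prob, size=trace.n_labels)
    else:
        bleach = np.full(trace.n_labels, params.n_frames + 1)

    frames = np.zeros((params.n_frames, h, w))
    for i, bx in enumerate(x_px):
        spot = _gaussian_spot(h, w, bx, y0, params.psf_sigma_px, params.photons_per_frame)
        t_off = min(int(bleach[i]), params.n_frames)
        frames[:t_off] += spot
    frames += params.background
    if params.poisson_noise:
        frames = rng.poisson(frames).astype(float)

    truth = [
        {
            "x_nm": float(bx * params.pixel_size_nm),
            "y_nm": float(y0 * params.pixel_size_nm),
            "bleach_frame": int(bleach[i]),
        }
        for i, bx in enumerate(x_px)
    ]
    return ImageStack(frames, params.pixel_size_nm, params.psf_sigma_px), truth


def bleaching_difference(stack: ImageStack) -> np.ndarray:
    """Consecutive-frame differences frame_t - frame_{t+1}.

    A fluorophore bleaching between frames t and t+1 appears as an isolated
    positive spot in difference frame t, even when its neighbours are within
    the diffraction limit.
    """
    if stack.n_frames < 2:
        raise ValueError("bleaching analysis needs >= 2 frames")
    return stack.frames[:-1] - stack.frames[1:]


def _fit_spot(
    frame: np.ndarray, x0: float, y0: float, sigma: float, radius: int
) -> tuple[float, float, float] | None:
    h, w = frame.shape
    xlo, xhi = max(0, int(x0) - radius), min(w, int(x0) + radius + 1)
    ylo, yhi = max(0, int(y0) - radius), min(h, int(y0) + radius + 1)
    win = frame[ylo:yhi, xlo:xhi]
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]

    def model(p):
        x, y, n, b = p
        return b + n * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)) / (
            2 * np.pi * sigma**2
        )

    n0 = max(win.sum() - win.size * np.median(win), 1.0)
    p0 = np.array([x0, y0, n0, float(np.median(win))])
    try:
        res = least_squares(
            lambda p: (model(p) - win).ravel(),
            p0,
            bounds=([xlo - 1, ylo - 1, 0, -np.inf], [xhi, yhi, np.inf, np.inf]),
            max_nfev=200,
        )
    except Exception as exc:  # pragma: no cover - scipy failure path
        logger.warning("spot fit at (%.1f, %.1f) raised %s; dropped", x0, y0, exc)
        return None
    if not res.success or res.x[2] <= 0:
        logger.warning("spot fit at (%.1f, %.1f) did not converge; dropped", x0, y0)
        return None
    x, y, n, _ = res.x
    return float(x), float(y), float(n)


def localize_spots(
    frame: np.ndarray,
    pixel_size_nm: float,
    psf_sigma_px: float,
    threshold: float,
    frame_index: int = 0,
) -> list[Localization2D]:
    """Detect and fit isolated spots in one (difference) frame.

    Candidates are local maxima of the matched-filtered (Gaussian-smoothed)
    frame above ``threshold`` (same photon units as the frame); each is
    refined by least-squares 2D Gaussian fitting with fixed PSF width.
    Precision is the photon-limited estimate sigma / sqrt(N).
    """
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    smoothed = gaussian_filter(frame, psf_sigma_px)
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(2 * psf_sigma_px))),
        threshold_abs=threshold,
    )
    out = []
    radius = max(2, int(np.ceil(3 * psf_sigma_px)))
    for y0, x0 in peaks:
        fit = _fit_spot(frame, float(x0), float(y0), psf_sigma_px, radius)
        if fit is None:
            continue
        x, y, n = fit
        out.append(
            Localization2D(
                x_nm=x * pixel_size_nm,
                y_nm=y * pixel_size_nm,
                frame=frame_index,
                photons=n,
                precision_nm=psf_sigma_px * pixel_size_nm / np.sqrt(n),
            )
        )
    return out


def project_onto_backbone(localizations: Sequence[Localization2D]) -> MoleculeTrace:
    """Collapse 2D localizations onto the best-fit molecule axis.

    The axis is the first principal component (orthogonal least squares);
    positions are signed projections shifted so the smallest is 0.  The
    mirror ambiguity of the axis direction is left to the aligner's
    orientation search.
    """
    if len(localizations) < 2:
        raise ValueError("need >= 2 localizations to define a backbone")
    pts = np.array([[l.x_nm, l.y_nm] for l in localizations])
    centre = pts.mean(axis=0)
    d = pts - centre
    if np.allclose(d, 0):
        raise ValueError("all localizations coincide; backbone undefined")
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    proj = d @ vt[0]
    proj -= proj.min()
    order = np.argsort(proj, kind="stable")
    return MoleculeTrace(
        molecule_id="backbone",
        positions_nm=proj[order],
        length_nm=float(proj.max()),
        photons=np.array([localizations[i].photons for i in order]),
        precision_nm=np.array([localizations[i].precision_nm for i in order]),
    )


def trace_from_stack(
    stack: ImageStack, threshold: float, molecule_id: str = "movie"
) -> MoleculeTrace:
    """Full bleaching-analysis route: stack -> differences -> spots -> 1D trace."""
    diffs = bleaching_difference(stack)
    locs: list[Localization2D] = []
    for t, frame in enumerate(diffs):
        locs.extend(
            localize_spots(frame, stack.pixel_size_nm, stack.psf_sigma_px, threshold, t)
        )
    trace = project_onto_backbone(locs)
    trace.molecule_id = molecule_id
    return trace


def write_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page 16-bit TIFF."""
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        frames,
        metadata={
            "pixel_size_nm": stack.pixel_size_nm,
            "psf_sigma_px": stack.psf_sigma_px,
        },
    )


def read_tiff(path: str | Path, pixel_size_nm: float, psf_sigma_px: float) -> ImageStack:
    frames = tifffile.imread(str(path)).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, pixel_size_nm, psf_sigma_px)
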