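"""Spot detection at a fixed false-positive rate and sub-pixel localization.

Detection performs a pixel-wise hypothesis test of a fixed-width Gaussian
peak over a locally constant background against background alone, inside a
sliding evaluation box (default 9x9 px).  With locally Gaussian noise of
unknown level the generalized likelihood-ratio statistic is the regression
t-statistic of the peak amplitude, whose null distribution is Student-t
with ``box**2 - 2`` degrees of freedom; the detection threshold for a
nominal per-pixel false-positive rate (default 1e-6) follows directly from
its quantile, with no Monte-Carlo table required.  Candidates are then
refined by least-squares fitting of an integrated 2D Gaussian with fixed
PSF width, yielding sub-pixel positions with a Cramer-Rao-style precision
estimate from the fit covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from scipy.stats import t as t_dist

__all__ = [
    "FrameStack",
    "detect_particles",
    "localize",
    "localize_stack",
    "render_smlm_image",
    "density_qc",
]


@dataclass
class FrameStack:
    """Single-channel image time series with acquisition metadata."""

    pixels: np.ndarray  # (frame, row, col), non-negative counts
    pixel_size: float  # um
    frame_interval: float  # s
    channel: str = "A"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (frame, row, col) array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def fov_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in um."""
        return (
            self.pixels.shape[2] * self.pixel_size,
            self.pixels.shape[1] * self.pixel_size,
        )

    @property
    def area_um2(self) -> float:
        return self.fov_um[0] * self.fov_um[1]


def _psf_template(box: int, sigma_px: float) -> np.ndarray:
    """Integrated Gaussian PSF centered in a box (pixel units)."""
    half = box // 2
    g = np.arange(-half, half + 1)
    s = sigma_px * math.sqrt(2.0)
    f = 0.5 * (erf((g + 0.5) / s) - erf((g - 0.5) / s))
    return np.outer(f, f)


def detection_threshold(alpha_det: float, box: int) -> float:
    """GLRT threshold for a per-pixel false-positive rate ``alpha_det``.

    Under the null (constant background plus iid Gaussian noise of unknown
    variance) the amplitude t-statistic is Student-t distributed with
    ``box**2 - 2`` degrees of freedom; the threshold is its upper
    ``alpha_det`` quantile (one-sided: only positive peaks are spots).
    """
    if not 0.0 < alpha_det < 1.0:
        raise ValueError("alpha_det must be in (0, 1)")
    return float(t_dist.ppf(1.0 - alpha_det, box * box - 2))


def detect_particles(
    frame: np.ndarray,
    alpha_det: float = 1e-6,
    box: int = 9,
    psf_sigma_px: float = 1.3,
) -> pd.DataFrame:
    """Detect candidate spots in one frame at a fixed false-positive rate.

    Returns a DataFrame with columns ``row``, ``col``, ``tstat`` for pixels
    whose amplitude t-statistic exceeds the threshold and that are local
    maxima of the statistic within their 8-connected neighborhood.  Pixels
    closer than ``box // 2`` to the image border are not eligible (the
    evaluation box would leave the image).
    """
    frame = np.asarray(frame, dtype=float)
    if box % 2 != 1 or box < 3:
        raise ValueError("box must be an odd integer >= 3")
    if frame.ndim != 2 or min(frame.shape) < box:
        raise ValueError("frame must be 2D and at least box x box pixels")

    n = box * box
    tmpl = _psf_template(box, psf_sigma_px)
    g = tmpl - tmpl.mean()
    g2 = float((g * g).sum())

    ones = np.ones((box, box))
    s1 = ndimage.correlate(frame, ones, mode="mirror")
    s2 = ndimage.correlate(frame * frame, ones, mode="mirror")
    c = ndimage.correlate(frame, g, mode="mirror")

    ss_res = s2 - s1 * s1 / n - c * c / g2
    ss_res = np.maximum(ss_res, 0.0)
    s = np.sqrt(np.maximum(ss_res / (n - 2), 1e-300))
    tstat = (c / math.sqrt(g2)) / s

    thr = detection_threshold(alpha_det, box)
    mask = tstat > thr
    half = box // 2
    mask[:half, :] = mask[-half:, :] = False
    mask[:, :half] = mask[:, -half:] = False
    # local-maximum deduplication within the 8-connected neighborhood
    mask &= tstat >= ndimage.maximum_filter(tstat, size=3, mode="nearest")
    rows, cols = np.nonzero(mask)
    if len(rows) > 1:
        # resolve plateau ties (equal neighboring statistics): keep the
        # first candidate in row-major order within each 8-neighborhood
        keep = np.ones(len(rows), bool)
        for i in range(1, len(rows)):
            close = (np.abs(rows[:i] - rows[i]) <= 1) & (
                np.abs(cols[:i] - cols[i]) <= 1
            )
            if (close & keep[:i]).any():
                keep[i] = False
        rows, cols = rows[keep], cols[keep]
    return pd.DataFrame(
        {"row": rows, "col": cols, "tstat": tstat[rows, cols]}
    )


def _spot_model(params, rows, cols, sigma_px):
    a, b, x, y = params
    s = sigma_px * math.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - x) / s) - erf((cols - 0.5 - x) / s))
    fy = 0.5 * (erf((rows + 0.5 - y) / s) - erf((rows - 0.5 - y) / s))
    return a * np.outer(fy, fx) + b


def localize(
    frame: np.ndarray,
    candidates: pd.DataFrame,
    psf_sigma_px: float = 1.3,
    box: int = 9,
    pixel_size: float = 0.1067,
    frame_index: int = 0,
    channel: str = "A",
) -> pd.DataFrame:
    """Least-squares sub-pixel localization of detected candidates.

    Fits amplitude, constant background and the sub-pixel center of an
    integrated 2D Gaussian with fixed ``psf_sigma_px`` inside the
    evaluation box.  The localization precision is estimated from the fit
    covariance (square root of the mean of the x/y position variances).
    Non-converged fits and fits landing outside the box are dropped; the
    number dropped is stored in ``df.attrs["n_dropped"]``.

    Positions are in um with the center of pixel (0, 0) at (0, 0) um and
    x running along columns.
    """
    frame = np.asarray(frame, dtype=float)
    half = box // 2
    grid = np.arange(-half, half + 1, dtype=float)
    out = []
    n_dropped = 0
    for cand in candidates.itertuples(index=False):
        r0, c0 = int(cand.row), int(cand.col)
        sub = frame[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
        if sub.shape != (box, box):
            n_dropped += 1
            continue
        b0 = float(np.percentile(sub, 25))
        a0 = max(float(sub.max() - b0) / max(_psf_template(box, psf_sigma_px).max(), 1e-12), 1e-6)

        def resid(p, sub=sub):
            return (_spot_model(p, grid, grid, psf_sigma_px) - sub).ravel()

        try:
            fit = least_squares(
                resid,
                x0=[a0, b0, 0.0, 0.0],
                bounds=([0, -np.inf, -half, -half], [np.inf, np.inf, half, half]),
                method="trf",
            )
        except Exception:
            n_dropped += 1
            continue
        a, b, dx, dy = fit.x
        at_edge = max(abs(dx), abs(dy)) > half - 1e-6
        # a vanishing amplitude (flat box) leaves the center unidentified
        flat = a < 1e-4 * max(abs(b), 1.0)
        if not fit.success or at_edge or flat:
            n_dropped += 1
            continue
        # Cramer-Rao-style precision: sandwich covariance of the
        # least-squares estimator with shot-noise-limited per-pixel
        # variances (Poisson: var = model value), floored at the residual
        # variance so purely Gaussian backgrounds are not underestimated
        dof = max(box * box - 4, 1)
        s2_res = 2.0 * fit.cost / dof
        model = _spot_model(fit.x, grid, grid, psf_sigma_px).ravel()
        var_px = np.maximum(model, s2_res)
        try:
            bread = np.linalg.inv(fit.jac.T @ fit.jac)
            meat = (fit.jac * var_px[:, None]).T @ fit.jac
            cov = bread @ meat @ bread
            prec_px = math.sqrt(max((cov[2, 2] + cov[3, 3]) / 2.0, 0.0))
        except np.linalg.LinAlgError:
            n_dropped += 1
            continue
        if not np.isfinite(prec_px):
            n_dropped += 1
            continue
        out.append(
            {
                "frame": frame_index,
                "x_um": (c0 + dx) * pixel_size,
                "y_um": (r0 + dy) * pixel_size,
                "precision_um": max(prec_px, 1e-6) * pixel_size,
                "intensity": a,
                "background": b,
                "channel": channel,
            }
        )
    df = pd.DataFrame(
        out,
        columns=[
            "frame", "x_um", "y_um", "precision_um",
            "intensity", "background", "channel",
        ],
    )
    df.attrs["n_dropped"] = n_dropped
    return df


def localize_stack(
    stack: FrameStack,
    alpha_det: float = 1e-6,
    box: int = 9,
    psf_sigma_um: float = 0.139,
) -> pd.DataFrame:
    """Run detection and localization over every frame of a stack."""
    sigma_px = psf_sigma_um / stack.pixel_size
    frames = []
    for t in range(stack.n_frames):
        cands = detect_particles(stack.pixels[t], alpha_det, box, sigma_px)
        frames.append(
            localize(
                stack.pixels[t],
                cands,
                sigma_px,
                box,
                stack.pixel_size,
                frame_index=t,
                channel=stack.channel,
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_smlm_image(
    localizations: pd.DataFrame,
    pixel_size: float = 0.1067,
    upsampling: int = 10,
    n_frames_window: int | None = 500,
    blur_sigma_um: float | None = None,
    fov_um: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render a super-resolution image from localizations.

    Localizations within the first ``n_frames_window`` frames are
    histogrammed on a grid upsampled by ``upsampling`` and blurred with a
    Gaussian of the mean localization precision (or ``blur_sigma_um``).
    Total image mass equals the number of rendered localizations; the
    canvas is padded so that blurred intensity is not clipped.
    """
    if upsampling < 1:
        raise ValueError("upsampling must be >= 1")
    locs = localizations
    if n_frames_window is not None:
        locs = locs[locs.frame < n_frames_window]
    sub_px = pixel_size / upsampling
    if fov_um is None:
        if len(locs) == 0:
            return np.zeros((1, 1))
        fov_um = (
            float(locs.x_um.max()) + pixel_size,
            float(locs.y_um.max()) + pixel_size,
        )
    if blur_sigma_um is None:
        blur_sigma_um = (
            float(locs.precision_um.mean())
            if "precision_um" in locs and len(locs)
            else 0.0
        )
    blur_px = blur_sigma_um / sub_px if blur_sigma_um else 0.0
    pad = int(math.ceil(5 * blur_px)) + 1
    nx = int(math.ceil(fov_um[0] / sub_px))
    ny = int(math.ceil(fov_um[1] / sub_px))
    img, _, _ = np.histogram2d(
        locs.y_um.to_numpy() if len(locs) else np.empty(0),
        locs.x_um.to_numpy() if len(locs) else np.empty(0),
        bins=(ny, nx),
        range=((0, ny * sub_px), (0, nx * sub_px)),
    )
    img = np.pad(img, pad)
    if blur_px > 0:
        img = ndimage.gaussian_filter(img, blur_px, truncate=6.0, mode="constant")
    return img


def density_qc(
    localizations: pd.DataFrame | dict[str, pd.DataFrame],
    area_um2: float,
    n_frames: int,
    max_density: float = 1.0,
) -> dict:
    """Observable particle-density QC gate.

    Computes the time-averaged per-frame localization density for each
    channel; the cell is accepted only if the density is below
    ``max_density`` (default 1 um^-2) in *every* channel.
    """
    if not area_um2 > 0:
        raise ValueError("area must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    tables = (
        localizations
        if isinstance(localizations, dict)
        else {"A": localizations}
    )
    densities = {}
    for ch, df in tables.items():
        counts = df.groupby("frame").size().reindex(
            np.arange(n_frames), fill_value=0
        )
        densities[ch] = float(counts.mean() / area_um2)
    accepted = all(d < max_density for d in densities.values())
    return {"density_um2": densities, "accepted": accepted,
            "max_density": max_density}
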