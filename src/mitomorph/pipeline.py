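"""Preprocessing and segmentation of TEM micrographs.

The chain runs, in fixed order: intensity inversion (mitochondria are
electron dense, i.e. dark; downstream stages assume bright-on-dark), rolling
ball background subtraction (radius 60 px by default), an FFT bandpass
passing structures between 8 and 60 px with optional suppression of vertical
scan-line stripes (5% directional tolerance), maximum-entropy (Kapur)
histogram thresholding, and binarization.

Conventions that the original toolchain leaves open are fixed here and
documented: the bandpass transfer function is a Gaussian band in
log-characteristic-size with 50% amplitude cuts exactly at the two size
bounds (``bandpass_gain`` exposes it in closed form); stripe suppression is
an angular notch around the stripe axis applied inside the band; filtered
images are rescaled to the input dynamic range by an affine min-max map
before thresholding; threshold ties break toward the lowest gray level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
from skimage.restoration import rolling_ball
from skimage.transform import resize

logger = logging.getLogger("mitomorph")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "invert",
    "rolling_ball_subtract",
    "fft_bandpass",
    "bandpass_gain",
    "max_entropy_threshold",
    "binarize",
    "run_preprocess",
]

# Background estimation on a downscaled copy once the ball no longer resolves
# single pixels; keeps the default radius-60 stage ~30x faster than the exact
# full-resolution opening at negligible cost in background accuracy.
_RB_DOWNSCALE_RADIUS = 24
_RB_TARGET_RADIUS = 15.0


def _bit_depth(img: np.ndarray) -> int:
    if img.dtype == np.uint8:
        return 8
    if img.dtype == np.uint16:
        return 16
    raise TypeError(f"expected uint8 or uint16 image, got {img.dtype}")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the segmentation chain (defaults follow the TEM protocol)."""

    rolling_ball_radius: float = 60.0
    bandpass_large: float = 60.0
    bandpass_small: float = 8.0
    stripe_direction: str = "vertical"      # "vertical" | "horizontal" | "none"
    stripe_tolerance: float = 5.0           # percent of direction
    threshold_method: str = "max_entropy"
    min_particle_px: int = 600

    def __post_init__(self) -> None:
        if self.rolling_ball_radius <= 0:
            raise ValueError("rolling_ball_radius must be > 0")
        if not (0 < self.bandpass_small < self.bandpass_large):
            raise ValueError("require 0 < bandpass_small < bandpass_large")
        if self.stripe_direction not in ("vertical", "horizontal", "none"):
            raise ValueError("stripe_direction must be vertical|horizontal|none")
        if not (0.0 < self.stripe_tolerance < 100.0):
            raise ValueError("stripe_tolerance must be in (0, 100)")
        if self.threshold_method != "max_entropy":
            raise ValueError("only max_entropy thresholding is implemented")
        if self.min_particle_px < 0:
            raise ValueError("min_particle_px must be >= 0")

    def fingerprint(self) -> str:
        """Stable hash of all analysis-relevant settings."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Mask plus retrievable intermediate stages of one run."""

    mask: np.ndarray
    threshold: int
    stages: dict = field(default_factory=dict)
    config: PipelineConfig | None = None


def invert(img: np.ndarray) -> np.ndarray:
    """Intensity inversion: out = (2^depth - 1) - in.  Involutive."""
    maxv = (1 << _bit_depth(img)) - 1
    return (maxv - img.astype(np.int64)).astype(img.dtype)


def rolling_ball_subtract(img: np.ndarray, radius: float) -> np.ndarray:
    """Subtract the rolling-ball background estimate (bright features kept).

    The background is the grayscale opening of the image by a ball-shaped
    structuring element of the given radius — the surface traced by a ball
    rolled under the intensity landscape.  For radii >= 24 px the estimate is
    computed on a downscaled copy (factor ceil(radius/15)) and resized back,
    then clamped to lie at or below the image so the residual is nonnegative.
    Constant images map to all-zero output.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if radius >= min(img.shape):
        raise ValueError(
            f"rolling ball radius {radius} does not fit the {img.shape} image"
        )
    f = np.asarray(img, dtype=np.float64)
    if radius >= _RB_DOWNSCALE_RADIUS:
        s = int(np.ceil(radius / _RB_TARGET_RADIUS))
        small_shape = (max(f.shape[0] // s, 8), max(f.shape[1] // s, 8))
        small = resize(f, small_shape, anti_aliasing=True)
        bg = rolling_ball(small, radius=radius / s)
        bg = resize(bg, f.shape)
        bg = np.minimum(bg, f)
    else:
        bg = rolling_ball(f, radius=radius)
    out = f - bg
    if np.issubdtype(img.dtype, np.integer):
        maxv = (1 << _bit_depth(img)) - 1
        return np.clip(np.round(out), 0, maxv).astype(img.dtype)
    return out


def bandpass_gain(
    period: np.ndarray | float,
    angle: np.ndarray | float = 0.0,
    *,
    large: float = 60.0,
    small: float = 8.0,
    stripe_direction: str = "none",
    tolerance_pct: float = 5.0,
) -> np.ndarray | float:
    """Closed-form amplitude gain of :func:`fft_bandpass`.

    ``period`` is the characteristic size of a structure in px (the full
    period of a sinusoid); ``angle`` the direction of its wave vector in
    radians from the +x axis.  The band term is Gaussian in log-size,
    ``2**(-((ln s - ln s0)/w)**2)`` with ``s0 = sqrt(small*large)`` and
    ``w = ln(large/small)/2``, which equals exactly 0.5 at both size cuts.
    The stripe notch ``1 - 2**(-(theta/theta_tol)**2)`` (``theta`` the angular
    distance of the wave vector from the stripe's wave-vector axis,
    ``theta_tol = tolerance_pct/100 * 90 deg``) applies only to frequencies at
    or above the band's low cut (period <= large): lower frequencies are
    already attenuated by the band term, and notching them would distort
    large in-band structures far from the stripes.
    """
    period = np.asarray(period, dtype=np.float64)
    angle = np.asarray(angle, dtype=np.float64)
    u0 = 0.5 * (np.log(small) + np.log(large))
    w = 0.5 * (np.log(large) - np.log(small))
    gain = 2.0 ** (-(((np.log(period) - u0) / w) ** 2))
    if stripe_direction != "none":
        # vertical stripes vary along x: wave vector on the x axis
        axis = 0.0 if stripe_direction == "vertical" else np.pi / 2.0
        theta = np.abs((np.abs(angle) - axis + np.pi / 2) % np.pi - np.pi / 2)
        theta_tol = (tolerance_pct / 100.0) * (np.pi / 2.0)
        notch = 1.0 - 2.0 ** (-((theta / theta_tol) ** 2))
        gain = np.where(period <= large, gain * notch, gain)
    return gain if gain.ndim else float(gain)


def fft_bandpass(
    img: np.ndarray,
    large: float = 60.0,
    small: float = 8.0,
    stripe_direction: str = "none",
    tolerance_pct: float = 5.0,
    rescale: str = "input-range",
) -> np.ndarray:
    """FFT bandpass with optional directional stripe suppression.

    The mean is removed, the spectrum multiplied by :func:`bandpass_gain`
    evaluated on the frequency grid (DC gain 0), and the result inverse
    transformed.  ``rescale="input-range"`` affinely maps the filtered image
    onto [0, 2^depth - 1] (min -> 0, max -> max) and quantizes to the input
    dtype — the representation the threshold stage consumes.  ``"none"``
    returns the raw float residual (plus the image mean), which is what the
    transfer-function contract is stated on.
    """
    if small <= 0 or large <= 0:
        raise ValueError("bandpass bounds must be positive")
    if small >= large:
        raise ValueError("require small < large")
    if min(img.shape) < 64:
        raise ValueError("image must be at least 64x64 for the FFT stage")
    f = np.asarray(img, dtype=np.float64)
    mean = f.mean()
    # reflective padding by the large-structure cut suppresses wrap-around
    # ringing from features near the borders (the image is not periodic)
    pad = int(np.ceil(large))
    f_p = np.pad(f - mean, pad, mode="reflect")
    F = np.fft.fft2(f_p)
    fy = np.fft.fftfreq(f_p.shape[0])[:, None]
    fx = np.fft.fftfreq(f_p.shape[1])[None, :]
    rho = np.hypot(fx, fy)
    with np.errstate(divide="ignore"):
        period = np.where(rho > 0, 1.0 / np.where(rho > 0, rho, 1.0), np.inf)
    angle = np.arctan2(fy, fx) * np.ones_like(rho)
    gain = np.where(
        rho > 0,
        bandpass_gain(
            np.where(rho > 0, period, 1.0),
            angle,
            large=large,
            small=small,
            stripe_direction=stripe_direction,
            tolerance_pct=tolerance_pct,
        ),
        0.0,
    )
    out = np.real(np.fft.ifft2(F * gain))[pad:-pad, pad:-pad]
    if rescale == "none":
        return out + mean
    if rescale != "input-range":
        raise ValueError("rescale must be 'input-range' or 'none'")
    maxv = (1 << _bit_depth(img)) - 1
    lo, hi = out.min(), out.max()
    if hi <= lo:
        return np.zeros_like(img)
    scaled = (out - lo) / (hi - lo) * maxv
    return np.round(scaled).astype(img.dtype)


def max_entropy_threshold(img: np.ndarray, nbins: int = 256) -> int:
    """Kapur maximum-entropy threshold of a grayscale image.

    Maximizes H_b(t) + H_f(t), the Shannon entropies of the below- and
    above-threshold histogram classes.  8-bit images use all 256 levels;
    16-bit images are binned to ``nbins`` levels first and the returned
    threshold is mapped back to the original gray scale (upper edge of the
    selected bin).  Ties break toward the lowest threshold.  Raises on
    constant images, for which no threshold exists.
    """
    depth = _bit_depth(img)
    vals = np.asarray(img).ravel()
    if vals.min() == vals.max():
        raise ValueError("constant image has no threshold")
    if depth == 8:
        hist = np.bincount(vals, minlength=256).astype(np.float64)
        scale = 1
    else:
        scale = (1 << depth) // nbins
        hist = np.bincount(vals // scale, minlength=nbins).astype(np.float64)
    counts = np.cumsum(hist)
    p = hist / hist.sum()
    P = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    total = S[-1]
    # integer-count guard: both classes must be non-empty (a float cumsum can
    # land at 0.999... for the last populated bin and admit a degenerate split)
    valid = (counts > 0) & (counts < counts[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        Hb = np.where(valid, np.log(np.where(valid, P, 1.0)) - S / np.where(valid, P, 1.0), -np.inf)
        Hf = np.where(
            valid,
            np.log(np.where(valid, 1.0 - P, 1.0))
            - (total - S) / np.where(valid, 1.0 - P, 1.0),
            -np.inf,
        )
    crit = np.where(valid, Hb + Hf, -np.inf)[:-1]   # t = nbins-1 leaves empty foreground
    t = int(np.argmax(crit))                        # argmax returns lowest maximizer
    if scale > 1:
        t = (t + 1) * scale - 1
    return t


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground mask: pixels strictly above the threshold."""
    return np.asarray(img) > threshold


def run_preprocess(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    threshold_mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full chain: invert -> rolling ball -> bandpass -> threshold -> mask.

    By default the threshold is computed from the whole processed image.
    ``threshold_mask`` (a boolean raster, typically the rasterized analysis
    ROIs) restricts the threshold's histogram to those pixels: regions of
    extreme contrast that the ROIs exclude — plasma membrane, staining
    artifacts — then cannot skew the entropy split, while binarization still
    covers the full frame.  Intermediate stages are kept on the result for
    inspection.  Deterministic: identical inputs give identical output.
    """
    cfg = cfg or PipelineConfig()
    logger.info("run_preprocess config fingerprint=%s", cfg.fingerprint())
    inv = invert(img)
    sub = rolling_ball_subtract(inv, cfg.rolling_ball_radius)
    bp = fft_bandpass(
        sub,
        large=cfg.bandpass_large,
        small=cfg.bandpass_small,
        stripe_direction=cfg.stripe_direction,
        tolerance_pct=cfg.stripe_tolerance,
    )
    if threshold_mask is not None:
        if threshold_mask.shape != bp.shape:
            raise ValueError("threshold_mask shape must match the image")
        t = max_entropy_threshold(bp[threshold_mask])
    else:
        t = max_entropy_threshold(bp)
    mask = binarize(bp, t)
    return PipelineResult(
        mask=mask,
        threshold=t,
        stages={"inverted": inv, "background_subtracted": sub, "bandpassed": bp},
        config=cfg,
    )
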