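"""Synthetic inputs for the fusion and angiography pipeline.

Real full-field optical angiograms of e.g. a mouse ear show bright
curvilinear vessels on a dark, nearly uniform background, acquired as focal
stacks (only part of the field is within the lens's depth of field) and, at
acquisition time, as temporal speckle series whose flow pixels fluctuate
while tissue pixels are static.  Three generators emulate exactly those
features:

* :func:`make_vessel_phantom` -- branching vessels with Gaussian
  cross-sections on a constant background;
* :func:`make_multifocus_pair` -- a complementary-blur pair with a smooth
  focus transition band and known ground-truth focus mask;
* :func:`make_temporal_stack` -- a background-plus-band-limited-fluctuation
  time series matching the intensity-fluctuation-modulation model.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, ValidationError
from .amd_imaging import TemporalStack

__all__ = [
    "make_vessel_phantom",
    "make_multifocus_pair",
    "make_temporal_stack",
]


def _trace_path(rng, shape, start, heading, n_steps, turn_std=0.08):
    """Smooth random path: unit steps with small seeded heading increments."""
    h, w = shape
    pts = np.empty((n_steps, 2))
    r, c = start
    for s in range(n_steps):
        pts[s] = (r, c)
        heading += rng.normal(0.0, turn_std)
        r += np.sin(heading)
        c += np.cos(heading)
        if not (0 <= r < h and 0 <= c < w):
            return pts[: s + 1]
    return pts


def make_vessel_phantom(
    height: int,
    width: int,
    n_vessels: int = 6,
    seed: int = 0,
    background: float = 0.08,
    texture_amplitude: float = 0.0,
    return_mask: bool = False,
):
    """Render a vessel phantom: bright curvilinear structures on a dark field.

    Each vessel is a smooth random path (with an optional branch) rendered
    with a Gaussian cross-section of seeded width and brightness; vessels
    combine by maximum so crossings stay bright.  Intensities lie in [0, 1]
    and with ``n_vessels=0`` the image is the constant background level.

    ``texture_amplitude`` > 0 adds a seeded multi-scale tissue texture
    (Gaussian-filtered noise at correlation lengths 1.5, 5 and 12 px, summed
    and scaled to that standard deviation).  Real angiograms show such weak
    background texture everywhere, and it is what carries focus information
    in vessel-free areas of a multi-focus pair.

    With ``return_mask`` also returns the boolean vessel-support mask
    (within two cross-section sigmas of a centreline).
    """
    if min(height, width) < 64:
        raise ValidationError("phantom dimensions must be >= 64")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((height, width))
    mask = np.zeros((height, width), dtype=bool)
    for _ in range(n_vessels):
        start = (rng.uniform(0, height), rng.uniform(0, width))
        heading = rng.uniform(0, 2 * np.pi)
        n_steps = int(0.9 * (height + width))
        pts = _trace_path(rng, (height, width), start, heading, n_steps)
        paths = [pts]
        if pts.shape[0] > 20 and rng.uniform() < 0.6:  # one side branch
            mid = pts[rng.integers(10, pts.shape[0] - 5)]
            branch = _trace_path(
                rng, (height, width), tuple(mid), rng.uniform(0, 2 * np.pi), n_steps // 2
            )
            paths.append(branch)
        sigma = rng.uniform(1.0, 3.0)
        amplitude = rng.uniform(0.6, 1.0)
        support = np.zeros((height, width), dtype=bool)
        for p in paths:
            rr = np.clip(np.round(p[:, 0]).astype(int), 0, height - 1)
            cc = np.clip(np.round(p[:, 1]).astype(int), 0, width - 1)
            support[rr, cc] = True
        dist = ndimage.distance_transform_edt(~support)
        profile = amplitude * np.exp(-(dist**2) / (2.0 * sigma**2))
        canvas = np.maximum(canvas, profile)
        mask |= dist < 2.0 * sigma
    image = background + (1.0 - background) * canvas
    if texture_amplitude > 0.0:
        tex = (
            0.5 * ndimage.gaussian_filter(rng.standard_normal(image.shape), 1.5)
            + 0.3 * ndimage.gaussian_filter(rng.standard_normal(image.shape), 5.0)
            + 0.2 * ndimage.gaussian_filter(rng.standard_normal(image.shape), 12.0)
        )
        image = image + texture_amplitude / tex.std() * tex
    image = np.clip(image, 0.0, 1.0)
    if return_mask:
        return image, mask
    return image


def make_multifocus_pair(
    sharp: np.ndarray,
    focus_mask: np.ndarray,
    blur_sigma: float = 3.0,
    seed: int = 0,
    noise_std: float = 0.0,
    transition_band: float = 8.0,
):
    """Complementary-blur multi-focus pair with known ground truth.

    Image A is sharp where ``focus_mask`` is 1 and Gaussian-blurred
    (``blur_sigma``) elsewhere; B is the complement.  The focus boundary is
    a distance-transform-weighted blend over ``transition_band`` pixels
    (hard boundaries are unphysical for a depth-of-field cut).  Optional
    additive Gaussian noise (``noise_std``) is seeded.

    Returns ``(A, B, mask)`` with the mask returned as uint8 ground truth.
    """
    sharp = np.asarray(sharp, dtype=float)
    focus_mask = np.asarray(focus_mask).astype(bool)
    if focus_mask.shape != sharp.shape:
        raise ValidationError("focus mask shape must match the image")
    if blur_sigma <= 0:
        raise ConfigurationError("blur_sigma must be > 0")
    blurred = ndimage.gaussian_filter(sharp, blur_sigma, mode="reflect")
    if focus_mask.all() or not focus_mask.any():
        # no focus boundary: the weight field is uniform
        w = np.full(sharp.shape, 1.0 if focus_mask.all() else 0.0)
    else:
        inside = ndimage.distance_transform_edt(focus_mask)
        outside = ndimage.distance_transform_edt(~focus_mask)
        w = np.clip(0.5 + (inside - outside) / transition_band, 0.0, 1.0)
    A = w * sharp + (1.0 - w) * blurred
    B = (1.0 - w) * sharp + w * blurred
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_std, A.shape)
        B = B + rng.normal(0.0, noise_std, B.shape)
    return np.clip(A, 0.0, 1.0), np.clip(B, 0.0, 1.0), focus_mask.astype(np.uint8)


def make_temporal_stack(
    vessel_mask: np.ndarray,
    background_level: float = 0.5,
    flow_amplitude: float = 0.2,
    flow_hz: float = 8.0,
    frame_rate: float = 42.0,
    n_frames: int = 128,
    noise_std: float = 0.002,
    seed: int = 0,
    bandwidth_hz: float = 2.0,
) -> TemporalStack:
    """Temporal speckle stack with flow fluctuations confined to vessels.

    Inside the vessel mask each pixel carries a unit-RMS stochastic
    band-limited fluctuation (Gaussian spectral window of width
    ``bandwidth_hz`` centred on ``flow_hz``) scaled by ``flow_amplitude``;
    with ``bandwidth_hz=0`` the fluctuation is a pure sinusoid of amplitude
    ``flow_amplitude`` with a seeded random phase per pixel, for which the
    modulation depth has the closed form (2a/pi)/background.  Seeded
    Gaussian sensor noise is added everywhere.
    """
    vessel_mask = np.asarray(vessel_mask).astype(bool)
    if flow_hz >= frame_rate / 2.0:
        raise ConfigurationError(
            f"flow_hz={flow_hz} violates Nyquist for frame_rate={frame_rate}"
        )
    rng = np.random.default_rng(seed)
    h, w = vessel_mask.shape
    t = np.arange(n_frames) / frame_rate
    frames = np.full((n_frames, h, w), float(background_level))

    if vessel_mask.any():
        if bandwidth_hz == 0.0:
            phase = rng.uniform(0, 2 * np.pi, size=(h, w))
            fluct = np.sin(2 * np.pi * flow_hz * t[:, None, None] + phase[None])
        else:
            white = rng.standard_normal((n_frames, h, w))
            spec = np.fft.rfft(white, axis=0)
            freqs = np.fft.rfftfreq(n_frames, d=1.0 / frame_rate)
            window = np.exp(-0.5 * ((freqs - flow_hz) / bandwidth_hz) ** 2)
            fluct = np.fft.irfft(spec * window[:, None, None], n=n_frames, axis=0)
            rms = np.sqrt(np.mean(fluct**2, axis=0, keepdims=True))
            rms[rms < 1e-12] = 1.0
            fluct = fluct / rms
        frames += flow_amplitude * fluct * vessel_mask[None]
    if noise_std > 0:
        frames += rng.normal(0.0, noise_std, frames.shape)
    return TemporalStack(frames=np.clip(frames, 0.0, None), frame_rate=frame_rate)
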