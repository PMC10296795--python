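"""Contrast-spatial-frequency (CSF) fusion of NSCT bandpass subbands.

Each pair of directional subbands is fused by a binary decision map built in
four stages:

1. spatial-frequency saliency: windowed mean of squared horizontal/vertical
   first differences (RF/CF) combined into S = sqrt(RF^2 + CF^2);
2. contrast comparison: S_A is compared against the *local mean* of S_B over
   a p x q neighbourhood, which rewards regions that are both sharp and
   locally contrasted;
3. area opening: connected components (and, by default, background holes)
   smaller than r x C pixels are removed, C being the image area;
4. consistency verification: a strict-majority vote over an N x N window.

The final map selects, per pixel, exactly one of the two source subbands.
All neighbourhood operations use mirror (reflect-without-edge) padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage import morphology

from .exceptions import ConfigurationError, DimensionError, ValidationError

__all__ = [
    "SaliencyMap",
    "DecisionMap",
    "spatial_frequency",
    "csf_decision_map",
    "remove_small_regions",
    "consistency_verify",
    "fuse_bandpass_subband",
    "build_decision_map",
]


@dataclass
class SaliencyMap:
    """Spatial-frequency saliency S with its row/column components."""

    S: np.ndarray
    RF: np.ndarray
    CF: np.ndarray
    window: tuple[int, int]


@dataclass
class DecisionMap:
    """Binary focus map for one subband pair, at its three refinement stages."""

    raw: np.ndarray
    cleaned: np.ndarray
    final: np.ndarray
    params: dict = field(default_factory=dict)


def _check_odd_window(m: int, n: int, shape: tuple[int, int]) -> None:
    if m % 2 == 0 or n % 2 == 0:
        raise ConfigurationError(f"window sizes must be odd, got {(m, n)}")
    if m > shape[0] or n > shape[1]:
        raise DimensionError(f"window {(m, n)} larger than subband {shape}")


def spatial_frequency(
    H: np.ndarray, M: int = 7, N: int = 7, literal_formulas: bool = True
) -> SaliencyMap:
    """Windowed spatial-frequency saliency of a bandpass subband.

    The subband is mirror-padded and, for every pixel, RF is the mean over
    its M x N window of the squared horizontal first differences between
    window pixels (differences whose left pixel falls outside the window
    are excluded, i.e. the window's first column carries no term, matching
    the j=2..N summation limits); CF likewise with vertical differences and
    the first row excluded.  With ``literal_formulas`` (default) RF/CF are
    those mean squares directly; otherwise the conventional
    root-mean-square is taken.  Either way S = sqrt(RF^2 + CF^2) pointwise,
    and a constant subband yields S identically zero.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValidationError("subband contains non-finite values")
    _check_odd_window(M, N, H.shape)
    ph, pw = M // 2, N // 2
    Hp = np.pad(H, ((ph, ph), (pw, pw)), mode="reflect")
    dh2 = np.square(Hp[:, 1:] - Hp[:, :-1])
    dv2 = np.square(Hp[1:, :] - Hp[:-1, :])
    # sliding in-window sums: N-1 horizontal (M-1 vertical) difference columns
    # per window; 'valid' output realigns exactly with the input grid
    rf = signal.convolve2d(dh2, np.ones((M, N - 1)), mode="valid") / (M * N)
    cf = signal.convolve2d(dv2, np.ones((M - 1, N)), mode="valid") / (M * N)
    if not literal_formulas:
        rf = np.sqrt(rf)
        cf = np.sqrt(cf)
    S = np.hypot(rf, cf)
    return SaliencyMap(S=S, RF=rf, CF=cf, window=(M, N))


def _saliency_array(S) -> np.ndarray:
    return S.S if isinstance(S, SaliencyMap) else np.asarray(S, dtype=float)


def csf_decision_map(SA, SB, p: int = 7, q: int = 7) -> np.ndarray:
    """Contrast-spatial-frequency decision: 1 where S_A exceeds the local mean of S_B.

    The comparison is strict, so ties go to source B.
    """
    SA = _saliency_array(SA)
    SB = _saliency_array(SB)
    if SA.shape != SB.shape:
        raise DimensionError(f"saliency shapes differ: {SA.shape} vs {SB.shape}")
    _check_odd_window(p, q, SA.shape)
    local_mean = ndimage.correlate(SB, np.full((p, q), 1.0 / (p * q)), mode="mirror")
    return (SA > local_mean).astype(np.uint8)


def _check_binary(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("decision map must be strictly binary {0,1}")
    return m.astype(bool)


def remove_small_regions(
    decision_map: np.ndarray,
    r: float = 0.05,
    C: int | None = None,
    fill_background: bool = True,
) -> np.ndarray:
    """Area-opening cleanup of a binary decision map.

    Every 8-connected foreground component with area < ceil(r*C) is removed;
    with ``fill_background`` (default) the same opening is applied to the
    background, filling small holes, bumps and narrow breaks.  ``C``
    defaults to the map's pixel count (the source-image area).
    """
    m = _check_binary(decision_map)
    if not 0.0 < r < 1.0:
        raise ConfigurationError(f"area fraction r must be in (0, 1), got {r}")
    if C is None:
        C = m.size
    threshold = math.ceil(r * C)
    # max_size removes areas <= its value; areas of exactly ceil(r*C) survive
    out = morphology.remove_small_objects(m, max_size=threshold - 1, connectivity=2)
    if fill_background:
        out = ~morphology.remove_small_objects(~out, max_size=threshold - 1, connectivity=2)
    return out.astype(np.uint8)


def consistency_verify(decision_map: np.ndarray, N: int = 59) -> np.ndarray:
    """Strict-majority vote over an N x N neighbourhood (mirror padding)."""
    if N % 2 == 0:
        raise ConfigurationError(f"consistency window must be odd, got {N}")
    m = _check_binary(decision_map).astype(float)
    counts = ndimage.correlate(m, np.ones((N, N)), mode="mirror")
    return (counts > (N * N) / 2.0).astype(np.uint8)


def fuse_bandpass_subband(
    HA: np.ndarray, HB: np.ndarray, final_map: np.ndarray
) -> np.ndarray:
    """Pixel-wise masked combination: A where the map is 1, B where it is 0."""
    HA = np.asarray(HA, dtype=float)
    HB = np.asarray(HB, dtype=float)
    if HA.shape != HB.shape or HA.shape != np.shape(final_map):
        raise DimensionError(
            f"shapes differ: {HA.shape}, {HB.shape}, {np.shape(final_map)}"
        )
    mask = _check_binary(final_map)
    return np.where(mask, HA, HB)


def build_decision_map(
    HA: np.ndarray,
    HB: np.ndarray,
    sf_window: int = 7,
    contrast_window: int = 7,
    area_fraction: float = 0.05,
    consistency_window: int = 59,
    literal_formulas: bool = True,
    fill_background: bool = True,
) -> DecisionMap:
    """Run the full CSF decision pipeline for one subband pair."""
    SA = spatial_frequency(HA, sf_window, sf_window, literal_formulas)
    SB = spatial_frequency(HB, sf_window, sf_window, literal_formulas)
    raw = csf_decision_map(SA, SB, contrast_window, contrast_window)
    cleaned = remove_small_regions(raw, area_fraction, fill_background=fill_background)
    final = consistency_verify(cleaned, consistency_window)
    return DecisionMap(
        raw=raw,
        cleaned=cleaned,
        final=final,
        params={
            "sf_window": sf_window,
            "contrast_window": contrast_window,
            "area_fraction": area_fraction,
            "consistency_window": consistency_window,
            "literal_formulas": literal_formulas,
            "fill_background": fill_background,
        },
    )
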