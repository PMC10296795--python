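"""Nonsubsampled contourlet transform (NSCT): shift-invariant multi-scale,
multi-directional decomposition with an exact inverse.

The transform has two stages, neither of which downsamples, so every subband
keeps the spatial dimensions of the input:

* a nonsubsampled pyramid built by a-trous filtering: at scale ``u`` the
  2-D lowpass kernel is upsampled by ``2**(u-1)`` (zeros inserted between
  taps) and the detail band is the difference between successive
  approximations;
* a nonsubsampled directional filter bank: each detail band is split into
  ``2**l`` directional wedges by a fan filter and (at the second tree level)
  its quincunx-upsampled version.

Both stages use complementary analysis channels that sum to the identity
(the highpass/second channel is ``delta - lowpass``), so synthesis is plain
summation and reconstruction is exact to machine precision for any padding
mode.  Bandpass channels consequently have exactly zero DC gain.

Filter kernels are shipped as whitespace-delimited text tables and loaded by
name; ``"pyrexc"`` (pyramid) and ``"vk"`` (directional) are the default
registered names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage, signal

from .exceptions import ConfigurationError, DimensionError, ValidationError

__all__ = [
    "FilterBank",
    "NsctPyramid",
    "build_filter_banks",
    "nsct_decompose",
    "nsct_reconstruct",
]

#: kernels up to this linear size are convolved in the spatial domain;
#: larger (a-trous upsampled) kernels go through FFT products.
_SPATIAL_KERNEL_LIMIT = 32

_PYRAMID_TABLES = {"pyrexc": "pyrexc.txt", "maxflat": "maxflat.txt"}
_DIRECTIONAL_TABLES = {"vk": "vk_halfband.txt"}


def _load_table(fname: str) -> np.ndarray:
    text = resources.files("ffoafuse.filterdata").joinpath(fname).read_text()
    return np.atleast_2d(np.loadtxt(text.splitlines()))


def _delta_like(kernel: np.ndarray) -> np.ndarray:
    d = np.zeros_like(kernel)
    d[kernel.shape[0] // 2, kernel.shape[1] // 2] = 1.0
    return d


def _add_centered(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sum two odd-sized zero-phase kernels, aligning their centers."""
    rows = max(a.shape[0], b.shape[0])
    cols = max(a.shape[1], b.shape[1])
    out = np.zeros((rows, cols))
    for k in (a, b):
        r0 = (rows - k.shape[0]) // 2
        c0 = (cols - k.shape[1]) // 2
        out[r0 : r0 + k.shape[0], c0 : c0 + k.shape[1]] += k
    return out


def _diamond_from_halfband(hb: np.ndarray) -> np.ndarray:
    """McClellan transform of a zero-phase 1-D halfband filter.

    Substituting ``cos(w) -> (cos(w1) + cos(w2)) / 2`` turns the 1-D lowpass
    into a diamond-shaped 2-D lowpass with gain 1 at DC and 0 at (pi, pi).
    Chebyshev polynomials of the substitution kernel are built by the
    recursion ``P_n = 2 K * P_{n-1} - P_{n-2}`` (kernel-domain convolution).
    """
    hb = np.asarray(hb, dtype=float).ravel()
    if hb.size % 2 == 0:
        raise ConfigurationError("halfband filter must have odd length")
    c = hb.size // 2
    K = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float) / 4.0
    p_prev = np.ones((1, 1))  # T_0 = 1
    p_cur = K  # T_1
    out = hb[c] * np.ones((1, 1))
    for n in range(1, c + 1):
        out = _add_centered(out, 2.0 * hb[c + n] * p_cur)
        if n < c:
            p_next = _add_centered(2.0 * signal.convolve2d(K, p_cur), -p_prev)
            p_prev, p_cur = p_cur, p_next
    return out


def _fan_from_diamond(diamond: np.ndarray) -> np.ndarray:
    """Modulate the first frequency axis by pi: diamond -> fan wedge filter."""
    rows = np.arange(diamond.shape[0]) - diamond.shape[0] // 2
    return diamond * ((-1.0) ** rows)[:, None]


def _atrous_upsample(kernel: np.ndarray, factor: int) -> np.ndarray:
    """Insert ``factor - 1`` zeros between taps along both axes."""
    if factor == 1:
        return kernel
    out = np.zeros(((kernel.shape[0] - 1) * factor + 1, (kernel.shape[1] - 1) * factor + 1))
    out[::factor, ::factor] = kernel
    return out


def _quincunx_upsample(kernel: np.ndarray) -> np.ndarray:
    """Upsample a kernel on the quincunx lattice Q = [[1, 1], [-1, 1]].

    A tap at centered offset (a, b) moves to (a + b, b - a); the support
    rotates by 45 degrees and widens, which is what splits a fan wedge into
    two finer directional wedges at the second tree level.
    """
    rc, cc = kernel.shape[0] // 2, kernel.shape[1] // 2
    half = (kernel.shape[0] - 1) // 2 + (kernel.shape[1] - 1) // 2
    out = np.zeros((2 * half + 1, 2 * half + 1))
    rows, cols = np.nonzero(np.ones_like(kernel, dtype=bool))
    a, b = rows - rc, cols - cc
    out[a + b + half, b - a + half] = kernel[rows, cols]
    return out


_PAD_MODES = {"mirror": "mirror", "wrap": "wrap"}
_NP_PAD = {"mirror": "reflect", "wrap": "wrap"}


def _convolve(image: np.ndarray, kernel: np.ndarray, pad_mode: str = "mirror") -> np.ndarray:
    """Zero-phase 2-D convolution with the requested boundary handling.

    Spatial path for small kernels, FFT path for large a-trous kernels; both
    implement identical padded linear convolution.
    """
    if pad_mode not in _PAD_MODES:
        raise ConfigurationError(f"unknown pad_mode {pad_mode!r}; use 'mirror' or 'wrap'")
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    if ph > image.shape[0] - 1 or pw > image.shape[1] - 1:
        raise DimensionError(
            f"image of shape {image.shape} is too small for filter support "
            f"{kernel.shape} (needs at least {(ph + 1, pw + 1)})"
        )
    if max(kernel.shape) <= _SPATIAL_KERNEL_LIMIT:
        return _convolve_spatial(image, kernel, pad_mode)
    return _convolve_fft(image, kernel, pad_mode)


def _convolve_spatial(image, kernel, pad_mode="mirror"):
    return ndimage.convolve(image, kernel, mode=_PAD_MODES[pad_mode])


def _convolve_fft(image, kernel, pad_mode="mirror"):
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode=_NP_PAD[pad_mode])
    return signal.fftconvolve(padded, kernel, mode="valid")


@dataclass(frozen=True)
class FilterBank:
    """Analysis/synthesis kernels for the pyramid and directional stages.

    The bank is Laplacian-style: the second analysis channel is
    ``delta - first channel`` and the synthesis kernels are deltas, so the
    perfect-reconstruction identity ``h0*g0 + h1*g1 = delta`` holds exactly.
    """

    pyramid_name: str
    directional_name: str
    pyramid_lowpass: np.ndarray  # h0, DC gain 1
    fan: np.ndarray  # f0, directional wedge filter, gain 1 at (pi, 0)

    @property
    def pyramid_highpass(self) -> np.ndarray:
        return _delta_like(self.pyramid_lowpass) - self.pyramid_lowpass

    @property
    def pyramid_synthesis(self) -> tuple[np.ndarray, np.ndarray]:
        d = _delta_like(self.pyramid_lowpass)
        return d, d

    @property
    def fan_complement(self) -> np.ndarray:
        return _delta_like(self.fan) - self.fan

    def pr_impulse_error(self) -> float:
        """Max deviation of composed analysis+synthesis from a delta."""
        g0, g1 = self.pyramid_synthesis
        pyr = signal.convolve2d(self.pyramid_lowpass, g0) + signal.convolve2d(
            self.pyramid_highpass, g1
        )
        pyr_err = np.abs(pyr - _delta_like(pyr)).max()
        fan = _add_centered(self.fan, self.fan_complement)
        fan_err = np.abs(fan - _delta_like(fan)).max()
        return max(pyr_err, fan_err)


def build_filter_banks(pyramid_name: str = "pyrexc", directional_name: str = "vk") -> FilterBank:
    """Load the named pyramid/directional kernel tables.

    Raises
    ------
    ConfigurationError
        If a name is not registered; the message lists the supported names.
    """
    if pyramid_name not in _PYRAMID_TABLES:
        raise ConfigurationError(
            f"unknown pyramid filter {pyramid_name!r}; supported: {sorted(_PYRAMID_TABLES)}"
        )
    if directional_name not in _DIRECTIONAL_TABLES:
        raise ConfigurationError(
            f"unknown directional filter {directional_name!r}; "
            f"supported: {sorted(_DIRECTIONAL_TABLES)}"
        )
    h0 = _load_table(_PYRAMID_TABLES[pyramid_name])
    halfband = _load_table(_DIRECTIONAL_TABLES[directional_name]).ravel()
    fan = _fan_from_diamond(_diamond_from_halfband(halfband))
    return FilterBank(pyramid_name, directional_name, h0, fan)


@dataclass
class NsctPyramid:
    """One full-resolution lowpass image plus per-scale directional bandpass images.

    ``bandpass[(u, k)]`` is the detail at scale ``u`` (1 = finest) and
    direction ``k`` with ``1 <= k <= dirs_per_level[u - 1]``.
    """

    lowpass: np.ndarray
    bandpass: dict[tuple[int, int], np.ndarray]
    n_levels: int
    dirs_per_level: list[int] = field(default_factory=list)
    pad_mode: str = "mirror"

    def subbands(self):
        """Iterate ``((u, k), array)`` in scale-then-direction order."""
        for u in range(1, self.n_levels + 1):
            for k in range(1, self.dirs_per_level[u - 1] + 1):
                yield (u, k), self.bandpass[(u, k)]

    def validate_shapes(self) -> None:
        shape = self.lowpass.shape
        for key, sub in self.bandpass.items():
            if sub.shape != shape:
                raise DimensionError(
                    f"subband {key} has shape {sub.shape}, expected {shape}"
                )
        expected = {
            (u, k)
            for u in range(1, self.n_levels + 1)
            for k in range(1, self.dirs_per_level[u - 1] + 1)
        }
        if expected != set(self.bandpass):
            raise DimensionError("bandpass keys inconsistent with n_levels/dirs_per_level")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale array, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite pixels")
    return image


def _nsdfb_decompose(band: np.ndarray, levels: int, filters: FilterBank, pad_mode: str):
    """Split one detail band into 2**levels directional subbands (levels <= 2)."""
    if levels == 0:
        return [band]
    f0 = filters.fan
    y0 = _convolve(band, f0, pad_mode)
    y1 = band - y0
    if levels == 1:
        return [y0, y1]
    if levels == 2:
        fq = _quincunx_upsample(f0)
        out = []
        for y in (y0, y1):
            c0 = _convolve(y, fq, pad_mode)
            out.extend([c0, y - c0])
        return out
    raise ConfigurationError(
        "directional decomposition depth per scale is supported up to 2 "
        f"(4 subbands); got {levels}"
    )


def nsct_decompose(
    image: np.ndarray,
    n_levels: int = 4,
    dir_levels: list[int] | tuple[int, ...] = (2, 2, 2, 2),
    filters: FilterBank | None = None,
    pad_mode: str = "mirror",
) -> NsctPyramid:
    """Decompose ``image`` into a lowpass band and directional bandpass bands.

    Parameters
    ----------
    image : 2-D array
        Grayscale image, finite values; both dimensions must be >= 16.
    n_levels : int
        Number of pyramid scales Q.
    dir_levels : sequence of int, length ``n_levels``
        Directional decomposition depth per scale; scale ``u`` gets
        ``2**dir_levels[u-1]`` subbands (entries in {0, 1, 2}).
    filters : FilterBank, optional
        Defaults to ``build_filter_banks("pyrexc", "vk")``.
    pad_mode : {"mirror", "wrap"}
        Boundary handling; "wrap" makes the transform exactly circular-shift
        covariant.

    The operator is linear and every subband has the input's shape.
    """
    image = _validate_image(image)
    if n_levels < 1:
        raise ConfigurationError("n_levels must be >= 1")
    dir_levels = list(dir_levels)
    if len(dir_levels) != n_levels:
        raise ConfigurationError(
            f"dir_levels must have {n_levels} entries, got {len(dir_levels)}"
        )
    if min(image.shape) < 16:
        raise DimensionError(
            f"image shape {image.shape} too small; decomposition requires >= 16 pixels per axis"
        )
    if filters is None:
        filters = build_filter_banks()
    h0 = filters.pyramid_lowpass
    deepest = (h0.shape[0] - 1) * 2 ** (n_levels - 1) + 1
    if deepest // 2 > min(image.shape) - 1:
        raise DimensionError(
            f"image shape {image.shape} too small for the level-{n_levels} "
            f"a-trous filter support ({deepest}x{deepest})"
        )

    approx = image
    bandpass: dict[tuple[int, int], np.ndarray] = {}
    for u in range(1, n_levels + 1):
        h0u = _atrous_upsample(h0, 2 ** (u - 1))
        smooth = _convolve(approx, h0u, pad_mode)
        detail = approx - smooth
        for k, sub in enumerate(_nsdfb_decompose(detail, dir_levels[u - 1], filters, pad_mode), 1):
            bandpass[(u, k)] = sub
        approx = smooth
    return NsctPyramid(
        lowpass=approx,
        bandpass=bandpass,
        n_levels=n_levels,
        dirs_per_level=[2**d for d in dir_levels],
        pad_mode=pad_mode,
    )


def nsct_reconstruct(pyr: NsctPyramid, filters: FilterBank | None = None) -> np.ndarray:
    """Exact inverse of :func:`nsct_decompose`.

    With delta synthesis filters the inverse is the sum of the lowpass and
    all bandpass subbands; no clipping is applied here.
    """
    pyr.validate_shapes()
    out = pyr.lowpass.astype(float).copy()
    for _, sub in pyr.subbands():
        out += sub
    return out
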