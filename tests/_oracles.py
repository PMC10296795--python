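"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, literal definitions)
and shares no code with the package implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, signal


# ---------------------------------------------------------------- OMP oracle
def naive_omp(x, D, tolerance, max_nonzeros):
    """Greedy OMP, one signal, explicit per-step argmax + lstsq re-solve."""
    r = x.astype(float).copy()
    support: list[int] = []
    coef = np.zeros(D.shape[1])
    sol = np.zeros(0)
    while len(support) < max_nonzeros and np.linalg.norm(r) >= tolerance:
        corr = np.abs(D.T @ r)
        corr[support] = -1.0
        j = int(np.argmax(corr))  # lowest index wins ties
        if corr[j] <= 1e-13:
            break
        support.append(j)
        sol, *_ = np.linalg.lstsq(D[:, support], x, rcond=None)
        r = x - D[:, support] @ sol
    if support:
        coef[support] = sol
    return support, coef


# ------------------------------------------------- spatial-frequency oracle
def _reflect_get(H, i, j):
    h, w = H.shape
    i = -i if i < 0 else (2 * h - 2 - i if i >= h else i)
    j = -j if j < 0 else (2 * w - 2 - j if j >= w else j)
    return H[i, j]


def sf_bruteforce(H, M, N, literal=True):
    """Direct double loop over the window; reflect (mirror) padding.

    Horizontal differences use pixel pairs fully inside the window (the
    window's first column contributes no term), vertical likewise.
    """
    h, w = H.shape
    RF = np.zeros((h, w))
    CF = np.zeros((h, w))
    m2, n2 = M // 2, N // 2
    for i in range(h):
        for j in range(w):
            srf = 0.0
            scf = 0.0
            for a in range(-m2, m2 + 1):
                for b in range(-n2, n2 + 1):
                    if b > -n2:
                        d = _reflect_get(H, i + a, j + b) - _reflect_get(H, i + a, j + b - 1)
                        srf += d * d
                    if a > -m2:
                        d = _reflect_get(H, i + a, j + b) - _reflect_get(H, i + a - 1, j + b)
                        scf += d * d
            RF[i, j] = srf / (M * N)
            CF[i, j] = scf / (M * N)
    if not literal:
        RF = np.sqrt(RF)
        CF = np.sqrt(CF)
    return np.sqrt(RF**2 + CF**2), RF, CF


def local_mean_bruteforce(S, p, q):
    h, w = S.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(-(p // 2), p // 2 + 1):
                for b in range(-(q // 2), q // 2 + 1):
                    acc += _reflect_get(S, i + a, j + b)
            out[i, j] = acc / (p * q)
    return out


def area_open_bruteforce(mask, r, C, fill_background=True):
    """Connected-component labelling (scipy) + explicit area threshold."""
    thr = math.ceil(r * C)
    eight = np.ones((3, 3), dtype=int)

    def _open(m):
        lab, n = ndimage.label(m, structure=eight)
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= thr
        return keep[lab]

    out = _open(mask.astype(bool))
    if fill_background:
        out = ~_open(~out)
    return out.astype(np.uint8)


def majority_bruteforce(mask, N):
    h, w = mask.shape
    out = np.zeros((h, w), dtype=np.uint8)
    n2 = N // 2
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(-n2, n2 + 1):
                for b in range(-n2, n2 + 1):
                    acc += _reflect_get(mask.astype(float), i + a, j + b)
            out[i, j] = 1 if acc > N * N / 2.0 else 0
    return out


# ---------------------------------------------------- NSCT equivalent kernels
def _delta():
    return np.ones((1, 1))


def _ksub(a, b):
    """Centered kernel subtraction a - b (zero-phase odd-sized kernels)."""
    rows = max(a.shape[0], b.shape[0])
    cols = max(a.shape[1], b.shape[1])
    out = np.zeros((rows, cols))
    for k, s in ((a, 1.0), (b, -1.0)):
        r0 = (rows - k.shape[0]) // 2
        c0 = (cols - k.shape[1]) // 2
        out[r0 : r0 + k.shape[0], c0 : c0 + k.shape[1]] += s * k
    return out


def _upsample(kernel, factor):
    if factor == 1:
        return kernel
    out = np.zeros(((kernel.shape[0] - 1) * factor + 1, (kernel.shape[1] - 1) * factor + 1))
    out[::factor, ::factor] = kernel
    return out


def _qup(kernel):
    rc, cc = kernel.shape[0] // 2, kernel.shape[1] // 2
    half = (kernel.shape[0] - 1) // 2 + (kernel.shape[1] - 1) // 2
    out = np.zeros((2 * half + 1, 2 * half + 1))
    for i in range(kernel.shape[0]):
        for j in range(kernel.shape[1]):
            a, b = i - rc, j - cc
            out[a + b + half, b - a + half] = kernel[i, j]
    return out


def equivalent_kernels(n_levels, dir_levels, h0, f0):
    """Literal a-trous composition of the full analysis bank.

    Returns (subband kernels in (u, k) order, final lowpass kernel), each a
    single explicit 2-D kernel whose plain convolution with the input equals
    the corresponding transform subband.
    """
    kernels = {}
    low = _delta()
    for u in range(1, n_levels + 1):
        h0u = _upsample(h0, 2 ** (u - 1))
        new_low = signal.convolve2d(low, h0u)
        detail = _ksub(low, new_low)
        lev = dir_levels[u - 1]
        if lev == 0:
            subs = [detail]
        else:
            d0 = signal.convolve2d(detail, f0)
            d1 = _ksub(detail, d0)
            if lev == 1:
                subs = [d0, d1]
            else:
                fq = _qup(f0)
                subs = []
                for d in (d0, d1):
                    c0 = signal.convolve2d(d, fq)
                    subs.extend([c0, _ksub(d, c0)])
        for k, s in enumerate(subs, 1):
            kernels[(u, k)] = s
        low = new_low
    return kernels, low


def circular_convolve(image, kernel):
    """Exact circular convolution with a centered zero-phase kernel via FFT."""
    h, w = image.shape
    emb = np.zeros((h, w))
    rc, cc = kernel.shape[0] // 2, kernel.shape[1] // 2
    for i in range(kernel.shape[0]):
        for j in range(kernel.shape[1]):
            emb[(i - rc) % h, (j - cc) % w] += kernel[i, j]
    return np.real(np.fft.ifft2(np.fft.fft2(image) * np.fft.fft2(emb)))


# ----------------------------------------------------------- AMD band oracle
def band_split_bruteforce(frames, frame_rate, cutoff_hz):
    """Per-pixel explicit DFT bin masking (full complex FFT, loop over pixels)."""
    T, h, w = frames.shape
    freqs = np.abs(np.fft.fftfreq(T, d=1.0 / frame_rate))
    dyn = np.zeros_like(frames)
    stat = np.zeros_like(frames)
    for i in range(h):
        for j in range(w):
            spec = np.fft.fft(frames[:, i, j])
            dyn[:, i, j] = np.real(np.fft.ifft(np.where(freqs > cutoff_hz, spec, 0)))
            stat[:, i, j] = np.real(np.fft.ifft(np.where(freqs <= cutoff_hz, spec, 0)))
    return dyn, stat


# -------------------------------------------------------- histogram metrics
def joint_counts(x_levels, y_levels):
    """Plain dict-of-pairs joint histogram (independent of np.bincount path)."""
    counts: dict[tuple[int, int], int] = {}
    for a, b in zip(x_levels.ravel().tolist(), y_levels.ravel().tolist()):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def mi_from_counts(counts):
    """Mutual information (nats) and marginal entropies from a pair-count dict."""
    n = sum(counts.values())
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    for (a, b), c in counts.items():
        px[a] = px.get(a, 0.0) + c / n
        py[b] = py.get(b, 0.0) + c / n
    hx = -sum(p * math.log(p) for p in px.values())
    hy = -sum(p * math.log(p) for p in py.values())
    mi = 0.0
    for (a, b), c in counts.items():
        p = c / n
        mi += p * math.log(p / (px[a] * py[b]))
    return mi, hx, hy
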