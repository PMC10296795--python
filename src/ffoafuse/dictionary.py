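"""Patch extraction, K-SVD dictionary learning and orthogonal matching pursuit.

These are the sparse-representation primitives behind the low-pass fusion
rule: the low-pass subbands are cut into overlapping 8x8 blocks with a
sliding window, each block is raster-scanned (column-major) into a length-64
vector, and the vectors are sparse-coded over a redundant learned dictionary.

``omp_encode`` is a vectorised batch OMP (precomputed Gram matrix, batched
normal-equation solves); ``ksvd_train`` alternates monotone sparse coding
with exact rank-1 SVD atom updates, so the logged mean representation error
is non-increasing by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DimensionError, ValidationError

__all__ = [
    "PatchGrid",
    "Dictionary",
    "SparseCodes",
    "extract_patches",
    "reassemble_patches",
    "omp_encode",
    "ksvd_train",
    "save_dictionary",
    "load_dictionary",
]


@dataclass
class PatchGrid:
    """All sliding-window patches of an image, as columns.

    ``patches[:, l]`` is patch ``l`` raster-scanned column-major;
    ``positions[l]`` is its (row, col) top-left anchor.  Anchors enumerate
    top-to-bottom then left-to-right with the given stride; the final
    row/column anchor is clamped to the border so coverage is complete.
    """

    patches: np.ndarray
    positions: list[tuple[int, int]]
    patch_size: int
    step: int
    source_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.patches.shape[1]


def _anchors(extent: int, patch: int, step: int) -> list[int]:
    pos = list(range(0, extent - patch + 1, step))
    if pos[-1] != extent - patch:
        pos.append(extent - patch)
    return pos


def extract_patches(image: np.ndarray, patch_size: int = 8, step: int = 1) -> PatchGrid:
    """Divide ``image`` into overlapping ``patch_size`` blocks with stride ``step``."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("extract_patches expects a 2-D image")
    if patch_size > min(image.shape):
        raise DimensionError(
            f"patch size {patch_size} exceeds image extent {image.shape}"
        )
    if not 1 <= step <= patch_size:
        raise ConfigurationError(
            f"step must be in [1, patch_size]; step={step} would leave coverage gaps"
        )
    rows = _anchors(image.shape[0], patch_size, step)
    cols = _anchors(image.shape[1], patch_size, step)
    positions = [(r, c) for c in cols for r in rows]  # top-to-bottom, then left-to-right
    cols_out = np.empty((patch_size * patch_size, len(positions)))
    for l, (r, c) in enumerate(positions):
        cols_out[:, l] = image[r : r + patch_size, c : c + patch_size].ravel(order="F")
    return PatchGrid(cols_out, positions, patch_size, step, image.shape)


def reassemble_patches(
    patches: np.ndarray,
    positions: list[tuple[int, int]],
    patch_size: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Inverse of :func:`extract_patches`: paste patch columns back, averaging overlaps.

    Every pixel is covered by at least one patch (clamped anchors), so the
    output is a per-pixel convex combination of decoded patch contents.
    """
    acc = np.zeros(shape)
    cover = np.zeros(shape)
    for l, (r, c) in enumerate(positions):
        block = patches[:, l].reshape((patch_size, patch_size), order="F")
        acc[r : r + patch_size, c : c + patch_size] += block
        cover[r : r + patch_size, c : c + patch_size] += 1.0
    if np.any(cover == 0):
        raise DimensionError("patch grid does not cover the full image")
    return acc / cover


@dataclass
class Dictionary:
    """A learned redundant patch dictionary: unit-norm atom columns."""

    atoms: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def atom_length(self) -> int:
        return self.atoms.shape[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.atoms)):
            raise ValidationError("dictionary contains non-finite entries")
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValidationError("dictionary atoms are not unit-norm")
        gram = np.abs(self.atoms.T @ self.atoms)
        np.fill_diagonal(gram, 0.0)
        if gram.max() >= 1.0 - 1e-8:
            raise ValidationError("dictionary contains (near-)duplicate atoms")


@dataclass
class SparseCodes:
    """Per-patch sparse coefficient vectors, one dense column per patch."""

    coefficients: np.ndarray  # (n_atoms, W)
    tolerance: float
    max_nonzeros: int
    residual_norms: np.ndarray | None = None

    def l1_norms(self) -> np.ndarray:
        return np.abs(self.coefficients).sum(axis=0)


def omp_encode(
    signals: np.ndarray,
    dictionary: Dictionary,
    tolerance: float = 0.01,
    max_nonzeros: int = 8,
) -> SparseCodes:
    """Greedy orthogonal matching pursuit, batched over signal columns.

    At each step the atom with the largest absolute correlation with the
    current residual is added (ties broken toward the lowest atom index),
    the coefficients are re-solved by least squares on the active set, and
    the residual is updated.  A signal stops when its residual 2-norm drops
    below ``tolerance`` or ``max_nonzeros`` atoms are active.
    """
    X = np.asarray(signals, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    D = dictionary.atoms
    if X.shape[0] != D.shape[0]:
        raise DimensionError(
            f"signal length {X.shape[0]} != atom length {D.shape[0]}"
        )
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    n_atoms, W = D.shape[1], X.shape[1]
    max_nonzeros = min(max_nonzeros, n_atoms, X.shape[0])

    G = D.T @ D
    alpha0 = D.T @ X  # (n_atoms, W)
    norms2 = np.einsum("ij,ij->j", X, X)
    tol2 = tolerance * tolerance

    C = np.zeros((n_atoms, W))
    residual2 = norms2.copy()
    active = residual2 >= tol2 if tolerance > 0 else residual2 > 0
    supports = np.full((max_nonzeros, W), -1, dtype=int)
    chosen = np.zeros((n_atoms, W), dtype=bool)
    alpha = alpha0.copy()

    for k in range(max_nonzeros):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        a = np.abs(alpha[:, idx])
        a[chosen[:, idx]] = -1.0
        best = np.argmax(a, axis=0)  # argmax returns the first (lowest) index on ties
        peak = a[best, np.arange(idx.size)]
        dead = peak <= 1e-13  # residual orthogonal to all remaining atoms
        if dead.any():
            active[idx[dead]] = False
            idx = idx[~dead]
            best = best[~dead]
            if idx.size == 0:
                break
        supports[k, idx] = best
        chosen[best, idx] = True

        S = supports[: k + 1, idx]  # (k+1, n_act)
        St = S.T  # (n_act, k+1)
        Gs = G[St[:, :, None], St[:, None, :]]  # (n_act, k+1, k+1)
        b = alpha0[S, idx[None, :]].T  # (n_act, k+1)
        coef = np.linalg.solve(Gs, b[..., None])[..., 0]  # (n_act, k+1)

        C[:, idx] = 0.0
        C[S, idx[None, :]] = coef.T
        residual2[idx] = np.maximum(norms2[idx] - np.einsum("ij,ij->i", coef, b), 0.0)
        # update correlations for the next selection step
        contrib = np.einsum("ksm,sk->ms", G[S], coef)
        alpha[:, idx] = alpha0[:, idx] - contrib
        if tolerance > 0:
            active[idx] = residual2[idx] >= tol2
    return SparseCodes(C, tolerance, max_nonzeros, np.sqrt(residual2))


def _code_residuals(X: np.ndarray, D: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.linalg.norm(X - D @ C, axis=0)


def ksvd_train(
    training_patches: np.ndarray,
    n_atoms: int = 256,
    max_nonzeros: int = 8,
    n_iterations: int = 30,
    seed: int = 42,
    tolerance: float = 0.0,
) -> Dictionary:
    """Learn a redundant unit-norm patch dictionary with K-SVD.

    Alternates (a) batch-OMP sparse coding, keeping a signal's previous code
    whenever it beats the fresh one, with (b) sequential exact rank-1 SVD
    updates of each atom and its active coefficients.  Unused atoms are
    re-initialised from the worst-represented training signals.  The mean
    residual logged after each coding stage (``metadata["errors"]``) is
    therefore non-increasing.  Deterministic given ``seed``.
    """
    X = np.asarray(training_patches, dtype=float)
    if X.ndim != 2:
        raise ValidationError("training_patches must be (signal_length, n_signals)")
    dim, n_signals = X.shape
    if n_atoms <= dim:
        raise ConfigurationError(
            f"dictionary must be redundant: n_atoms={n_atoms} must exceed signal length {dim}"
        )
    rng = np.random.default_rng(seed)

    if n_signals < n_atoms:
        warnings.warn(
            f"training set ({n_signals} signals) smaller than n_atoms={n_atoms}; "
            "re-initialising atoms from random training patches with replacement",
            stacklevel=2,
        )
        pick = rng.integers(0, n_signals, size=n_atoms)
        D = X[:, pick] + 1e-6 * rng.standard_normal((dim, n_atoms))
    else:
        pick = rng.choice(n_signals, size=n_atoms, replace=False)
        D = X[:, pick].copy()
    D = D + np.where(np.linalg.norm(D, axis=0) < 1e-12, 1.0, 0.0) * rng.standard_normal(
        (dim, n_atoms)
    ) * 1e-3  # guard against all-zero initial atoms
    D /= np.linalg.norm(D, axis=0)
    # distinct patch indices can still carry identical content (e.g. flat
    # background blocks); jitter repeats so every initial atom is distinct
    for _ in range(20):
        gram = np.abs(D.T @ D)
        np.fill_diagonal(gram, 0.0)
        dup = np.argwhere(np.triu(gram, 1) >= 1.0 - 1e-8)
        if dup.size == 0:
            break
        cols = np.unique(dup[:, 1])
        D[:, cols] += 1e-3 * rng.standard_normal((dim, cols.size))
        D[:, cols] /= np.linalg.norm(D[:, cols], axis=0)

    errors: list[float] = []
    C_prev: np.ndarray | None = None
    dict_obj = Dictionary(D)
    for _ in range(n_iterations):
        codes = omp_encode(X, dict_obj, tolerance=tolerance, max_nonzeros=max_nonzeros)
        C = codes.coefficients
        if C_prev is not None:
            res_new = _code_residuals(X, D, C)
            res_old = _code_residuals(X, D, C_prev)
            keep_old = res_old < res_new
            C[:, keep_old] = C_prev[:, keep_old]
        errors.append(float(np.mean(_code_residuals(X, D, C))))

        # atom updates: exact rank-1 SVD on the restricted residual
        R_full = X - D @ C
        for j in range(n_atoms):
            users = np.flatnonzero(C[j] != 0.0)
            if users.size == 0:
                continue
            Ej = R_full[:, users] + np.outer(D[:, j], C[j, users])
            U, s, Vt = np.linalg.svd(Ej, full_matrices=False)
            D[:, j] = U[:, 0]
            C[j, users] = s[0] * Vt[0]
            R_full[:, users] = Ej - np.outer(D[:, j], C[j, users])
        # refresh unused atoms from the worst-coded signals (does not change
        # the current representation, so monotonicity is preserved)
        unused = np.flatnonzero(np.all(C == 0.0, axis=1))
        if unused.size:
            res = _code_residuals(X, D, C)
            worst = np.argsort(res)[::-1][: unused.size]
            repl = X[:, worst] + 1e-8 * rng.standard_normal((dim, unused.size))
            norms = np.linalg.norm(repl, axis=0)
            norms[norms < 1e-12] = 1.0
            D[:, unused] = repl / norms
        C_prev = C
        dict_obj = Dictionary(D)

    meta = {
        "n_atoms": n_atoms,
        "max_nonzeros": max_nonzeros,
        "n_iterations": n_iterations,
        "seed": seed,
        "tolerance": tolerance,
        "n_training_patches": n_signals,
        "errors": errors,
    }
    return Dictionary(D, meta)


def save_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    """Write atoms as a whitespace-delimited text matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, dictionary.atoms)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dictionary.metadata, indent=2))


def load_dictionary(path: str | Path) -> Dictionary:
    path = Path(path)
    atoms = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    d = Dictionary(atoms, meta)
    d.validate()
    return d
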