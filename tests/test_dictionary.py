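"""Patch grids, OMP sparse coding, and K-SVD learning."""

import warnings

import numpy as np
import pytest

from ffoafuse.dictionary import (
    Dictionary,
    extract_patches,
    ksvd_train,
    load_dictionary,
    omp_encode,
    reassemble_patches,
    save_dictionary,
)
from ffoafuse.exceptions import ConfigurationError, DimensionError, ValidationError

from _oracles import naive_omp


# ----------------------------------------------------------------- patches
def test_single_patch_degenerate_tiling():
    img = np.arange(64, dtype=float).reshape(8, 8)
    grid = extract_patches(img, 8, 1)
    assert grid.n_patches == 1
    assert grid.positions == [(0, 0)]
    np.testing.assert_array_equal(
        grid.patches[:, 0].reshape(8, 8, order="F"), img
    )


@pytest.mark.parametrize(
    "shape,step,expected_anchors",
    [
        ((16, 16), 4, [0, 4, 8]),
        ((10, 10), 8, [0, 2]),  # final anchor clamped to the border
    ],
)
def test_anchor_enumeration(shape, step, expected_anchors):
    grid = extract_patches(np.zeros(shape), 8, step)
    rows = sorted({p[0] for p in grid.positions})
    cols = sorted({p[1] for p in grid.positions})
    assert rows == expected_anchors and cols == expected_anchors
    assert grid.n_patches == len(expected_anchors) ** 2


def test_patch_roundtrip_is_identity():
    img = np.random.default_rng(0).random((21, 17))
    grid = extract_patches(img, 8, 5)
    out = reassemble_patches(grid.patches, grid.positions, 8, img.shape)
    np.testing.assert_allclose(out, img, atol=1e-12)


def test_patch_parameter_errors():
    with pytest.raises(ConfigurationError):
        extract_patches(np.zeros((16, 16)), 8, 9)  # coverage gap
    with pytest.raises(DimensionError):
        extract_patches(np.zeros((6, 16)), 8, 1)


# --------------------------------------------------------------------- OMP
def test_omp_recovers_exact_atom():
    rng = np.random.default_rng(1)
    D = rng.standard_normal((64, 80))
    D /= np.linalg.norm(D, axis=0)
    codes = omp_encode(3.0 * D[:, 17], Dictionary(D), tolerance=1e-8, max_nonzeros=4)
    c = codes.coefficients[:, 0]
    assert np.flatnonzero(c).tolist() == [17]
    assert c[17] == pytest.approx(3.0, abs=1e-10)


def test_omp_zero_signal_gives_empty_code():
    rng = np.random.default_rng(2)
    D = rng.standard_normal((8, 16))
    D /= np.linalg.norm(D, axis=0)
    codes = omp_encode(np.zeros((8, 3)), Dictionary(D), 0.01, 2)
    assert np.abs(codes.coefficients).max() == 0.0
    assert np.abs(codes.residual_norms).max() == 0.0


@pytest.mark.parametrize("seed", range(4))
def test_omp_matches_bruteforce_greedy_oracle(seed):
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((8, 16))
    D /= np.linalg.norm(D, axis=0)
    X = rng.standard_normal((8, 40))
    codes = omp_encode(X, Dictionary(D), tolerance=1e-6, max_nonzeros=2)
    for i in range(X.shape[1]):
        support, coef = naive_omp(X[:, i], D, 1e-6, 2)
        got = codes.coefficients[:, i]
        assert set(np.flatnonzero(got)) == set(support)
        np.testing.assert_allclose(got, coef, atol=1e-8)


def test_omp_residuals_nonincreasing_in_sparsity():
    """Allowing one more atom can only shrink each signal's residual."""
    rng = np.random.default_rng(5)
    D = rng.standard_normal((16, 40))
    D /= np.linalg.norm(D, axis=0)
    X = rng.standard_normal((16, 30))
    prev = None
    for k in range(1, 6):
        res = omp_encode(X, Dictionary(D), tolerance=1e-12, max_nonzeros=k).residual_norms
        if prev is not None:
            assert np.all(res <= prev + 1e-10)
        prev = res


def test_omp_meets_tolerance_when_sparsity_not_binding():
    rng = np.random.default_rng(6)
    D = rng.standard_normal((8, 32))
    D /= np.linalg.norm(D, axis=0)
    X = rng.standard_normal((8, 20))
    codes = omp_encode(X, Dictionary(D), tolerance=0.05, max_nonzeros=8)
    # max_nonzeros = signal dimension: the greedy LS can always reach any
    # tolerance, so every residual must be below it
    assert np.all(codes.residual_norms < 0.05)


def test_omp_shape_mismatch():
    D = np.eye(8)[:, :5] * 1.0
    with pytest.raises(DimensionError):
        omp_encode(np.zeros((9, 2)), Dictionary(D), 0.01, 2)


# ------------------------------------------------------------------- K-SVD
def test_ksvd_memorisation_regime():
    """With as many atoms as distinct training vectors and sparsity 1, the
    dictionary memorises the training set: mean residual ~ 0."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((64, 256))
    X /= np.linalg.norm(X, axis=0)
    d = ksvd_train(X, n_atoms=256, max_nonzeros=1, n_iterations=2, seed=1)
    assert d.metadata["errors"][-1] < 1e-8


def test_ksvd_monotone_and_recovers_planted_atoms():
    rng = np.random.default_rng(8)
    gen = rng.standard_normal((64, 3))
    gen /= np.linalg.norm(gen, axis=0)
    coefs = rng.uniform(0.2, 1.0, (3, 800)) * (rng.random((3, 800)) < 0.5)
    coefs[:, coefs.sum(axis=0) == 0] = 0.5
    X = gen @ coefs + 0.01 * rng.standard_normal((64, 800))
    d = ksvd_train(X, n_atoms=80, max_nonzeros=3, n_iterations=15, seed=9)
    errs = d.metadata["errors"]
    assert all(errs[i + 1] <= errs[i] + 1e-9 for i in range(len(errs) - 1))
    corr = np.abs(gen.T @ d.atoms).max(axis=1)
    assert np.all(corr > 0.99)
    d.validate()


def test_ksvd_deterministic_given_seed():
    rng = np.random.default_rng(10)
    X = rng.standard_normal((64, 400))
    a = ksvd_train(X, n_atoms=70, max_nonzeros=3, n_iterations=3, seed=11)
    b = ksvd_train(X, n_atoms=70, max_nonzeros=3, n_iterations=3, seed=11)
    np.testing.assert_array_equal(a.atoms, b.atoms)


def test_ksvd_small_corpus_warns_and_reinitialises():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((64, 50))
    with pytest.warns(UserWarning, match="smaller than n_atoms"):
        d = ksvd_train(X, n_atoms=72, max_nonzeros=2, n_iterations=1, seed=13)
    assert d.n_atoms == 72
    np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-10)


def test_ksvd_rejects_non_redundant_dictionary():
    with pytest.raises(ConfigurationError):
        ksvd_train(np.zeros((64, 100)), n_atoms=64)


# ---------------------------------------------------------- persistence
def test_dictionary_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(14)
    D = rng.standard_normal((64, 72))
    D /= np.linalg.norm(D, axis=0)
    d = Dictionary(D, {"note": "test"})
    path = tmp_path / "dict.txt"
    save_dictionary(d, path)
    loaded = load_dictionary(path)
    np.testing.assert_allclose(loaded.atoms, D, atol=1e-12)
    assert loaded.metadata["note"] == "test"


def test_dictionary_validation_rejects_bad_atoms():
    with pytest.raises(ValidationError, match="unit-norm"):
        Dictionary(np.ones((64, 70))).validate()
    a = np.random.default_rng(15).standard_normal((64, 70))
    a /= np.linalg.norm(a, axis=0)
    a[:, 1] = a[:, 0]
    with pytest.raises(ValidationError, match="duplicate"):
        Dictionary(a).validate()
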