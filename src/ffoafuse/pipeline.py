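"""End-to-end multi-focus fusion pipeline.

``fuse_pair`` runs the full method on two co-registered grayscale images:
NSCT decomposition, sparse-representation (l1-max) fusion of the low-pass
subbands, contrast-spatial-frequency fusion of every directional bandpass
pair, and inverse NSCT with a final clip to [0, 1].  ``fuse_sequence``
left-folds a focal stack (n images -> n-1 pairwise fusions).

All tunables live in :class:`FusionConfig`; the shipped defaults are the
method's chosen operating point ({Q=4, dirs {2,2,2,2}, M=N=7, p=q=7,
r=0.05, N_cv=59}) and are echoed to the module logger on every run.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .bandpass_fusion import DecisionMap, build_decision_map, fuse_bandpass_subband
from .dictionary import Dictionary, ksvd_train, load_dictionary, extract_patches
from .exceptions import ConfigurationError, DimensionError, ValidationError
from .lowpass_fusion import fuse_lowpass
from .nsct import build_filter_banks, nsct_decompose, nsct_reconstruct

__all__ = [
    "FusionConfig",
    "fuse_pair",
    "fuse_sequence",
    "train_default_dictionary",
]

logger = logging.getLogger("ffoafuse")


@dataclass
class FusionConfig:
    """Parameters of the fusion pipeline (defaults = the method's operating point)."""

    n_levels: int = 4
    dir_levels: tuple[int, ...] = (2, 2, 2, 2)
    pyramid_filter: str = "pyrexc"
    directional_filter: str = "vk"
    sf_window: int = 7  # M = N
    contrast_window: int = 7  # p = q
    area_fraction: float = 0.05  # r
    consistency_window: int = 59  # N of the majority vote
    patch_size: int = 8
    patch_step: int = 1  # lambda
    omp_tolerance: float = 0.01  # delta
    max_nonzeros: int = 8
    literal_sf: bool = True
    fill_background: bool = True
    dictionary_path: str | None = None
    seed: int = 42

    def __post_init__(self):
        self.dir_levels = tuple(int(d) for d in self.dir_levels)
        if len(self.dir_levels) != self.n_levels:
            raise ConfigurationError(
                f"dir_levels must have n_levels={self.n_levels} entries, "
                f"got {len(self.dir_levels)}"
            )
        for name in ("sf_window", "contrast_window", "consistency_window"):
            if getattr(self, name) % 2 == 0:
                raise ConfigurationError(f"{name} must be odd")
        if not 0.0 < self.area_fraction < 1.0:
            raise ConfigurationError("area_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FusionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["dir_levels"] = list(self.dir_levels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def describe(self) -> str:
        return (
            f"Q={self.n_levels} dirs={list(self.dir_levels)} "
            f"filters=({self.pyramid_filter},{self.directional_filter}) "
            f"M=N={self.sf_window} p=q={self.contrast_window} "
            f"r={self.area_fraction} N_cv={self.consistency_window} "
            f"patch={self.patch_size} step={self.patch_step} "
            f"delta={self.omp_tolerance} max_nonzeros={self.max_nonzeros}"
        )


def train_default_dictionary(
    seed: int = 42,
    n_atoms: int = 256,
    n_iterations: int = 30,
    n_patches: int = 20000,
    patch_size: int = 8,
    max_nonzeros: int = 8,
) -> Dictionary:
    """Train the default patch dictionary on a synthetic vessel-phantom corpus.

    The corpus is a set of seeded vessel phantoms (plus their partially
    blurred versions, so smooth defocused patches are represented too); no
    external image collection is required.  Deterministic given ``seed``.
    """
    from scipy import ndimage as _ndi

    from .synthetic_data import make_vessel_phantom

    rng = np.random.default_rng(seed)
    pool = []
    n_images = 8
    per_image = int(np.ceil(n_patches / (2 * n_images)))
    for i in range(n_images):
        img = make_vessel_phantom(160, 160, n_vessels=7, seed=seed * 1000 + i)
        for variant in (img, _ndi.gaussian_filter(img, 2.0)):
            grid = extract_patches(variant, patch_size, step=3)
            take = rng.choice(grid.n_patches, size=min(per_image, grid.n_patches), replace=False)
            pool.append(grid.patches[:, take])
    patches = np.concatenate(pool, axis=1)[:, :n_patches]
    logger.info(
        "training default dictionary: %d atoms, %d iterations, %d patches, seed %d",
        n_atoms, n_iterations, patches.shape[1], seed,
    )
    return ksvd_train(
        patches,
        n_atoms=n_atoms,
        max_nonzeros=max_nonzeros,
        n_iterations=n_iterations,
        seed=seed,
    )


def _validate_pair(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise DimensionError(f"source shapes differ: {A.shape} vs {B.shape}")
    for name, img in (("A", A), ("B", B)):
        if img.ndim != 2:
            raise ValidationError(f"source {name} must be 2-D grayscale")
        if not np.all(np.isfinite(img)):
            raise ValidationError(f"source {name} contains non-finite pixels")
        if img.min() < -1e-9 or img.max() > 1 + 1e-9:
            raise ValidationError(f"source {name} must be normalised to [0, 1]")
    return A, B


def _resolve_dictionary(cfg: FusionConfig, dictionary: Dictionary | None) -> Dictionary:
    if dictionary is not None:
        return dictionary
    if cfg.dictionary_path is not None:
        return load_dictionary(cfg.dictionary_path)
    logger.warning("no dictionary supplied; training a reduced default (slow path)")
    return train_default_dictionary(
        seed=cfg.seed, n_atoms=128, n_iterations=10, n_patches=6000,
        patch_size=cfg.patch_size, max_nonzeros=cfg.max_nonzeros,
    )


def fuse_pair(
    A: np.ndarray,
    B: np.ndarray,
    cfg: FusionConfig | None = None,
    dictionary: Dictionary | None = None,
    return_details: bool = False,
):
    """Fuse two co-registered multi-focus images into one all-in-focus image.

    Returns the fused image clipped to [0, 1]; with ``return_details`` also
    a dict holding the two pyramids, the fused pyramid and the per-subband
    :class:`DecisionMap` stages.  Deterministic given config + dictionary.
    """
    cfg = cfg or FusionConfig()
    A, B = _validate_pair(A, B)
    logger.info("fusion config: %s", cfg.describe())
    dictionary = _resolve_dictionary(cfg, dictionary)
    filters = build_filter_banks(cfg.pyramid_filter, cfg.directional_filter)

    pyrA = nsct_decompose(A, cfg.n_levels, cfg.dir_levels, filters)
    pyrB = nsct_decompose(B, cfg.n_levels, cfg.dir_levels, filters)
    logger.info(
        "decomposed %s into lowpass %s + %d bandpass subbands",
        A.shape, pyrA.lowpass.shape, len(pyrA.bandpass),
    )

    fused_low = fuse_lowpass(
        pyrA.lowpass,
        pyrB.lowpass,
        dictionary,
        step=cfg.patch_step,
        tolerance=cfg.omp_tolerance,
        max_nonzeros=cfg.max_nonzeros,
        patch_size=cfg.patch_size,
    )

    fused_bands: dict[tuple[int, int], np.ndarray] = {}
    maps: dict[tuple[int, int], DecisionMap] = {}
    for key, HA in pyrA.bandpass.items():
        HB = pyrB.bandpass[key]
        dm = build_decision_map(
            HA,
            HB,
            sf_window=cfg.sf_window,
            contrast_window=cfg.contrast_window,
            area_fraction=cfg.area_fraction,
            consistency_window=cfg.consistency_window,
            literal_formulas=cfg.literal_sf,
            fill_background=cfg.fill_background,
        )
        fused_bands[key] = fuse_bandpass_subband(HA, HB, dm.final)
        maps[key] = dm

    fused_pyr = replace(pyrA)
    fused_pyr.lowpass = fused_low
    fused_pyr.bandpass = fused_bands
    F = np.clip(nsct_reconstruct(fused_pyr, filters), 0.0, 1.0)
    if return_details:
        return F, {"pyrA": pyrA, "pyrB": pyrB, "fused_pyramid": fused_pyr, "maps": maps}
    return F


def fuse_sequence(
    images: list[np.ndarray],
    cfg: FusionConfig | None = None,
    dictionary: Dictionary | None = None,
) -> np.ndarray:
    """Left-fold fusion of an ordered focal stack (n images, n-1 fusions)."""
    if images is None or len(images) < 2:
        raise ValidationError("fuse_sequence needs at least 2 images")
    cfg = cfg or FusionConfig()
    dictionary = _resolve_dictionary(cfg, dictionary)
    fused = np.asarray(images[0], dtype=float)
    for t, img in enumerate(images[1:], start=2):
        logger.info("fusion process %d of %d", t - 1, len(images) - 1)
        fused = fuse_pair(fused, img, cfg, dictionary)
    return fused
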