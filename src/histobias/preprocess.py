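"""TMA spot preprocessing: tiling, stain normalization, ROI selection.

The pipeline turns per-spot RGB rasters into square, non-overlapping tiles
at several objective-equivalent magnifications, normalizes their colour
against a reference (Macenko stain-vector normalization, optionally followed
by dataset-statistics standardization), classifies each tile into one of
nine colorectal tissue classes, and keeps only the regions of interest
(tumour epithelium, lymphocytic infiltrates, mucin) — discarding whole
spots that retain no tumour epithelium at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import model as _model
from .synthgen import ROI_CLASSES, TISSUE_CLASSES

__all__ = [
    "SpotImage",
    "TileRecord",
    "MacenkoReference",
    "BlankTileWarning",
    "UnsupportedMagnificationError",
    "AugmentPolicy",
    "TissueClassifier",
    "extract_tiles",
    "fit_macenko_reference",
    "macenko_normalize",
    "dataset_stats_normalize",
    "rotate_tile",
    "augment",
    "train_tissue_classifier",
    "filter_rois",
    "exclude_spots",
    "tiles_to_network_input",
]

#: native microns-per-pixel corresponding to each magnification name;
#: "x0" is a whole-spot thumbnail rather than a fixed resolution.
MAGNIFICATION_MPP = {"x40": 0.25, "x20": 0.5, "x10": 1.0, "x5": 2.0}

# Background pre-filter: a tile is dropped when more than this fraction of
# its pixels has HSV saturation below the threshold (glass with no tissue).
BACKGROUND_SAT_THRESHOLD = 0.05
BACKGROUND_FRACTION = 0.80


class UnsupportedMagnificationError(ValueError):
    pass


class BlankTileWarning(UserWarning):
    pass


@dataclass
class SpotImage:
    """One TMA spot: an RGB raster plus its provenance identifiers."""

    pixels: np.ndarray
    mpp: float
    spot_id: str = ""
    patient: str = ""
    project: str = ""
    glass: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty H×W×3 raster")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")

    @classmethod
    def from_file(cls, path, mpp: float, **ids) -> "SpotImage":
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
        return cls(pixels=arr, mpp=mpp, **ids)


@dataclass
class TileRecord:
    """One extracted tile with its full metadata chain."""

    pixels: np.ndarray
    magnification: str
    row: int = 0
    col: int = 0
    tissue: Optional[str] = None
    spot_id: str = ""
    patient: str = ""
    project: str = ""
    glass: str = ""
    msi_label: Optional[str] = None

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("tile must be square H×H×3")
        if self.tissue is not None and self.tissue not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue!r}")
        if self.msi_label is not None and self.msi_label not in ("MSI-H", "MSS"):
            raise ValueError(f"msi_label must be 'MSI-H' or 'MSS'")


def _background_fraction(tile: np.ndarray) -> float:
    from skimage.color import rgb2hsv

    sat = rgb2hsv(np.asarray(tile, dtype=float) / 255.0)[..., 1]
    return float((sat < BACKGROUND_SAT_THRESHOLD).mean())


def extract_tiles(
    spot: SpotImage,
    magnifications: Sequence[str] = ("x20",),
    tile_px: int = 400,
    drop_background: bool = True,
) -> list:
    """Cut a spot into non-overlapping square tiles at each magnification.

    For a resolution magnification the native raster is downsampled by
    ``target_mpp / spot.mpp`` and a top-left-anchored, row-major grid of
    ``tile_px`` squares is cut; partial border tiles are discarded, so the
    count per magnification is ``floor(h/tile_px) * floor(w/tile_px)`` of
    the downsampled raster.  ``"x0"`` instead produces a single whole-spot
    thumbnail resized to ``tile_px``.  Tiles that are almost entirely
    unsaturated glass are dropped when ``drop_background`` is set.

    Raises :class:`UnsupportedMagnificationError` when the spot's native
    resolution is coarser than the requested magnification.
    """
    from skimage.transform import resize

    tiles = []
    native = np.asarray(spot.pixels, dtype=float)
    for mag in magnifications:
        if mag == "x0":
            thumb = resize(native, (tile_px, tile_px, 3), anti_aliasing=True,
                           preserve_range=True)
            img = np.clip(thumb, 0, 255).astype(np.uint8)
            if drop_background and _background_fraction(img) > BACKGROUND_FRACTION:
                continue
            tiles.append(TileRecord(pixels=img, magnification=mag, row=0, col=0,
                                    spot_id=spot.spot_id, patient=spot.patient,
                                    project=spot.project, glass=spot.glass))
            continue
        if mag not in MAGNIFICATION_MPP:
            raise UnsupportedMagnificationError(f"unknown magnification {mag!r}")
        factor = MAGNIFICATION_MPP[mag] / spot.mpp
        if factor < 1.0 - 1e-9:
            raise UnsupportedMagnificationError(
                f"{mag} needs {MAGNIFICATION_MPP[mag]} MPP but spot is at "
                f"{spot.mpp} MPP (coarser)"
            )
        if abs(factor - 1.0) < 1e-9:
            scaled = native
        else:
            h = int(round(native.shape[0] / factor))
            w = int(round(native.shape[1] / factor))
            scaled = resize(native, (h, w, 3), anti_aliasing=True,
                            preserve_range=True)
        n_rows = scaled.shape[0] // tile_px
        n_cols = scaled.shape[1] // tile_px
        for r in range(n_rows):
            for c in range(n_cols):
                img = np.clip(
                    scaled[r * tile_px:(r + 1) * tile_px,
                           c * tile_px:(c + 1) * tile_px], 0, 255
                ).astype(np.uint8)
                if drop_background and _background_fraction(img) > BACKGROUND_FRACTION:
                    continue
                tiles.append(TileRecord(
                    pixels=img, magnification=mag, row=r, col=c,
                    spot_id=spot.spot_id, patient=spot.patient,
                    project=spot.project, glass=spot.glass))
    return tiles


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

_OD_BETA = 0.15   # optical-density threshold excluding near-white pixels
_OD_ALPHA = 1.0   # robust percentile (degrees of the angle distribution)


@dataclass(frozen=True)
class MacenkoReference:
    """Target stain statistics: unit H/E stain vectors (columns of a 3×2
    optical-density matrix) and the reference 99th-percentile concentration
    of each stain."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray


def _rgb_to_od(img: np.ndarray) -> np.ndarray:
    return -np.log((np.asarray(img, dtype=float) + 1.0) / 256.0)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(256.0 * np.exp(-od) - 1.0, 0.0, 255.0)


def _estimate_stain_matrix(od_pixels: np.ndarray, alpha: float = _OD_ALPHA) -> np.ndarray:
    """Macenko plane fit: project tissue OD pixels onto the two leading
    eigenvectors of their covariance, take the robust extreme angles, and
    map them back to unit stain vectors (columns sorted so the more
    hematoxylin-like — larger blue OD — vector comes first)."""
    _, eigvecs = np.linalg.eigh(np.cov(od_pixels.T))
    plane = eigvecs[:, -2:]  # two leading eigenvectors
    # orient the plane so projections land in a consistent half-space
    if plane[:, 0].sum() < 0:
        plane[:, 0] *= -1
    if plane[:, 1].sum() < 0:
        plane[:, 1] *= -1
    proj = od_pixels @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    stains = np.stack([v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)], axis=1)
    if stains[2, 0] < stains[2, 1]:  # hematoxylin first (stronger blue OD)
        stains = stains[:, ::-1]
    return stains


def fit_macenko_reference(tile: np.ndarray, beta: float = _OD_BETA,
                          alpha: float = _OD_ALPHA) -> MacenkoReference:
    """Estimate reference stain statistics from a well-stained tile."""
    od = _rgb_to_od(tile).reshape(-1, 3)
    mask = (od > beta).any(axis=1)
    if mask.sum() < 10:
        raise ValueError("reference tile has too few stained pixels")
    stains = _estimate_stain_matrix(od[mask], alpha)
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    return MacenkoReference(
        stain_matrix=stains,
        max_concentrations=np.percentile(conc, 99, axis=1),
    )


def macenko_normalize(tile: np.ndarray, reference: MacenkoReference,
                      beta: float = _OD_BETA, alpha: float = _OD_ALPHA) -> np.ndarray:
    """Normalize a tile's stain appearance to the reference.

    The tile's own stain vectors are estimated by the Macenko plane-fitting
    construction, per-pixel stain concentrations are solved by least
    squares, rescaled so their 99th percentiles match the reference, and the
    image is rebuilt with the reference stain matrix.  A blank tile (no
    pixel above the OD threshold) is returned unchanged with a
    :class:`BlankTileWarning`.
    """
    tile = np.asarray(tile)
    od = _rgb_to_od(tile).reshape(-1, 3)
    mask = (od > beta).any(axis=1)
    if mask.sum() < 10:
        warnings.warn("blank tile: no above-threshold optical density",
                      BlankTileWarning, stacklevel=2)
        return tile.copy()
    stains = _estimate_stain_matrix(od[mask], alpha)
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    maxc = np.percentile(conc, 99, axis=1)
    maxc[maxc <= 1e-8] = 1e-8
    conc *= (reference.max_concentrations / maxc)[:, None]
    out = _od_to_rgb((reference.stain_matrix @ conc).T).reshape(tile.shape)
    return out.astype(np.uint8)


def dataset_stats_normalize(tile: np.ndarray, channel_stats,
                            enabled: bool = True) -> np.ndarray:
    """Channel-wise standardization to dataset-level target statistics.

    ``channel_stats`` is a ``(mean, sd)`` pair of length-3 arrays on the
    0–255 scale.  Each channel is standardized by its own mean/sd and
    re-expressed with the target statistics; the float result stays on the
    display scale but is deliberately not clipped, so the mapping is exactly
    invertible.  With ``enabled=False`` the tile passes through unchanged.
    """
    tile = np.asarray(tile, dtype=float)
    if not enabled:
        return tile
    mean_t, sd_t = (np.asarray(v, dtype=float) for v in channel_stats)
    own_mean = tile.reshape(-1, 3).mean(axis=0)
    own_sd = tile.reshape(-1, 3).std(axis=0)
    if np.any(own_sd < 1e-12) or np.any(sd_t < 1e-12):
        raise ValueError("zero standard deviation channel")
    return (tile - own_mean) / own_sd * sd_t + mean_t


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentPolicy:
    """Training-time augmentation ranges: random rotation up to
    ``rotate_max`` degrees, a dihedral flip with probability ``flip_p``,
    perspective warping up to ``warp_max`` (fraction of the side length)
    and a hue shift up to ``hue_max`` (HSV hue units)."""

    rotate_max: float = 90.0
    flip_p: float = 0.5
    warp_max: float = 0.2
    hue_max: float = 0.15
    enabled: bool = True


def rotate_tile(tile: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a tile; exact right-angle rotations use array permutation."""
    from skimage.transform import rotate as _sk_rotate

    q, r = divmod(angle, 90.0)
    if abs(r) < 1e-9 or abs(r - 90.0) < 1e-9:
        k = int(round(angle / 90.0))
        return np.rot90(tile, k=k, axes=(0, 1)).copy()
    out = _sk_rotate(np.asarray(tile, dtype=float) / 255.0, angle,
                     mode="reflect", order=1)
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


_DIHEDRAL = (
    lambda t: t[::-1],            # vertical flip
    lambda t: t[:, ::-1],         # horizontal flip
    lambda t: t[::-1, ::-1],      # 180°
    lambda t: np.swapaxes(t, 0, 1),           # transpose
    lambda t: np.swapaxes(t, 0, 1)[::-1],     # rot90
    lambda t: np.swapaxes(t, 0, 1)[:, ::-1],  # rot270
    lambda t: np.swapaxes(t[::-1, ::-1], 0, 1),  # anti-transpose
)


def augment(tile: np.ndarray, policy: AugmentPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation policy.

    Deterministic under a fixed generator state; a disabled policy returns
    the input untouched without consuming randomness.
    """
    if not policy.enabled:
        return np.asarray(tile).copy()
    from skimage.color import hsv2rgb, rgb2hsv
    from skimage.transform import ProjectiveTransform, warp

    out = np.asarray(tile)
    if policy.rotate_max > 0:
        out = rotate_tile(out, float(rng.uniform(-policy.rotate_max,
                                                 policy.rotate_max)))
    if rng.random() < policy.flip_p:
        out = _DIHEDRAL[int(rng.integers(len(_DIHEDRAL)))](out).copy()
    if policy.warp_max > 0:
        h, w = out.shape[:2]
        src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
        jitter = rng.uniform(-policy.warp_max, policy.warp_max, size=(4, 2))
        dst = src + jitter * np.array([w, h])
        if hasattr(ProjectiveTransform, "from_estimate"):
            tf = ProjectiveTransform.from_estimate(dst, src)
        else:  # older scikit-image
            tf = ProjectiveTransform()
            tf.estimate(dst, src)
        out = np.clip(warp(out.astype(float) / 255.0, tf, mode="reflect",
                           order=1) * 255.0, 0, 255).astype(np.uint8)
    if policy.hue_max > 0:
        hsv = rgb2hsv(out.astype(float) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-policy.hue_max,
                                                 policy.hue_max)) % 1.0
        out = np.clip(hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# tissue classifier
# ---------------------------------------------------------------------------

def tiles_to_network_input(images: np.ndarray, input_px: int) -> np.ndarray:
    """Block-average tiles down to ``input_px``² and flatten to [0, 1] rows.

    The cheap fixed "stem" in front of the trainable stacks; exact block
    means are used when the tile size divides evenly, bilinear resize
    otherwise.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    n, h, w, _ = images.shape
    if h == input_px and w == input_px:
        small = images
    elif h % input_px == 0 and w % input_px == 0:
        fh, fw = h // input_px, w // input_px
        small = images.reshape(n, input_px, fh, input_px, fw, 3).mean(axis=(2, 4))
    else:
        from skimage.transform import resize

        small = np.stack([
            resize(img, (input_px, input_px, 3), anti_aliasing=True,
                   preserve_range=True)
            for img in images
        ])
    # centred inputs keep the all-positive pixel scale from
    # saturating the first ReLU layer's activations
    return (small / 255.0 - 0.5).reshape(n, -1)


@dataclass
class TissueClassifier:
    """Nine-class tissue classifier: FE trunk + a two-hidden-layer head.

    The trunk has exactly the feature-extractor shape of the MSI system, so
    after tissue training it can be reused (head removed) as the FE
    initialisation of the end-to-end model.
    """

    spec: _model.NetworkSpec
    trunk: _model.DenseStack
    head: _model.DenseStack
    classes_: tuple

    @property
    def feature_extractor(self) -> _model.DenseStack:
        return self.trunk

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        X = tiles_to_network_input(images, self.spec.input_px)
        return _model.softmax(self.head.forward(self.trunk.forward(X, cache=False),
                                                cache=False))

    def predict(self, images: np.ndarray) -> np.ndarray:
        codes = self.predict_proba(images).argmax(axis=1)
        return np.asarray(self.classes_)[codes]


def train_tissue_classifier(
    images: np.ndarray,
    labels: Sequence[str],
    spec: Optional[_model.NetworkSpec] = None,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> TissueClassifier:
    """Train the nine-class tissue classifier on labeled tiles.

    Any real or synthetic 9-class tile set works; every class must be
    represented.  Mini-batch Adam on a mean cross-entropy; deterministic
    under ``seed``.
    """
    labels = np.asarray(labels)
    present = set(labels.tolist())
    missing = sorted(set(TISSUE_CLASSES) - present)
    if missing:
        raise ValueError(f"training data lacks tissue class(es): {missing}")
    spec = spec or _model.NetworkSpec()
    classes = tuple(sorted(present))
    y = np.searchsorted(np.asarray(classes), labels)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 21])))
    trunk = _model.DenseStack((spec.input_dim, 2 * spec.feature_dim,
                               spec.feature_dim), rng, final_relu=True)
    head = _model.DenseStack((spec.feature_dim, spec.head_hidden,
                              spec.head_hidden, len(classes)), rng,
                             final_relu=False)
    opt_t = _model.Adam(trunk.parameters(), lr=lr)
    opt_h = _model.Adam(head.parameters(), lr=lr)

    X = tiles_to_network_input(images, spec.input_px)
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            F = trunk.forward(X[idx])
            logits = head.forward(F)
            _, dlogits = _model.msi_loss_grad(y[idx], logits)
            dlogits /= len(idx)
            dF, g_head = head.backward(dlogits)
            _, g_trunk = trunk.backward(dF)
            opt_h.step(head.parameters(), g_head)
            opt_t.step(trunk.parameters(), g_trunk)
    return TissueClassifier(spec=spec, trunk=trunk, head=head, classes_=classes)


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------

def filter_rois(manifest: pd.DataFrame, keep: Iterable[str] = ROI_CLASSES,
                tissue_col: str = "tissue") -> pd.DataFrame:
    """Keep only tiles whose (predicted) tissue class is in ``keep``."""
    keep = set(keep)
    return manifest[manifest[tissue_col].isin(keep)].copy()


def exclude_spots(manifest: pd.DataFrame, spot_col: str = "spot",
                  tissue_col: str = "tissue",
                  required: str = "TUM") -> pd.DataFrame:
    """Drop every tile of any spot with no remaining tumour-epithelium tile.

    Mirrors the study-flow exclusion criterion: a spot that retains no
    viable tumour epithelium after ROI filtering is removed entirely.
    """
    has_tum = manifest.groupby(spot_col)[tissue_col].transform(
        lambda s: (s == required).any())
    return manifest[has_tum].copy()
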