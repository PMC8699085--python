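"""Synthetic TMA-like tile data with controllable batch effects.

Real tissue-microarray cohorts confound the biological signal with several
nuisance factors: the project a sample came from (different hospitals,
years, staining runs), the TMA glass a spot was mounted on (per-slide tint
picked up by background *and* tissue), and the patient's own tissue/staining
signature shared by all of that patient's tiles.  This module generates tile
datasets in which those factors are injected as pure colour/texture
overlays with known strengths, while the only biologically "real" class
signal is morphological: MSI-H tiles carry a higher density of dark
elliptical nuclei and pale mucin-like regions.

Because every nuisance factor is a construction knob, downstream components
(bias audit, adversarial ablation, evaluation) can be tested for exactly the
behaviours they claim: a removable confound must be removed, a degenerate
one (single-class glasses) must *not* silently disappear.

Generation is fully deterministic: the same ``(seed, config)`` pair yields a
byte-identical manifest and pixel data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "GroundTruthRecord",
    "IncompleteEvidenceError",
    "label_msi_status",
    "synthesize_manifest",
    "render_tiles",
    "synthesize_dataset",
    "synthesize_tissue_dataset",
    "TISSUE_CLASSES",
    "ROI_CLASSES",
]

TISSUE_CLASSES = ("ADI", "BACK", "DEB", "LYM", "MUC", "MUS", "NORM", "STR", "TUM")
ROI_CLASSES = ("TUM", "LYM", "MUC")
MAGNIFICATIONS = ("x40", "x20", "x10", "x5", "x0")

# Relative strength of the class-dependent morphology per tissue type: the
# nuclear signal is specific to tumour epithelium, while lymphocytic and
# mucinous regions are correlated with the class but less discriminative.
_TISSUE_SIGNAL = {"TUM": 1.0, "LYM": 0.4, "MUC": 0.4}


# ---------------------------------------------------------------------------
# ground-truth labeling rule
# ---------------------------------------------------------------------------

class IncompleteEvidenceError(ValueError):
    """Raised when the decision rule needs a BRAF result that is missing."""


@dataclass(frozen=True)
class GroundTruthRecord:
    """Molecular evidence for one tumour.

    ``ihc_loss`` is the set of mismatch-repair proteins with lost expression
    on immunohistochemistry; ``msi_pcr_positive`` is the PCR microsatellite
    instability result; ``braf_mutant`` / ``mlh1_promoter_methylated`` may be
    ``None`` when the respective test was not run.
    """

    ihc_loss: frozenset = frozenset()
    msi_pcr_positive: bool = False
    braf_mutant: Optional[bool] = None
    mlh1_promoter_methylated: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "ihc_loss", frozenset(self.ihc_loss))
        bad = self.ihc_loss - {"MLH1", "PMS2", "MSH2", "MSH6"}
        if bad:
            raise ValueError(f"unknown MMR protein(s): {sorted(bad)}")


def label_msi_status(record: GroundTruthRecord) -> str:
    """Apply the MSI-H vs MSS decision rule to molecular evidence.

    * MSH2 loss, MSH6 loss, or isolated PMS2 loss (PMS2 without MLH1)
      → MSI-H directly.
    * MLH1 loss or a positive MSI PCR requires a BRAF result: with no BRAF
      mutation the tumour is MSI-H regardless of MLH1 promoter methylation;
      with a BRAF mutation it is labeled MSS.
    * Anything else → MSS.

    Raises :class:`IncompleteEvidenceError` when BRAF testing is required
    (MSI or MLH1 loss present) but the result is unknown.
    """
    loss = record.ihc_loss
    if ("MSH2" in loss) or ("MSH6" in loss) or ("PMS2" in loss and "MLH1" not in loss):
        return "MSI-H"
    if ("MLH1" in loss) or record.msi_pcr_positive:
        if record.braf_mutant is None:
            raise IncompleteEvidenceError(
                "BRAF testing required for MLH1-loss/MSI-positive tumours"
            )
        return "MSS" if record.braf_mutant else "MSI-H"
    return "MSS"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Generative conditions for one synthetic cohort.

    Structural knobs
        ``n_patients``, ``tiles_per_patient_range``, ``msi_prevalence``
        (default 0.074, a population-based colorectal cohort),
        ``n_projects``, ``n_glasses``, ``magnifications``, ``tile_px``.

    Confound knobs, all in [0, 1]
        ``project_confound`` — probability that a patient's project follows
        their class (1.0: project determines class almost surely);
        ``glass_class_purity`` — probability that a patient lands on a glass
        "reserved" for their class (1.0: every glass holds one class only);
        ``confound_flip`` — reverse the class→project association, used to
        build bias-flipped test splits.

    Appearance knobs
        ``stain_shift_magnitude`` — per-project RGB offset scale;
        ``glass_tint_magnitude`` — per-glass tint scale;
        ``patient_texture_sd`` — per-patient smooth texture amplitude;
        ``hue_jitter`` — per-tile staining noise in the hue plane (makes
        colour cues noisy at tile level, as section-to-section staining
        variation does);
        ``signal_strength`` — separation of the class-dependent morphology
        (0: no biological signal at all).

    All appearance scales are fractions of the 8-bit dynamic range.
    """

    n_patients: int = 200
    tiles_per_patient_range: tuple = (35, 45)
    msi_prevalence: float = 0.074
    n_projects: int = 2
    n_glasses: int = 8
    glass_class_purity: float = 0.5
    project_confound: float = 0.0
    stain_shift_magnitude: float = 0.15
    glass_tint_magnitude: float = 0.08
    patient_texture_sd: float = 0.04
    hue_jitter: float = 0.0
    signal_strength: float = 0.7
    magnifications: tuple = ("x20",)
    tile_px: int = 64
    seed: int = 0
    confound_flip: bool = False
    spots_per_patient: int = 2
    tissue_probs: tuple = (0.7, 0.15, 0.15)  # TUM, LYM, MUC

    def __post_init__(self):
        for name in ("msi_prevalence", "glass_class_purity", "project_confound",
                     "signal_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 1 or self.n_projects < 1 or self.n_glasses < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.tiles_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid tiles_per_patient_range")
        unknown = set(self.magnifications) - set(MAGNIFICATIONS)
        if unknown:
            raise ValueError(f"unknown magnifications {sorted(unknown)}")
        if self.tile_px < 16:
            raise ValueError("tile_px must be >= 16")
        if (self.glass_class_purity == 1.0 and self.n_glasses < 2
                and 0.0 < self.msi_prevalence < 1.0):
            raise ValueError(
                "glass_class_purity=1.0 with both classes present needs "
                "n_glasses >= 2 (one pure glass per class)"
            )
        if abs(sum(self.tissue_probs) - 1.0) > 1e-9:
            raise ValueError("tissue_probs must sum to 1")


@dataclass
class SynthDataset:
    """In-memory synthetic cohort: manifest rows aligned with pixel stack."""

    manifest: pd.DataFrame
    images: np.ndarray  # (N, tile_px, tile_px, 3) uint8
    config: SynthConfig


# ---------------------------------------------------------------------------
# manifest synthesis (patients → projects/glasses/spots → tiles)
# ---------------------------------------------------------------------------

def _rng(config: SynthConfig) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))


def synthesize_manifest(config: SynthConfig) -> pd.DataFrame:
    """Draw the cohort structure: one row per tile, no pixels yet.

    Columns: ``tile_id, patient, spot, project, glass, magnification,
    tissue, msi_label``.
    """
    rng = _rng(config)
    n = config.n_patients
    labels = np.where(rng.random(n) < config.msi_prevalence, "MSI-H", "MSS")

    # project: with prob project_confound the assignment follows the class
    # (MSI-H -> last project, MSS -> one of the others); otherwise uniform.
    # confound_flip reverses the association for bias-flipped test splits.
    projects = np.empty(n, dtype=object)
    for i in range(n):
        is_pos = labels[i] == "MSI-H"
        if config.confound_flip:
            is_pos = not is_pos
        if rng.random() < config.project_confound and config.n_projects >= 2:
            if is_pos:
                projects[i] = f"proj{config.n_projects - 1}"
            else:
                projects[i] = f"proj{int(rng.integers(config.n_projects - 1))}"
        else:
            projects[i] = f"proj{int(rng.integers(config.n_projects))}"

    # glass: each glass has a preferred class (round-robin); with prob
    # glass_class_purity a patient lands on a glass of their own class.
    glass_pref = np.array(["MSI-H" if g % 2 else "MSS" for g in range(config.n_glasses)])
    glasses = np.empty(n, dtype=object)
    for i in range(n):
        if rng.random() < config.glass_class_purity:
            pool = np.flatnonzero(glass_pref == labels[i])
        else:
            pool = np.arange(config.n_glasses)
        glasses[i] = f"glass{int(rng.choice(pool))}"

    lo, hi = config.tiles_per_patient_range
    n_tiles = rng.integers(lo, hi + 1, size=n)

    rows = []
    tissue_p = np.asarray(config.tissue_probs)
    for i in range(n):
        pid = f"pat{i:04d}"
        for t in range(int(n_tiles[i])):
            spot = f"{pid}_s{t % config.spots_per_patient}"
            mag = config.magnifications[int(rng.integers(len(config.magnifications)))]
            tissue = ROI_CLASSES[int(rng.choice(len(ROI_CLASSES), p=tissue_p))]
            rows.append((pid, spot, projects[i], glasses[i], mag, tissue, labels[i]))
    manifest = pd.DataFrame(
        rows,
        columns=["patient", "spot", "project", "glass", "magnification",
                 "tissue", "msi_label"],
    )
    manifest.insert(0, "tile_id", [f"tile{j:06d}" for j in range(len(manifest))])
    return manifest


# ---------------------------------------------------------------------------
# tile rendering
# ---------------------------------------------------------------------------

_BASE_RGB = {  # H&E-ish base colours per tissue class
    "TUM": (222, 188, 210),
    "LYM": (198, 172, 214),
    "MUC": (236, 224, 234),
}
_NUCLEUS_RGB = np.array([92.0, 58.0, 124.0])  # dark basophilic purple
_MUCIN_RGB = np.array([244.0, 238.0, 244.0])


def _draw_ellipses(img: np.ndarray, rng: np.random.Generator, count: int,
                   color: np.ndarray, r_lo: float, r_hi: float, alpha: float) -> None:
    """Alpha-blend ``count`` random soft ellipses into ``img`` in place."""
    px = img.shape[0]
    for _ in range(count):
        cx, cy = rng.random(2) * px
        rx = rng.uniform(r_lo, r_hi)
        ry = rng.uniform(r_lo, r_hi)
        theta = rng.uniform(0.0, np.pi)
        x0, x1 = int(max(cx - 2 * rx - 2, 0)), int(min(cx + 2 * rx + 3, px))
        y0, y1 = int(max(cy - 2 * ry - 2, 0)), int(min(cy + 2 * ry + 3, px))
        if x0 >= x1 or y0 >= y1:
            continue
        yy = np.arange(y0, y1, dtype=float)[:, None]
        xx = np.arange(x0, x1, dtype=float)[None, :]
        dx, dy = xx - cx, yy - cy
        ct, st = np.cos(theta), np.sin(theta)
        u = (dx * ct + dy * st) / rx
        v = (-dx * st + dy * ct) / ry
        mask = np.clip(1.5 - (u * u + v * v), 0.0, 1.0)  # soft edge
        w = (alpha * mask)[..., None]
        img[y0:y1, x0:x1] = (1.0 - w) * img[y0:y1, x0:x1] + w * color


def _project_offsets(config: SynthConfig) -> np.ndarray:
    """Per-project RGB stain offsets.

    Offsets are spread around the colour plane orthogonal to the
    nucleus-versus-background axis, so the project signature is a pure hue
    shift that carries no morphological (density/darkness) information —
    the defining property of a confound that is removable in principle.
    """
    e1, e2 = _hue_plane()
    angles = 2.0 * np.pi * np.arange(config.n_projects) / max(config.n_projects, 2)
    dirs = np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
    return dirs * config.stain_shift_magnitude * 255.0


def _hue_plane() -> tuple:
    """Orthonormal basis of the colour plane orthogonal to the
    nucleus-versus-background axis (the morphology-free hue plane in which
    every batch-effect overlay lives)."""
    nucleus_axis = _NUCLEUS_RGB - np.array(_BASE_RGB["TUM"], dtype=float)
    n_hat = nucleus_axis / np.linalg.norm(nucleus_axis)
    e1 = np.array([1.0, -1.0, 0.0])
    e1 -= (e1 @ n_hat) * n_hat
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(n_hat, e1)


def _glass_tints(config: SynthConfig) -> np.ndarray:
    """Per-glass tints: fixed angles around the removable hue plane,
    interleaved between the project directions."""
    e1, e2 = _hue_plane()
    g = np.arange(config.n_glasses)
    angles = np.pi / config.n_glasses * (2 * g + 1)
    dirs = np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
    return dirs * config.glass_tint_magnitude * 255.0


def _patient_field(px: int, rng: np.random.Generator, sd: float) -> np.ndarray:
    """Smooth per-patient texture: low-resolution noise, bilinearly upsampled."""
    coarse = rng.normal(0.0, sd * 255.0, size=(8, 8, 3))
    idx = np.linspace(0, 7, px)
    i0 = np.floor(idx).astype(int)
    i1 = np.minimum(i0 + 1, 7)
    f = idx - i0
    rows = coarse[i0] * (1 - f)[:, None, None] + coarse[i1] * f[:, None, None]
    out = rows[:, i0] * (1 - f)[None, :, None] + rows[:, i1] * f[None, :, None]
    return out


def _degrade_magnification(img: np.ndarray, mag: str) -> np.ndarray:
    """Emulate a lower magnification of the same field: average-pool by the
    scale factor (the anti-aliasing blur and decimation in one step) and
    re-upsample to the common tile size.  ``x40`` is the native view;
    ``x0`` is a whole-spot thumbnail-like view (strongest degradation)."""
    factor = {"x40": 1, "x20": 2, "x10": 4, "x5": 8, "x0": 16}[mag]
    if factor == 1:
        return img
    px = img.shape[0]
    crop = (px // factor) * factor
    small = img[:crop, :crop].reshape(
        crop // factor, factor, crop // factor, factor, 3).mean(axis=(1, 3))
    up = np.repeat(np.repeat(small, factor, axis=0), factor, axis=1)
    if up.shape[0] < px:  # edge-pad when the factor does not divide evenly
        pad = px - up.shape[0]
        up = np.pad(up, ((0, pad), (0, pad), (0, 0)), mode="edge")
    return up


def render_tiles(manifest: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    """Render every manifest row to a ``tile_px``² RGB tile (uint8 stack).

    Class signal is carried only by morphology — nucleus density and
    mucin-like pale regions, both scaled by ``signal_strength`` and by the
    tissue's specificity — while project, glass and patient enter as
    additive colour/texture overlays.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 1])))
    px = config.tile_px
    proj_off = _project_offsets(config)
    tints = _glass_tints(config)

    patient_ids = manifest["patient"].unique()
    pfields = {}
    for pid in patient_ids:
        prng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([config.seed, 7, int(pid[3:])])))
        e1, e2 = _hue_plane()
        theta = prng.uniform(0.0, 2.0 * np.pi)
        hue_off = (np.cos(theta) * e1 + np.sin(theta) * e2) \
            * 0.6 * config.patient_texture_sd * 255.0
        pfields[pid] = _patient_field(px, prng, config.patient_texture_sd) + hue_off

    images = np.empty((len(manifest), px, px, 3), dtype=np.uint8)
    area_scale = (px / 64.0) ** 2
    for j, row in enumerate(manifest.itertuples(index=False)):
        img = np.empty((px, px, 3))
        img[...] = _BASE_RGB[row.tissue]

        sig = config.signal_strength * _TISSUE_SIGNAL[row.tissue]
        is_pos = row.msi_label == "MSI-H"
        # nuclei: MSI-H tiles are denser; baseline density keeps MSS tiles
        # from being blank so the contrast is graded, not binary
        base_n = 10.0 if row.tissue != "MUC" else 6.0
        mean_n = base_n * (1.0 + (2.2 * sig if is_pos else 0.0)) * area_scale
        n_nuc = int(rng.poisson(mean_n))
        _draw_ellipses(img, rng, n_nuc, _NUCLEUS_RGB,
                       r_lo=1.5 * px / 64, r_hi=3.5 * px / 64, alpha=0.85)
        # mucin-like pale pools: more frequent in MSI-H
        mean_m = (1.0 + (3.0 * sig if is_pos else 0.0)) * (2.0 if row.tissue == "MUC" else 0.5)
        n_muc = int(rng.poisson(mean_m))
        _draw_ellipses(img, rng, n_muc, _MUCIN_RGB,
                       r_lo=4.0 * px / 64, r_hi=8.0 * px / 64, alpha=0.6)

        img += proj_off[int(row.project[4:])]
        img += tints[int(row.glass[5:])]
        img += pfields[row.patient]
        if config.hue_jitter > 0:
            e1, e2 = _hue_plane()
            th = rng.uniform(0.0, 2.0 * np.pi)
            amp = rng.normal(0.0, config.hue_jitter * 255.0)
            img += amp * (np.cos(th) * e1 + np.sin(th) * e2)
        img += rng.normal(0.0, 3.0, size=img.shape)

        if row.magnification != "x40":
            img = _degrade_magnification(img, row.magnification)
        images[j] = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return images


def synthesize_dataset(config: SynthConfig, out_dir=None) -> SynthDataset:
    """Generate a full synthetic cohort; optionally write it to disk.

    When ``out_dir`` is given, tiles are written as PNG under
    ``<out_dir>/tiles/<magnification>/<tile_id>.png``, the manifest as
    ``manifest.csv`` (one row per tile; column dictionary in the README) and
    the configuration as ``config.yaml``.
    """
    manifest = synthesize_manifest(config)
    images = render_tiles(manifest, config)
    ds = SynthDataset(manifest=manifest, images=images, config=config)
    if out_dir is not None:
        out = Path(out_dir)
        from PIL import Image

        for mag in manifest["magnification"].unique():
            (out / "tiles" / mag).mkdir(parents=True, exist_ok=True)
        for j, row in enumerate(manifest.itertuples(index=False)):
            Image.fromarray(images[j]).save(
                out / "tiles" / row.magnification / f"{row.tile_id}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
        import yaml

        cfg = dataclasses.asdict(config)
        cfg["tiles_per_patient_range"] = list(config.tiles_per_patient_range)
        cfg["magnifications"] = list(config.magnifications)
        cfg["tissue_probs"] = list(config.tissue_probs)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    return ds


# ---------------------------------------------------------------------------
# nine-class texture dataset for the tissue classifier
# ---------------------------------------------------------------------------

def synthesize_tissue_dataset(n_per_class: int = 60, tile_px: int = 64,
                              seed: int = 0, classes=TISSUE_CLASSES):
    """Procedural nine-texture dataset standing in for an H&E tissue atlas.

    Each of the nine colorectal tissue classes gets a distinct colour and
    texture recipe (stripes for muscle, near-white emptiness for background,
    dense purple dots for lymphocytes, ...), separable by construction so a
    small classifier can be trained and sanity-checked without any download.

    Returns ``(images, labels)``: a uint8 stack and an aligned array of
    class codes.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 9])))
    base = {
        "ADI": (245, 235, 230), "BACK": (248, 248, 248), "DEB": (180, 150, 150),
        "LYM": (150, 120, 190), "MUC": (235, 225, 240), "MUS": (220, 160, 180),
        "NORM": (215, 180, 205), "STR": (230, 195, 215), "TUM": (200, 150, 190),
    }
    imgs, labels = [], []
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    for cls in classes:
        for _ in range(n_per_class):
            img = np.empty((tile_px, tile_px, 3))
            img[...] = base[cls]
            if cls == "MUS":  # fibrous stripes
                phase = rng.uniform(0, 2 * np.pi)
                freq = rng.uniform(0.4, 0.8)
                img += 25.0 * np.sin(freq * (xx + 0.5 * yy) + phase)[..., None]
            elif cls == "LYM":  # dense small dark dots
                _draw_ellipses(img, rng, int(60 * (tile_px / 64) ** 2),
                               np.array([60.0, 40.0, 110.0]), 1.0, 2.0, 0.9)
            elif cls == "TUM":  # larger irregular nuclei
                _draw_ellipses(img, rng, int(18 * (tile_px / 64) ** 2),
                               _NUCLEUS_RGB, 2.0, 5.0, 0.85)
            elif cls == "NORM":  # regular glandular rings
                _draw_ellipses(img, rng, int(8 * (tile_px / 64) ** 2),
                               np.array([150.0, 100.0, 160.0]), 3.0, 4.0, 0.5)
            elif cls == "DEB":  # coarse blotches
                _draw_ellipses(img, rng, int(10 * (tile_px / 64) ** 2),
                               np.array([120.0, 90.0, 90.0]), 3.0, 8.0, 0.6)
            elif cls == "ADI":  # pale voids with thin walls
                _draw_ellipses(img, rng, int(9 * (tile_px / 64) ** 2),
                               np.array([252.0, 248.0, 246.0]), 5.0, 9.0, 0.9)
            elif cls == "STR":  # wavy faint fibres
                phase = rng.uniform(0, 2 * np.pi)
                img += 12.0 * np.sin(0.3 * yy + 3.0 * np.sin(0.1 * xx) + phase)[..., None]
            elif cls == "MUC":  # smooth pale pools
                _draw_ellipses(img, rng, int(4 * (tile_px / 64) ** 2),
                               _MUCIN_RGB, 6.0, 12.0, 0.7)
            # BACK stays nearly blank
            img += rng.normal(0.0, 4.0, size=img.shape)
            imgs.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(cls)
    return np.stack(imgs), np.asarray(labels)
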