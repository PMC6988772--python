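"""Rendering of synthetic multi-channel fluorescence fields with ground truth.

Each field mimics one imaged area of a donor's culture: non-overlapping,
smoothed convex cell blobs (area and width/length sampled around the
donor's latent means), interior elliptical nuclei, a DAPI channel from the
nucleus masks, and actin/tubulin channels made of the cell body fill plus
oriented anti-aliased filament strokes (ridge-like after a sigma = 1 px
blur), on top of a smooth background gradient and Gaussian noise.

The ground truth (label maps plus a per-object table of pixel-exact areas
and equivalent-ellipse axes) is the oracle for the segmentation and
feature-extraction stages. Photorealism (PSF physics, confluent overlap)
is out of scope by design.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import line_aa, polygon

from .features import morphology_table
from .synth import DonorTruth

#: Channel order used for multi-page TIFF output.
CHANNEL_ORDER = ("dapi", "actin", "tubulin")


class PlacementError(RuntimeError):
    """Requested cell count unachievable without overlap."""


@dataclass(frozen=True)
class RenderConfig:
    """Field geometry, placement, and photometric settings."""

    shape: tuple[int, int] = (768, 768)
    pixel_size: float = 1.0          # um per px
    cells_per_field: int = 12
    margin_px: int = 3               # minimum gap between neighboring cells
    max_placement_tries: int = 400   # per cell
    noise_sd: float = 0.02
    background_gradient: float = 0.05
    nucleus_intensity: float = 0.8
    cell_fill: float = 0.25
    filament_intensity: float = 0.35
    blur_sigma: float = 1.0
    boundary_points: int = 72
    shape_perturbation: float = 0.06  # radial harmonic amplitude


DEFAULT_RENDER = RenderConfig()


@dataclass
class ImageField:
    """One rendered multi-channel field."""

    donor_id: str
    field_index: int
    pixel_size: float
    channels: dict[str, np.ndarray]


@dataclass
class GroundTruthLabels:
    """Pixel-exact rendering ground truth for one field."""

    nucleus_label_map: np.ndarray
    cell_label_map: np.ndarray
    table: pd.DataFrame  # object_id, per-compartment area/axes, touches_border


def _blob_mask(shape, center, area_px, wl, orientation, rng,
               perturbation, n_points) -> np.ndarray:
    """Rasterize a smoothed convex blob of target area and axis ratio."""
    a = np.sqrt(area_px / (np.pi * wl))  # semi-major
    b = a * wl
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    rel = theta - orientation
    r = a * b / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    if perturbation > 0:
        amp = perturbation * rng.uniform(0.5, 1.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        r = r * (1.0 + amp[0] * np.sin(2 * theta + phase[0])
                 + amp[1] * np.sin(3 * theta + phase[1]))
    # rescale to hit the target polygon area
    poly_area = 0.5 * np.sum(r**2) * (2 * np.pi / n_points)
    r = r * np.sqrt(area_px / poly_area)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    rr, cc = polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _place_cells(donor: DonorTruth, rng, config: RenderConfig):
    """Dart-throwing placement of non-overlapping cell blobs."""
    shape = config.shape
    px_area = config.pixel_size**2
    sd = donor.latent_noise_sd
    occupied = np.zeros(shape, dtype=bool)
    cells = []
    struct = ndi.generate_binary_structure(2, 2)
    for _ in range(config.cells_per_field):
        placed = False
        for _try in range(config.max_placement_tries):
            s_a = sd.get("cell_area_sdlog", 0.0)
            area = (donor.mean_cell_area / px_area
                    * np.exp(s_a * rng.standard_normal() - 0.5 * s_a**2))
            wl = float(np.clip(donor.cell_wl_ratio
                               + sd.get("cell_wl_sd", 0.0)
                               * rng.standard_normal(), 0.05, 1.0))
            orientation = rng.uniform(0, np.pi)
            center = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
            mask = _blob_mask(shape, center, area, wl, orientation, rng,
                              config.shape_perturbation,
                              config.boundary_points)
            if not mask.any():
                continue
            grown = ndi.binary_dilation(mask, structure=struct,
                                        iterations=config.margin_px)
            if not (grown & occupied).any():
                occupied |= mask
                cells.append(dict(mask=mask, center=center,
                                  orientation=orientation))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {config.cells_per_field} cells of donor "
                f"{donor.donor_id} in a {shape} field without overlap")
    return cells


def _nucleus_mask(cell, donor: DonorTruth, rng, config: RenderConfig):
    px_area = config.pixel_size**2
    sd = donor.latent_noise_sd
    s_a = sd.get("nucleus_area_sdlog", 0.0)
    area = (donor.mean_nucleus_area / px_area
            * np.exp(s_a * rng.standard_normal() - 0.5 * s_a**2))
    wl = float(np.clip(donor.nucleus_wl_ratio
                       + sd.get("nucleus_wl_sd", 0.0) * rng.standard_normal(),
                       0.05, 1.0))
    com = ndi.center_of_mass(cell["mask"])
    mask = _blob_mask(cell["mask"].shape, com, area, wl,
                      cell["orientation"] + rng.normal(0, 0.2), rng,
                      perturbation=0.0, n_points=config.boundary_points)
    interior = ndi.binary_erosion(cell["mask"], iterations=1)
    return mask & interior


def _filaments(mask, orientation, length_px, n_strokes, rng, out,
               intensity, angle_spread=0.5):
    """Add anti-aliased filament strokes inside ``mask`` to ``out``."""
    coords = np.argwhere(mask)
    if coords.size == 0 or n_strokes < 1:
        return
    for _ in range(n_strokes):
        r0, c0 = coords[rng.integers(len(coords))]
        ang = orientation + rng.normal(0, angle_spread)
        half = 0.5 * length_px * rng.uniform(0.5, 1.0)
        r1 = int(round(r0 - half * np.sin(ang)))
        c1 = int(round(c0 - half * np.cos(ang)))
        r2 = int(round(r0 + half * np.sin(ang)))
        c2 = int(round(c0 + half * np.cos(ang)))
        h, w = mask.shape
        r1, r2 = np.clip([r1, r2], 0, h - 1)
        c1, c2 = np.clip([c1, c2], 0, w - 1)
        rr, cc, val = line_aa(r1, c1, r2, c2)
        inside = mask[rr, cc]
        out[rr[inside], cc[inside]] += intensity * val[inside]


def _finish_channel(img, rng, config: RenderConfig) -> np.ndarray:
    """Blur, background gradient, and Gaussian noise; clip to [0, 1]."""
    h, w = img.shape
    img = ndi.gaussian_filter(img, config.blur_sigma)
    gy, gx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w),
                         indexing="ij")
    a, b = rng.uniform(-1, 1, size=2)
    img = img + config.background_gradient * (0.5 + 0.5 * (a * gx + b * gy))
    img = img + config.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def render_field(donor: DonorTruth, field_index: int, seed: int,
                 config: RenderConfig = DEFAULT_RENDER
                 ) -> tuple[ImageField, GroundTruthLabels]:
    """Render one field of a donor deterministically in (donor, seed, index)."""
    donor_hash = zlib.crc32(donor.donor_id.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), donor_hash, int(field_index)]))
    cells = _place_cells(donor, rng, config)
    shape = config.shape
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    tubulin = np.zeros(shape, dtype=float)
    actin = np.zeros(shape, dtype=float)
    dapi = np.zeros(shape, dtype=float)
    px_area = config.pixel_size**2
    for oid, cell in enumerate(cells, start=1):
        mask = cell["mask"]
        cell_labels[mask] = oid
        nuc = _nucleus_mask(cell, donor, rng, config)
        nucleus_labels[nuc] = oid
        dapi[nuc] += config.nucleus_intensity
        tubulin[mask] += config.cell_fill
        actin[mask] += 0.8 * config.cell_fill
        area_px = int(mask.sum())
        length = np.sqrt(4 * area_px / (np.pi * donor.cell_wl_ratio))
        n_tub = max(3, int(round(donor.texture_intensity * area_px / 800.0)))
        _filaments(mask, cell["orientation"], 0.8 * length, n_tub, rng,
                   tubulin, config.filament_intensity, angle_spread=0.5)
        _filaments(mask, cell["orientation"], 1.0 * length,
                   max(2, n_tub // 2), rng, actin,
                   1.2 * config.filament_intensity, angle_spread=0.25)
    channels = {
        "dapi": _finish_channel(dapi, rng, config),
        "actin": _finish_channel(actin, rng, config),
        "tubulin": _finish_channel(tubulin, rng, config),
    }
    cell_m = morphology_table(cell_labels, config.pixel_size, prefix="cell_")
    nuc_m = morphology_table(nucleus_labels, config.pixel_size,
                             prefix="nucleus_")
    table = cell_m.merge(nuc_m, on="object_id", how="left")
    table["cell_area_px"] = (table["cell_area"] / px_area).round().astype(int)
    border_ids = set(np.unique(np.concatenate([
        cell_labels[0, :], cell_labels[-1, :],
        cell_labels[:, 0], cell_labels[:, -1]])))
    table["touches_border"] = table["object_id"].isin(border_ids)
    field_obj = ImageField(donor.donor_id, field_index, config.pixel_size,
                           channels)
    truth = GroundTruthLabels(nucleus_labels, cell_labels, table)
    return field_obj, truth


# ---------------------------------------------------------------------------
# TIFF / CSV I/O
# ---------------------------------------------------------------------------

def write_field(field_obj: ImageField, truth: GroundTruthLabels,
                prefix) -> None:
    """Write channels as one multi-page TIFF (DAPI, actin, tubulin order),
    label maps as 16-bit TIFFs, and the truth table as CSV."""
    stack = np.stack([field_obj.channels[c] for c in CHANNEL_ORDER])
    tifffile.imwrite(f"{prefix}_channels.tif", stack,
                     photometric="minisblack")
    tifffile.imwrite(f"{prefix}_nuclei_labels.tif",
                     truth.nucleus_label_map.astype(np.uint16))
    tifffile.imwrite(f"{prefix}_cell_labels.tif",
                     truth.cell_label_map.astype(np.uint16))
    truth.table.to_csv(f"{prefix}_truth.csv", index=False)


def read_field(prefix, donor_id: str = "", field_index: int = 0,
               pixel_size: float = 1.0) -> ImageField:
    """Read a multi-page channel TIFF written by :func:`write_field`."""
    stack = tifffile.imread(f"{prefix}_channels.tif")
    channels = {name: stack[i] for i, name in enumerate(CHANNEL_ORDER)}
    return ImageField(donor_id, field_index, pixel_size, channels)
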