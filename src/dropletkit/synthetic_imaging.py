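"""Synthetic multi-channel fluorescence micrographs with exact ground truth.

Emulates confocal fields of lipid droplets: bright discs (or 2-px annular
rings, as droplet-coat protein stains appear) of lognormally distributed
sub-μm–to–μm diameters on a dark background, a second "protein" channel
marking a controllable fraction of droplets, a nuclei channel with
well-separated blobs, plus Gaussian read noise and signal-proportional
shot noise. Every image carries a per-droplet ground-truth record, so
segmentation and co-localisation estimators can be tested for parameter
recovery, and two-arm cohorts can be generated with prescribed
multiplicative effects on droplet number and size (the vehicle-vs-drug
design of lipid-droplet experiments).

Geometry is row-major with origin at the top-left pixel; lengths are in
μm, converted through ``pixel_size`` (μm per pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SyntheticParams",
    "DropletTruth",
    "NucleusTruth",
    "GroundTruth",
    "ImageStack",
    "PlacementError",
    "sample_droplet_field",
    "render_image",
    "simulate_image",
    "simulate_cohort",
    "write_tiff",
    "read_tiff",
    "ground_truth_table",
]

CHANNEL_NAMES = ("droplet", "protein", "nuclei")


class PlacementError(RuntimeError):
    """Raised when a droplet field cannot accommodate the requested density."""


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults emulate a 63×-confocal crop of one cell.

    ``n_droplets`` is the expected per-image count (Poisson-distributed
    across images unless ``poisson_counts`` is off). Droplet diameters are
    lognormal with the given median (μm) and log-scale shape, matching the
    right-skewed size distributions of BODIPY-stained droplets.
    """

    image_shape: tuple[int, int] = (256, 256)  # rows, cols (px)
    pixel_size: float = 0.1                    # μm per pixel
    n_droplets: float = 50.0                   # expected count per image
    poisson_counts: bool = True
    diameter_median: float = 0.6               # μm
    diameter_log_sd: float = 0.4               # lognormal shape (dimensionless)
    coloc_fraction: float = 0.5                # P(droplet carries protein signal)
    n_nuclei: int = 3
    nucleus_radius: float = 1.8                # μm
    droplet_intensity: float = 180.0
    nucleus_intensity: float = 120.0
    background: float = 20.0
    gaussian_sd: float = 4.0                   # read noise
    shot_noise_scale: float = 0.25             # var = scale × clean signal
    ring_mode: bool = False                    # render droplets as 2-px annuli
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.diameter_median <= 0:
            raise ValueError("diameter_median must be > 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.gaussian_sd < 0 or self.shot_noise_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_droplets < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be (rows, cols), each >= 8")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class DropletTruth:
    droplet_id: int
    row: float          # px
    col: float          # px
    radius_um: float
    in_channel2: bool


@dataclass(frozen=True)
class NucleusTruth:
    nucleus_id: int
    row: float
    col: float
    radius_um: float


@dataclass(frozen=True)
class GroundTruth:
    """Exact simulation record: all rendered geometry is recoverable from it."""

    droplets: tuple[DropletTruth, ...]
    nuclei: tuple[NucleusTruth, ...]
    params: SyntheticParams

    def droplet_mask(self, fill: bool = True, channel2_only: bool = False) -> np.ndarray:
        """Boolean footprint of the droplets (annuli when ring rendering)."""
        shape = self.params.image_shape
        mask = np.zeros(shape, dtype=bool)
        for d in self.droplets:
            if channel2_only and not d.in_channel2:
                continue
            mask |= _disc_mask(shape, d.row, d.col, d.radius_um / self.params.pixel_size,
                               ring=not fill)
        return mask


@dataclass(frozen=True)
class ImageStack:
    """Calibrated multi-channel image; all channels share shape and pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; have {sorted(self.channels)}"
            ) from None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _rng(seed: int, stream: int) -> np.random.Generator:
    # separate deterministic streams for placement vs. noise
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _disc_mask(shape, row, col, radius_px, ring=False, ring_width=2.0) -> np.ndarray:
    r0 = max(int(row - radius_px) - 1, 0)
    r1 = min(int(row + radius_px) + 2, shape[0])
    c0 = max(int(col - radius_px) - 1, 0)
    c1 = min(int(col + radius_px) + 2, shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    local = d2 <= radius_px**2
    if ring:
        inner = max(radius_px - ring_width, 0.0)
        local &= d2 > inner**2
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = local
    return out


def sample_droplet_field(
    params: SyntheticParams, max_attempts_per_droplet: int = 200
) -> GroundTruth:
    """Place non-overlapping droplets and nuclei; fully deterministic in seed.

    Droplet centres keep a minimum distance of the sum of the two radii
    plus one pixel, and every object lies fully inside the image bounds.
    Raises :class:`PlacementError` when the field cannot accommodate the
    requested density within the retry budget.
    """
    rng = _rng(params.seed, 0)
    rows, cols = params.image_shape
    if params.poisson_counts:
        n = int(rng.poisson(params.n_droplets))
    else:
        n = int(round(params.n_droplets))

    # lognormal with median = diameter_median: ln d ~ N(ln median, log_sd)
    diams = params.diameter_median * np.exp(
        params.diameter_log_sd * rng.standard_normal(n)
    )
    radii_px = diams / 2.0 / params.pixel_size
    # place big droplets first: greedy packing fails less often
    order = np.argsort(-radii_px)

    placed: list[tuple[float, float, float]] = []  # row, col, radius_px
    droplets: list[DropletTruth] = []
    for rank, idx in enumerate(order):
        r_px = float(radii_px[idx])
        margin = r_px + 1.0
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PlacementError(
                f"droplet of radius {r_px:.1f} px does not fit in a "
                f"{rows}x{cols} image"
            )
        for _ in range(max_attempts_per_droplet):
            row = rng.uniform(margin, rows - margin)
            col = rng.uniform(margin, cols - margin)
            if all(
                (row - pr) ** 2 + (col - pc) ** 2 >= (r_px + prad + 1.0) ** 2
                for pr, pc, prad in placed
            ):
                placed.append((row, col, r_px))
                droplets.append(
                    DropletTruth(
                        droplet_id=len(droplets),
                        row=row,
                        col=col,
                        radius_um=float(diams[idx] / 2.0),
                        in_channel2=bool(rng.random() < params.coloc_fraction),
                    )
                )
                break
        else:
            raise PlacementError(
                f"could not place droplet {rank + 1}/{n} after "
                f"{max_attempts_per_droplet} attempts: requested density "
                f"({n} droplets, median {params.diameter_median} μm) exceeds "
                f"what a {rows}x{cols} px field at {params.pixel_size} μm/px "
                "can hold without overlap"
            )

    nuc_r_px = params.nucleus_radius / params.pixel_size
    nuclei: list[NucleusTruth] = []
    nuc_placed: list[tuple[float, float]] = []
    for i in range(params.n_nuclei):
        margin = nuc_r_px + 1.0
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PlacementError("nucleus does not fit in the image")
        for _ in range(max_attempts_per_droplet):
            row = rng.uniform(margin, rows - margin)
            col = rng.uniform(margin, cols - margin)
            if all(
                (row - pr) ** 2 + (col - pc) ** 2 >= (2 * nuc_r_px + 3.0) ** 2
                for pr, pc in nuc_placed
            ):
                nuc_placed.append((row, col))
                nuclei.append(NucleusTruth(i, row, col, params.nucleus_radius))
                break
        else:
            raise PlacementError(
                f"could not place {params.n_nuclei} well-separated nuclei of "
                f"radius {params.nucleus_radius} μm in the field"
            )

    return GroundTruth(tuple(droplets), tuple(nuclei), params)


def render_image(truth: GroundTruth, params: SyntheticParams | None = None) -> ImageStack:
    """Rasterise a ground-truth field into a noisy multi-channel image.

    The droplet channel paints every droplet footprint (a filled disc, or
    a 2-px annulus in ring mode) at ``droplet_intensity`` over a flat
    background; the protein channel paints only droplets carrying
    second-channel membership; the nuclei channel paints nucleus discs.
    Gaussian read noise and Gaussian shot noise with variance
    ``shot_noise_scale × clean signal`` are then added and intensities
    clipped and quantised to the bit depth. Deterministic in the seed.
    """
    params = params or truth.params
    shape = params.image_shape
    px = params.pixel_size

    def paint(mask_channel2_only: bool | None) -> np.ndarray:
        img = np.full(shape, params.background, dtype=np.float64)
        for d in truth.droplets:
            if mask_channel2_only and not d.in_channel2:
                continue
            m = _disc_mask(shape, d.row, d.col, d.radius_um / px, ring=params.ring_mode)
            img[m] = params.droplet_intensity
        return img

    droplet = paint(False)
    protein = paint(True)
    nuclei = np.full(shape, params.background, dtype=np.float64)
    for nuc in truth.nuclei:
        m = _disc_mask(shape, nuc.row, nuc.col, nuc.radius_um / px)
        nuclei[m] = params.nucleus_intensity

    rng = _rng(params.seed, 1)
    channels = {}
    for name, clean in (("droplet", droplet), ("protein", protein), ("nuclei", nuclei)):
        noisy = clean.copy()
        if params.gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, params.gaussian_sd, size=shape)
        if params.shot_noise_scale > 0:
            shot_sd = np.sqrt(params.shot_noise_scale * clean)
            noisy = noisy + shot_sd * rng.standard_normal(shape)
        dtype = np.uint8 if params.bit_depth == 8 else np.uint16
        channels[name] = np.clip(np.rint(noisy), 0, params.max_intensity).astype(dtype)
    return ImageStack(channels=channels, pixel_size=px, bit_depth=params.bit_depth)


def simulate_image(params: SyntheticParams) -> tuple[ImageStack, GroundTruth]:
    truth = sample_droplet_field(params)
    return render_image(truth, params), truth


def simulate_cohort(
    base: SyntheticParams,
    number_multiplier: float = 1.0,
    size_multiplier: float = 1.0,
    coloc_shift: float = 0.0,
    n_images: int = 10,
    seed: int = 0,
    render: bool = True,
) -> tuple[list[tuple[ImageStack | None, GroundTruth]], list[tuple[ImageStack | None, GroundTruth]]]:
    """Two-arm cohort: arm A from ``base``, arm B with multiplicative effects.

    ``size_multiplier`` scales the median droplet *area*, so the median
    diameter scales by its square root. Per-image sub-seeds are derived
    deterministically from ``seed``. With ``render=False`` only ground
    truths are generated (the image slot is None) — useful for large
    calibration simulations on the sampling distribution itself.
    """
    if number_multiplier <= 0 or size_multiplier <= 0:
        raise ValueError("multipliers must be > 0")
    shifted = base.coloc_fraction + coloc_shift
    if not 0.0 <= shifted <= 1.0:
        raise ValueError(
            f"coloc_fraction + coloc_shift = {shifted:.3f} outside [0, 1]"
        )
    treated = replace(
        base,
        n_droplets=base.n_droplets * number_multiplier,
        diameter_median=base.diameter_median * math.sqrt(size_multiplier),
        coloc_fraction=shifted,
    )
    arms = []
    for arm_idx, arm_params in enumerate((base, treated)):
        images = []
        for i in range(n_images):
            sub_seed = int(
                np.random.SeedSequence((int(seed), arm_idx, i)).generate_state(1)[0]
                % 2**31
            )
            p = replace(arm_params, seed=sub_seed)
            truth = sample_droplet_field(p)
            stack = render_image(truth, p) if render else None
            images.append((stack, truth))
        arms.append(images)
    return arms[0], arms[1]


def write_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a multi-page TIFF, one page per channel, names in page metadata."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, arr in stack.channels.items():
            tif.write(
                arr,
                description=name,
                resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
                metadata=None,
            )


def read_tiff(path: str | Path, pixel_size: float) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_tiff`.

    Falls back to positional channel names for third-party TIFFs without
    page descriptions.
    """
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(str(path)) as tif:
        for i, page in enumerate(tif.pages):
            name = (page.description or "").strip()
            if not name or name.startswith("{"):
                name = CHANNEL_NAMES[i] if i < len(CHANNEL_NAMES) else f"channel{i}"
            channels[name] = page.asarray()
    first = next(iter(channels.values()))
    bit_depth = 16 if first.dtype.itemsize > 1 else 8
    return ImageStack(channels=channels, pixel_size=pixel_size, bit_depth=bit_depth)


def ground_truth_table(
    truths: Sequence[GroundTruth], image_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Flatten ground truths to a tidy per-droplet table (one row per droplet)."""
    rows = []
    for i, truth in enumerate(truths):
        image_id = image_ids[i] if image_ids is not None else f"image_{i:04d}"
        for d in truth.droplets:
            rows.append(
                {
                    "image_id": image_id,
                    "droplet_id": d.droplet_id,
                    "row_px": d.row,
                    "col_px": d.col,
                    "radius_um": d.radius_um,
                    "in_channel2": d.in_channel2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["image_id", "droplet_id", "row_px", "col_px", "radius_um", "in_channel2"],
    )
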