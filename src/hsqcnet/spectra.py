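"""Reading, rasterizing and preprocessing 2D HSQC spectra.

An HSQC (heteronuclear single quantum coherence) spectrum correlates directly
bonded 1H-13C pairs: each cross-peak is one C-H group, so the 2D peak pattern
acts as a molecular fingerprint.  The network downstream consumes spectra as
binary rasters ("black" = signal or noise, "white" = background), oriented
with the proton axis horizontal (shifts increasing right to left) and the
carbon axis vertical (shifts increasing top to bottom).

This module provides the raster representation, the peak-list rasterizer, the
binarization and cross-shaped median-filter preprocessing, the labelled
dataset manifest, and two small spectroscopy utilities (grid capacity of an
HSQC chemical-shift window, non-uniform-sampling density).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "AxisCalibration",
    "Peak",
    "PeakList",
    "SpectrumImage",
    "DatasetManifest",
    "CalibrationError",
    "OutOfWindowError",
    "load_spectrum_image",
    "save_spectrum_png",
    "binarize",
    "median_filter_cross",
    "rasterize_peaklist",
    "filter_families",
    "grid_capacity",
    "nus_density",
    "read_peaklist_csv",
    "write_peaklist_csv",
]

# Raster densities of the reference 512x512 representation: 51.2 px/ppm on the
# proton axis over a 10 ppm window, 2.8 px/ppm on the carbon axis.
H_PX_PER_PPM_512 = 51.2
C_PX_PER_PPM_512 = 2.8
DEFAULT_H_WINDOW = (0.0, 10.0)
DEFAULT_C_WINDOW = (0.0, 512.0 / C_PX_PER_PPM_512)  # ~182.857 ppm


class CalibrationError(ValueError):
    """Raster dimensions do not match the axis calibration."""


class OutOfWindowError(ValueError):
    """A peak lies outside the calibrated chemical-shift window."""


@dataclass(frozen=True)
class AxisCalibration:
    """Chemical-shift window and raster size of a spectrum image.

    Pixel densities follow from the window and the raster size; the default
    window (1H 0-10 ppm, 13C 0-182.857 ppm) reproduces 51.2 px/ppm (1H) and
    2.8 px/ppm (13C) at 512x512.
    """

    h_min_ppm: float = DEFAULT_H_WINDOW[0]
    h_max_ppm: float = DEFAULT_H_WINDOW[1]
    c_min_ppm: float = DEFAULT_C_WINDOW[0]
    c_max_ppm: float = DEFAULT_C_WINDOW[1]
    width_px: int = 512
    height_px: int = 512

    def __post_init__(self) -> None:
        if not self.h_max_ppm > self.h_min_ppm:
            raise ValueError("h_max_ppm must exceed h_min_ppm")
        if not self.c_max_ppm > self.c_min_ppm:
            raise ValueError("c_max_ppm must exceed c_min_ppm")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("raster dimensions must be >= 1 pixel")

    @property
    def h_px_per_ppm(self) -> float:
        return self.width_px / (self.h_max_ppm - self.h_min_ppm)

    @property
    def c_px_per_ppm(self) -> float:
        return self.height_px / (self.c_max_ppm - self.c_min_ppm)

    @classmethod
    def default(cls, side: int = 512) -> "AxisCalibration":
        """Standard window at an arbitrary (square) raster size."""
        return cls(width_px=side, height_px=side)

    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def peak_to_pixel(self, h_ppm: float, c_ppm: float) -> tuple[int, int]:
        """Map (1H, 13C) shifts to (row, col); half-open bins, upper edge clamped.

        Columns run right-to-left in ppm (high-field shifts on the right),
        rows top-to-bottom with increasing carbon shift.
        """
        if not (self.h_min_ppm <= h_ppm <= self.h_max_ppm):
            raise OutOfWindowError(
                f"1H shift {h_ppm} ppm outside window "
                f"[{self.h_min_ppm}, {self.h_max_ppm}]"
            )
        if not (self.c_min_ppm <= c_ppm <= self.c_max_ppm):
            raise OutOfWindowError(
                f"13C shift {c_ppm} ppm outside window "
                f"[{self.c_min_ppm}, {self.c_max_ppm}]"
            )
        col = int(np.floor((self.h_max_ppm - h_ppm) * self.h_px_per_ppm))
        row = int(np.floor((c_ppm - self.c_min_ppm) * self.c_px_per_ppm))
        col = min(col, self.width_px - 1)
        row = min(row, self.height_px - 1)
        return row, col

    def pixel_to_peak(self, row: int, col: int) -> tuple[float, float]:
        """Centre of a pixel in ppm (inverse of :meth:`peak_to_pixel`)."""
        h_ppm = self.h_max_ppm - (col + 0.5) / self.h_px_per_ppm
        c_ppm = self.c_min_ppm + (row + 0.5) / self.c_px_per_ppm
        return h_ppm, c_ppm


@dataclass(frozen=True)
class Peak:
    """One 1H-13C correlation signal."""

    h_ppm: float
    c_ppm: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class PeakList:
    """Ordered collection of peaks for one compound."""

    compound_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def positions(self) -> np.ndarray:
        return np.array([(p.h_ppm, p.c_ppm) for p in self.peaks], dtype=float)


@dataclass
class SpectrumImage:
    """Binary raster of an HSQC spectrum (1 = signal/noise, 0 = background)."""

    pixels: np.ndarray
    calibration: AxisCalibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != self.calibration.shape():
            raise CalibrationError(
                f"pixel array {self.pixels.shape} does not match calibration "
                f"{self.calibration.shape()}"
            )
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("SpectrumImage pixels must be 0/1")
        self.pixels = self.pixels.astype(np.uint8)

    def copy(self) -> "SpectrumImage":
        return SpectrumImage(self.pixels.copy(), self.calibration)


def load_spectrum_image(path: str | os.PathLike, calibration: AxisCalibration) -> np.ndarray:
    """Load a grayscale PNG as a darkness array in [0, 1].

    The PNG convention is black signal on white background; darkness is the
    inverted gray level so that signal -> values near 1.  Binarization is a
    separate, explicit step (:func:`binarize`).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"spectrum image not found: {path}")
    with Image.open(path) as im:
        gray = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    if gray.shape != calibration.shape():
        raise CalibrationError(
            f"image {path} has shape {gray.shape}, calibration expects "
            f"{calibration.shape()}"
        )
    return 1.0 - gray


def save_spectrum_png(image: SpectrumImage, path: str | os.PathLike) -> None:
    """Write a binary spectrum as a black-on-white grayscale PNG."""
    arr = ((1 - image.pixels) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def binarize(
    darkness: np.ndarray | SpectrumImage,
    calibration: AxisCalibration | None = None,
    threshold: float = 0.5,
) -> SpectrumImage:
    """Threshold a darkness raster into the binary signal/background image.

    A pixel is foreground (1) when its darkness is >= ``threshold``.
    Idempotent on already-binary input for any threshold in (0, 1).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if isinstance(darkness, SpectrumImage):
        calibration = darkness.calibration
        darkness = darkness.pixels
    if calibration is None:
        raise ValueError("calibration required when passing a bare array")
    arr = np.asarray(darkness, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("darkness values must lie in [0, 1]")
    return SpectrumImage((arr >= threshold).astype(np.uint8), calibration)


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def median_filter_cross(image: SpectrumImage) -> SpectrumImage:
    """Cross-shaped 3x3 median filter removing salt-and-pepper noise.

    Each pixel is replaced by the median of the 5-element cross neighbourhood
    {self, up, down, left, right}; borders use edge replication.  On binary
    input this keeps a pixel at 1 iff at least 3 of the 5 cross members are 1,
    so isolated single pixels vanish while contiguous peak blobs survive.
    """
    out = ndimage.median_filter(image.pixels, footprint=_CROSS, mode="nearest")
    return SpectrumImage(out.astype(np.uint8), image.calibration)


def rasterize_peaklist(
    peaklist: PeakList,
    calibration: AxisCalibration,
    footprint_px: int = 3,
) -> SpectrumImage:
    """Render a peak list as a binary raster.

    Each peak maps to its pixel via the calibration and a square footprint of
    side ``footprint_px`` (odd) centred there is set to 1; footprints are
    clipped at the raster border.
    """
    if len(peaklist) == 0:
        raise ValueError("cannot rasterize an empty peak list")
    if footprint_px < 1 or footprint_px % 2 == 0:
        raise ValueError(f"footprint_px must be a positive odd integer, got {footprint_px}")
    half = footprint_px // 2
    pixels = np.zeros(calibration.shape(), dtype=np.uint8)
    for pk in peaklist.peaks:
        row, col = calibration.peak_to_pixel(pk.h_ppm, pk.c_ppm)
        r0, r1 = max(0, row - half), min(calibration.height_px, row + half + 1)
        c0, c1 = max(0, col - half), min(calibration.width_px, col + half + 1)
        pixels[r0:r1, c0:c1] = 1
    return SpectrumImage(pixels, calibration)


MANIFEST_COLUMNS = ["spectrum_id", "path", "family", "compound", "source"]


@dataclass
class DatasetManifest:
    """Labelled collection of spectra grouped into compound families.

    Families operationalize the "same publication = same class" rule: spectra
    sharing a family label are treated as structurally related.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        df = df[MANIFEST_COLUMNS].reset_index(drop=True)
        if df["spectrum_id"].duplicated().any():
            dup = df.loc[df["spectrum_id"].duplicated(), "spectrum_id"].tolist()
            raise ValueError(f"duplicate spectrum ids: {dup}")
        if (df["family"].astype(str).str.len() == 0).any():
            raise ValueError("family labels must be non-empty")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def spectrum_ids(self) -> list[str]:
        return self.records["spectrum_id"].tolist()

    @property
    def families(self) -> list[str]:
        return self.records["family"].tolist()

    def family_sizes(self) -> pd.Series:
        return self.records["family"].value_counts()

    def labels_for(self, ids: Sequence[str]) -> list[str]:
        lookup = dict(zip(self.records["spectrum_id"], self.records["family"]))
        return [lookup[i] for i in ids]

    def subset(self, ids: Iterable[str]) -> "DatasetManifest":
        ids = set(ids)
        return DatasetManifest(
            self.records[self.records["spectrum_id"].isin(ids)].reset_index(drop=True)
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DatasetManifest":
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest not found: {path}")
        return cls(pd.read_csv(path, sep="\t", dtype=str).fillna(""))


def filter_families(manifest: DatasetManifest, min_members: int) -> DatasetManifest:
    """Keep only records whose family has at least ``min_members`` spectra.

    Corpus-construction rule: families too small to form training pairs and
    meaningful retrieval targets are dropped wholesale (typical thresholds
    are 5 or 10 members); record order is preserved.
    """
    if min_members < 1:
        raise ValueError(f"min_members must be >= 1, got {min_members}")
    sizes = manifest.records["family"].value_counts()
    keep = sizes[sizes >= min_members].index
    df = manifest.records[manifest.records["family"].isin(keep)].reset_index(drop=True)
    return DatasetManifest(df)


def grid_capacity(
    h_lo: float, h_hi: float, h_res: float, c_lo: float, c_hi: float, c_res: float
) -> int:
    """Number of distinguishable peak positions in an HSQC window.

    With resolvable-shift limits ``h_res`` and ``c_res`` (ppm) the window
    tiles into round(span/res) cells per axis; e.g. the typical 1H range
    0.5-9.5 ppm at 0.02 ppm and 13C range 10-215 ppm at 0.1 ppm give
    450 x 2050 = 922,500 positions.
    """
    if not (h_hi > h_lo and c_hi > c_lo):
        raise ValueError("window upper bounds must exceed lower bounds")
    if h_res <= 0 or c_res <= 0:
        raise ValueError("resolutions must be positive")
    return int(round((h_hi - h_lo) / h_res)) * int(round((c_hi - c_lo) / c_res))


def nus_density(sampled_increments: int, total_increments: int) -> float:
    """Non-uniform-sampling density: sampled / total indirect-dimension increments."""
    if total_increments < 1:
        raise ValueError("total_increments must be >= 1")
    if sampled_increments < 0 or sampled_increments > total_increments:
        raise ValueError("sampled_increments must lie in [0, total_increments]")
    return sampled_increments / total_increments


def read_peaklist_csv(path: str | os.PathLike, compound_id: str | None = None) -> PeakList:
    """Read a peak list CSV with columns h_ppm, c_ppm[, intensity]."""
    df = pd.read_csv(path)
    for col in ("h_ppm", "c_ppm"):
        if col not in df.columns:
            raise ValueError(f"peak list {path} missing column {col!r}")
    inten = df["intensity"] if "intensity" in df.columns else pd.Series(1.0, index=df.index)
    peaks = [
        Peak(float(h), float(c), float(i))
        for h, c, i in zip(df["h_ppm"], df["c_ppm"], inten)
    ]
    cid = compound_id or os.path.splitext(os.path.basename(str(path)))[0]
    return PeakList(cid, peaks)


def write_peaklist_csv(peaklist: PeakList, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "h_ppm": [p.h_ppm for p in peaklist.peaks],
            "c_ppm": [p.c_ppm for p in peaklist.peaks],
            "intensity": [p.intensity for p in peaklist.peaks],
        }
    ).to_csv(path, index=False)
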