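"""Bacterial spot detection in confocal-like sections.

The original analysis located DAPI-stained bacteria with a trained neural
network. This module provides a deterministic classical stand-in with the
same input/output contract: a multiscale Laplacian-of-Gaussian (LoG) blob
detector with local-maximum suppression, validated against synthetic ground
truth. No numeric parity with the original detector is claimed.

Coordinate convention: continuous micrometres, origin at the centre of the
top-left pixel's corner, i.e. pixel index ``i`` maps to ``(i + 0.5) *
pixel_size_um``. ``x`` increases with column index, ``y`` with row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max

__all__ = [
    "ConfocalSection",
    "Detections",
    "EpitheliumTrace",
    "DetectorParams",
    "read_section",
    "write_section",
    "detect_spots",
    "load_epithelium",
    "evaluate_detections",
]


class MetadataError(ValueError):
    """Raised when a section image carries no usable pixel-size metadata."""


@dataclass(frozen=True)
class ConfocalSection:
    """Single-channel confocal-like image with physical pixel size.

    Parameters
    ----------
    intensities
        2D array of nonnegative intensities, shape ``(height_px, width_px)``.
    pixel_size_um
        Edge length of one pixel in micrometres (square pixels assumed).
    """

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError(f"intensities must be 2D, got shape {arr.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(arr < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "intensities", arr)

    @property
    def height_px(self) -> int:
        return self.intensities.shape[0]

    @property
    def width_px(self) -> int:
        return self.intensities.shape[1]

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um


@dataclass(frozen=True)
class EpitheliumTrace:
    """Ordered polyline marking the epithelial border, in micrometres."""

    vertices: np.ndarray  # (n, 2) columns x_um, y_um

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("trace needs >= 2 (x, y) vertices")
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("repeated consecutive vertices in trace")
        object.__setattr__(self, "vertices", v)

    @property
    def length_um(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.vertices, columns=["x_um", "y_um"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class Detections:
    """Detected spot centroids (micrometres) with detection responses."""

    centroids: np.ndarray  # (n, 2) x_um, y_um
    scores: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        s = np.asarray(self.scores, dtype=float).reshape(-1)
        if len(c) != len(s):
            raise ValueError("centroids and scores length mismatch")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.centroids)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.centroids, columns=["x_um", "y_um"])
        df["score"] = self.scores
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Detections":
        df = pd.read_csv(path)
        return cls(df[["x_um", "y_um"]].to_numpy(),
                   df.get("score", pd.Series(np.ones(len(df)))).to_numpy())


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the LoG blob detector.

    spot_sigma_um
        Expected Gaussian radius of one bacterium (default 0.5 um, roughly
        a 1-um coccus imaged at the diffraction limit).
    min_separation_um
        Minimum centre-to-centre distance between reported detections.
    response_threshold
        Minimum scale-normalised LoG response, relative to the image
        dynamic range, in (0, 1).
    min_intensity_quantile
        Background model: a peak must exceed this intensity quantile of the
        whole image to be kept.
    """

    spot_sigma_um: float = 0.5
    min_separation_um: float = 1.0
    response_threshold: float = 0.1
    min_intensity_quantile: float = 0.99
    scale_factors: tuple[float, ...] = (0.75, 1.0, 1.3)

    def __post_init__(self) -> None:
        if self.spot_sigma_um <= 0 or self.min_separation_um <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 < self.response_threshold < 1.0:
            raise ValueError("response_threshold must be in (0, 1)")
        if not 0.0 < self.min_intensity_quantile < 1.0:
            raise ValueError("min_intensity_quantile must be in (0, 1)")


# ---------------------------------------------------------------- image I/O


def write_section(path: str | Path, section: ConfocalSection,
                  sidecar: bool = True) -> None:
    """Write a section as 16-bit single-channel TIFF with pixel size metadata.

    Pixel size is recorded in the TIFF resolution tags (pixels per
    micrometre) and, when ``sidecar`` is true, mirrored in a ``.yaml``
    sidecar next to the image.
    """
    import yaml

    path = Path(path)
    arr = np.clip(np.rint(section.intensities), 0, 65535).astype(np.uint16)
    ppu = 1.0 / section.pixel_size_um
    tifffile.imwrite(
        path, arr, imagej=True, resolution=(ppu, ppu),
        metadata={"unit": "um"},
    )
    if sidecar:
        meta = {"pixel_size_um": float(section.pixel_size_um),
                "width_px": int(section.width_px),
                "height_px": int(section.height_px)}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    # resolution is pixels per unit; only trust it when the unit is
    # explicitly micrometres (as written by write_section) — bare TIFFs
    # carry a meaningless default resolution tag
    ij = tif.imagej_metadata or {}
    if ij.get("unit") not in ("um", "micron", "µm", "\\u00b5m"):
        return None
    return den / num


def read_section(path: str | Path,
                 pixel_size_override: float | None = None) -> ConfocalSection:
    """Read a TIFF section; pixel size from metadata, else the override.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    MetadataError
        If neither the TIFF metadata nor ``pixel_size_override`` provides
        a pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        px = _pixel_size_from_tiff(tif)
    if px is None:
        px = pixel_size_override
    if px is None:
        raise MetadataError(
            f"{path}: no pixel size in TIFF metadata and no override given"
        )
    return ConfocalSection(arr.astype(float), float(px))


def load_epithelium(path: str | Path) -> EpitheliumTrace:
    """Load an epithelium trace from a CSV of ordered x_um,y_um vertices."""
    df = pd.read_csv(path)
    try:
        v = df[["x_um", "y_um"]].to_numpy(dtype=float)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: expected numeric x_um,y_um columns") from exc
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{path}: non-numeric or non-finite vertex rows")
    return EpitheliumTrace(v)


# ---------------------------------------------------------------- detection


def _log_response(img: np.ndarray, sigmas_px: list[float]) -> np.ndarray:
    """Scale-normalised negative LoG, maximum over scales (bright blobs)."""
    resp = None
    for s in sigmas_px:
        r = -(s ** 2) * ndimage.gaussian_laplace(img, s)
        resp = r if resp is None else np.maximum(resp, r)
    return resp


def _greedy_separation(coords: np.ndarray, scores: np.ndarray,
                       min_sep: float) -> np.ndarray:
    """Indices of coords kept by greedy descending-score suppression."""
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    for i in order:
        xy = coords[i]
        if len(kept_xy) and np.min(np.hypot(*(kept_xy - xy).T)) < min_sep:
            continue
        kept.append(i)
        kept_xy = np.vstack([kept_xy, xy])
    return np.array(kept, dtype=int)


def detect_spots(section: ConfocalSection,
                 params: DetectorParams = DetectorParams()) -> Detections:
    """Detect bright blobs; returns centroids sorted by descending score.

    A multiscale LoG filter centred on ``spot_sigma_um`` is followed by
    local-maximum extraction, a background-quantile intensity gate, and
    greedy suppression so that no two centroids lie closer than
    ``min_separation_um``. Deterministic for a fixed input.
    """
    img = section.intensities.astype(float)
    empty = Detections(np.empty((0, 2)), np.empty(0))
    span = float(img.max() - img.min())
    if span == 0.0:
        return empty

    px = section.pixel_size_um
    sigmas = [params.spot_sigma_um / px * f for f in params.scale_factors]
    resp = _log_response(img, sigmas)
    thr = params.response_threshold * span

    min_dist_px = max(1, int(params.min_separation_um / px / 2))
    peaks = peak_local_max(resp, min_distance=min_dist_px,
                           threshold_abs=thr, exclude_border=False)
    if len(peaks) == 0:
        return empty

    background = float(np.quantile(img, params.min_intensity_quantile))
    keep = img[peaks[:, 0], peaks[:, 1]] >= background
    peaks = peaks[keep]
    if len(peaks) == 0:
        return empty

    xy = np.column_stack([(peaks[:, 1] + 0.5) * px, (peaks[:, 0] + 0.5) * px])
    scores = resp[peaks[:, 0], peaks[:, 1]]
    idx = _greedy_separation(xy, scores, params.min_separation_um)
    order = idx[np.argsort(-scores[idx], kind="stable")]
    return Detections(xy[order], scores[order])


# --------------------------------------------------------------- evaluation


def evaluate_detections(detections: Detections | np.ndarray,
                        truth_centroids: np.ndarray,
                        radius_um: float) -> dict[str, float]:
    """Precision/recall/F1 by greedy one-to-one matching within a radius.

    Candidate (detection, truth) pairs within ``radius_um`` are matched
    greedily in ascending distance; each point participates in at most one
    match. With no detections, precision is 0 by convention (1 if there is
    also no truth).
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    det = detections.centroids if isinstance(detections, Detections) \
        else np.asarray(detections, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth_centroids, dtype=float).reshape(-1, 2)

    n_det, n_truth = len(det), len(truth)
    matches = 0
    if n_det and n_truth:
        d = cdist(det, truth)
        pairs = np.argwhere(d <= radius_um)
        order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
        used_det: set[int] = set()
        used_truth: set[int] = set()
        for i, j in pairs[order]:
            if i in used_det or j in used_truth:
                continue
            used_det.add(int(i))
            used_truth.add(int(j))
            matches += 1
    precision = matches / n_det if n_det else (1.0 if n_truth == 0 else 0.0)
    recall = matches / n_truth if n_truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_matched": matches, "n_detected": n_det, "n_truth": n_truth}
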