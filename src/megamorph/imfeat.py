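"""Frame segmentation, morphometric features (A, MFD, P), junk flagging, resizing.

The three features mirror what a sinking-specimen imaging device exports per
frame: projected area, maximum Feret diameter (the longest distance between
any two boundary points, a caliper-style size measure) and perimeter.

Conventions (these differ between libraries by >10%, so they are fixed here):

* coordinates are row-major with origin top-left; a pixel is the point at
  its integer center,
* the specimen is dark on a light background,
* MFD is the maximum Euclidean distance between boundary-pixel centers,
* perimeter is the length of the Moore-traced outer boundary polygon of the
  largest component (unit steps for 4-neighbor moves, sqrt(2) for
  diagonals); an isolated pixel has perimeter 0 under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .synthgen import FrameImage


class EmptyMaskError(ValueError):
    """Raised when a frame contains no foreground under the threshold policy."""


@dataclass
class BinaryMask:
    """Foreground mask aligned to its source frame (True = specimen)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def coords(self) -> np.ndarray:
        """(row, col) centers of foreground pixels."""
        return np.argwhere(self.data)


@dataclass
class FrameFeatures:
    specimen_id: str
    camera_id: int
    frame_index: int
    area_mm2: float
    mfd_mm: float
    perimeter_mm: float
    solidity: float
    height: int = 0
    width: int = 0
    nontarget_flag: bool = False


def segment(frame: FrameImage, threshold: float | str = "auto") -> BinaryMask:
    """Largest dark connected component (8-connectivity) under the threshold.

    ``threshold="auto"`` uses Otsu's bimodal threshold; a float fixes the
    gray level below which pixels count as foreground.
    """
    img = np.asarray(frame.pixels, dtype=float)
    thr = float(threshold_otsu(img)) if threshold == "auto" else float(threshold)
    fg = img < thr
    if not fg.any():
        raise EmptyMaskError(
            f"no foreground in frame {frame.specimen_id}/cam{frame.camera_id}/{frame.frame_index}"
        )
    lab = label(fg, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return BinaryMask(lab == int(counts.argmax()))


def area(mask: BinaryMask, px_per_mm: float) -> float:
    """Projected area: foreground pixel count / px_per_mm**2."""
    n = int(mask.data.sum())
    if n == 0:
        raise EmptyMaskError("empty mask")
    return n / px_per_mm**2


def boundary_pixels(mask: BinaryMask) -> np.ndarray:
    """Foreground pixels with a 4-neighbor outside the foreground (or on the edge)."""
    m = mask.data
    if not m.any():
        raise EmptyMaskError("empty mask")
    inner = np.zeros_like(m)
    inner[1:-1, 1:-1] = m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    return np.argwhere(m & ~inner)


def max_feret(mask: BinaryMask, px_per_mm: float) -> float:
    """Maximum Feret diameter between boundary-pixel centers, in mm.

    Computed on the convex hull of the boundary pixels (the pairwise maximum
    of a point set is attained between hull vertices); degenerate collinear
    masks fall back to the brute-force pairwise maximum.
    """
    pts = boundary_pixels(mask).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear point set; brute force below
    return float(pdist(pts).max()) / px_per_mm


def max_feret_bruteforce(mask: BinaryMask, px_per_mm: float) -> float:
    """O(n^2) pairwise maximum over all boundary pixels (oracle implementation)."""
    pts = boundary_pixels(mask).astype(float)
    if len(pts) == 1:
        return 0.0
    return float(pdist(pts).max()) / px_per_mm


def _moore_trace(m: np.ndarray) -> list[tuple[int, int]]:
    """Moore boundary trace (clockwise) of the foreground's outer contour.

    Uses Jacob's stopping criterion: terminate when the start pixel is
    re-entered from the start backtrack position.
    """
    rows, cols = np.nonzero(m)
    start = (int(rows[0]), int(cols[np.argmin(cols[rows == rows[0]])]))
    # Moore neighborhood in clockwise order starting West
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

    def inside(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < m.shape[0] and 0 <= p[1] < m.shape[1] and m[p]

    contour = [start]
    backtrack = (start[0], start[1] - 1)  # came from the West (scan direction)
    p = start
    first_transition: tuple | None = None
    while True:
        bdir = (backtrack[0] - p[0], backtrack[1] - p[1])
        k0 = nbrs.index(bdir)
        nxt = None
        for j in range(1, 9):
            d = nbrs[(k0 + j) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if inside(q):
                nxt = q
                break
            backtrack = q
        if nxt is None:
            return contour  # isolated pixel
        # Jacob's criterion: stop when the initial transition repeats
        if first_transition is None:
            first_transition = (p, nxt)
        elif (p, nxt) == first_transition:
            break
        contour.append(nxt)
        p = nxt
        if len(contour) > 4 * m.size:  # pragma: no cover - safety net
            raise RuntimeError("boundary trace failed to terminate")
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def perimeter(mask: BinaryMask, px_per_mm: float) -> float:
    """Length of the traced outer boundary polygon of the largest component, in mm."""
    m = mask.data
    if not m.any():
        raise EmptyMaskError("empty mask")
    lab = label(m, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    contour = np.array(_moore_trace(lab == int(counts.argmax())), dtype=float)
    if len(contour) < 2:
        return 0.0
    closed = np.vstack([contour, contour[:1]])
    steps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return float(steps.sum()) / px_per_mm


def solidity(mask: BinaryMask) -> float:
    """Foreground area / convex-hull area (1 for convex blobs)."""
    props = regionprops(mask.data.astype(np.uint8))
    if not props:
        raise EmptyMaskError("empty mask")
    return float(props[0].solidity)


def compute_frame_features(
    frame: FrameImage, threshold: float | str = "auto"
) -> FrameFeatures:
    """Segment one frame and measure A, MFD, P (in mm units) and solidity."""
    mask = segment(frame, threshold)
    ppm = frame.px_per_mm
    return FrameFeatures(
        specimen_id=frame.specimen_id,
        camera_id=frame.camera_id,
        frame_index=frame.frame_index,
        area_mm2=area(mask, ppm),
        mfd_mm=max_feret(mask, ppm),
        perimeter_mm=perimeter(mask, ppm),
        solidity=solidity(mask),
        height=frame.pixels.shape[0],
        width=frame.pixels.shape[1],
    )


def flag_nontarget(
    features: list[FrameFeatures],
    area_bounds_mm2: tuple[float, float] = (2.0, np.inf),
    solidity_bounds: tuple[float, float] = (0.25, 1.0),
) -> list[FrameFeatures]:
    """Flag frames whose area or solidity falls outside plausible specimen bounds.

    An automated stand-in for the manual removal of bubbles, forceps and
    debris frames; nothing is deleted, frames are only flagged.
    """
    out = []
    for f in features:
        bad = not (
            area_bounds_mm2[0] <= f.area_mm2 <= area_bounds_mm2[1]
            and solidity_bounds[0] <= f.solidity <= solidity_bounds[1]
        )
        out.append(replace(f, nontarget_flag=bad))
    return out


def resize_with_global_aspect(
    pixels: np.ndarray,
    global_max_dim: int,
    target: int,
    seed: int = 0,
) -> np.ndarray:
    """Scale a frame by target/global_max_dim, center, and border-pad to target^2.

    Every frame in a dataset is scaled by the same factor (derived from the
    largest frame dimension G over the whole dataset), so the size ratios
    between specimens — the signal biomass models rely on — survive the
    resize. Padding pixels are sampled from the resized frame's border.
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    if global_max_dim < max(h, w):
        raise ValueError(
            f"global_max_dim {global_max_dim} is smaller than the frame's own max dimension {max(h, w)}"
        )
    if target < 1:
        raise ValueError("target size must be >= 1")
    s = target / global_max_dim
    nh, nw = max(int(round(h * s)), 1), max(int(round(w * s)), 1)
    content = np.asarray(
        Image.fromarray(pixels.astype(np.uint8)).resize((nw, nh), Image.BILINEAR)
    )
    border = np.concatenate([content[0, :], content[-1, :], content[:, 0], content[:, -1]])
    rng = np.random.default_rng(seed)
    out = rng.choice(border, size=(target, target)).astype(np.uint8)
    top, left = (target - nh) // 2, (target - nw) // 2
    out[top : top + nh, left : left + nw] = content
    return out


# ---------------------------------------------------------------------------
# bulk IO


def features_table(features: list[FrameFeatures]) -> pd.DataFrame:
    """features.csv content, one row per frame."""
    return pd.DataFrame(
        {
            "specimen_id": [f.specimen_id for f in features],
            "camera_id": [f.camera_id for f in features],
            "frame_index": [f.frame_index for f in features],
            "area_mm2": [f.area_mm2 for f in features],
            "mfd_mm": [f.mfd_mm for f in features],
            "perimeter_mm": [f.perimeter_mm for f in features],
            "solidity": [f.solidity for f in features],
            "height": [f.height for f in features],
            "width": [f.width for f in features],
            "nontarget_flag": [f.nontarget_flag for f in features],
        }
    )


def write_png(frame: FrameImage, path) -> None:
    Image.fromarray(frame.pixels, mode="L").save(path)


def read_png(path, specimen_id: str, camera_id: int, frame_index: int, px_per_mm: float) -> FrameImage:
    return FrameImage(
        pixels=np.asarray(Image.open(path).convert("L")),
        specimen_id=specimen_id,
        camera_id=camera_id,
        frame_index=frame_index,
        px_per_mm=px_per_mm,
    )
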