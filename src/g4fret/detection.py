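"""Spot detection, trace extraction and spot counting on rendered movies.

Detection runs on the mean of the first ten green-excitation frames:
a median-filter background is subtracted and local maxima above
``k`` robust standard deviations (median absolute deviation) are kept,
with a minimum separation.  Integer-pixel maxima are sufficient for
aperture extraction at the default PSF width — no sub-pixel localization
is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .photophysics import FrameStack, IntensityTrace

__all__ = [
    "detect_spots",
    "extract_traces",
    "SpotCountSeries",
    "count_spots_series",
    "count_spots_from_movies",
    "match_spots",
]


def detect_spots(
    image: np.ndarray,
    threshold_k: float = 5.0,
    min_sep_px: int = 4,
    background_size: int = 15,
) -> pd.DataFrame:
    """Find diffraction-limited spots in an averaged image.

    Returns a DataFrame with columns ``y``, ``x`` (integer pixels) and
    ``intensity`` (background-subtracted peak value).  Deterministic for a
    fixed input; an empty image yields an empty table.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be > 0")
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    bg = ndimage.median_filter(img, size=background_size)
    resid = img - bg
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = max(1.4826 * mad, 1e-6)
    coords = peak_local_max(
        resid, min_distance=min_sep_px, threshold_abs=threshold_k * sigma
    )
    if coords.size == 0:
        return pd.DataFrame(columns=["y", "x", "intensity"])
    intens = resid[coords[:, 0], coords[:, 1]]
    order = np.argsort(-intens)
    return pd.DataFrame(
        {"y": coords[order, 0], "x": coords[order, 1], "intensity": intens[order]}
    ).reset_index(drop=True)


def match_spots(
    detected: pd.DataFrame, truth_yx: np.ndarray, tol_px: float = 2.0
) -> Tuple[int, int, int]:
    """Greedy nearest matching of detections to ground-truth centers.

    Returns ``(n_matched, n_false_positive, n_missed)``.
    """
    truth = np.asarray(truth_yx, dtype=float)
    if len(detected) == 0:
        return 0, 0, len(truth)
    det = detected[["y", "x"]].to_numpy(dtype=float)
    tree = cKDTree(truth)
    dist, idx = tree.query(det)
    used = set()
    matched = 0
    for d, i in sorted(zip(dist, idx)):
        if d <= tol_px and i not in used:
            used.add(i)
            matched += 1
    return matched, len(det) - matched, len(truth) - matched


def extract_traces(
    stack: FrameStack,
    spots: pd.DataFrame,
    aperture_px: int = 4,
) -> Tuple[List[IntensityTrace], int]:
    """Background-subtracted aperture sums per frame for both channels.

    The aperture is a ``(2*aperture_px+1)`` square; the local background
    per frame is the median pixel value of the surrounding 2-px border,
    scaled by the aperture area.  Spots whose aperture (or whose mapped
    acceptor-channel aperture) leaves the image are skipped; the number of
    skipped spots is returned alongside the traces.
    """
    a = aperture_px
    b = a + 2  # outer box for the background ring
    h, w = stack.donor.shape[1:]
    dy, dx = stack.channel_offset
    traces: List[IntensityTrace] = []
    skipped = 0
    area = (2 * a + 1) ** 2

    def aperture_series(cube: np.ndarray, y: int, x: int) -> np.ndarray:
        inner = cube[:, y - a : y + a + 1, x - a : x + a + 1].astype(float)
        outer = cube[:, y - b : y + b + 1, x - b : x + b + 1].astype(float)
        ring_sum = outer.sum(axis=(1, 2)) - inner.sum(axis=(1, 2))
        ring_n = (2 * b + 1) ** 2 - area
        local_bg = ring_sum / ring_n
        return inner.sum(axis=(1, 2)) - local_bg * area

    for i, row in spots.iterrows():
        y, x = int(round(row["y"])), int(round(row["x"]))
        ya, xa = int(round(y + dy)), int(round(x + dx))
        if (
            y - b < 0 or y + b + 1 > h or x - b < 0 or x + b + 1 > w
            or ya - b < 0 or ya + b + 1 > h or xa - b < 0 or xa + b + 1 > w
        ):
            skipped += 1
            continue
        donor = aperture_series(stack.donor, y, x)
        acceptor = aperture_series(stack.acceptor, ya, xa)
        traces.append(
            IntensityTrace(
                t=stack.t.copy(),
                donor=donor,
                acceptor=acceptor,
                exc=stack.exc.copy(),
                frame_s=stack.frame_s,
                background=0.0,
                molecule_id=int(i),
                truth={"y": y, "x": x},
            )
        )
    if skipped:
        warnings.warn(f"skipped {skipped} out-of-bounds spot(s)", stacklevel=2)
    return traces, skipped


@dataclass
class SpotCountSeries:
    """Spot counts over time with the 3-point joint smoothing rule.

    Consecutive groups of three counts (and their times) are averaged with
    a rolling window, so the smoothed series is two points shorter than
    the raw one.  With fewer than three points only the raw series is
    available and ``too_short`` is set.
    """

    t_s: np.ndarray
    counts: np.ndarray
    t_smooth_s: np.ndarray
    smoothed: np.ndarray
    too_short: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "count": self.counts})


def count_spots_series(times_s: Sequence[float], counts: Sequence[float]) -> SpotCountSeries:
    """Build a count series and apply the window-3 rolling mean jointly to
    counts and times."""
    t = np.asarray(times_s, dtype=float)
    c = np.asarray(counts, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and counts must have equal length")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    if t.size < 3:
        return SpotCountSeries(t, c, np.array([]), np.array([]), too_short=True)
    kernel = np.ones(3) / 3.0
    return SpotCountSeries(
        t_s=t,
        counts=c,
        t_smooth_s=np.convolve(t, kernel, mode="valid"),
        smoothed=np.convolve(c, kernel, mode="valid"),
    )


def count_spots_from_movies(
    stacks: Sequence[FrameStack],
    times_s: Sequence[float],
    threshold_k: float = 5.0,
    min_sep_px: int = 4,
) -> SpotCountSeries:
    """Detect and count spots in a sequence of short movies over time."""
    counts = [
        len(detect_spots(s.green_average(), threshold_k, min_sep_px)) for s in stacks
    ]
    return count_spots_series(times_s, counts)
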