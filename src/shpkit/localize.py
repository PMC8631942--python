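"""Single-molecule spot detection and trajectory-level analyses.

Sub-pixel localization (difference-of-Gaussians band-pass, local maxima,
2-D Gaussian refinement), intensity-histogram mixture fitting,
photobleaching step counting by penalized change-point segmentation, and
two-channel colocalization with a configurable time window.

Coordinates are 0-based with the origin at the center of the top-left
pixel; both channels are assumed registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from sklearn.mixture import GaussianMixture

from .exceptions import DegenerateDataError, InvalidParameterError, UndefinedRateError
from .hmm import Trajectory

DEFAULT_THRESHOLD_SIGMAS = 5.0
DEFAULT_COLOC_RADIUS_PX = 2.0
DEFAULT_COLOC_WINDOW_S = 0.5


@dataclass
class Spot:
    """One sub-pixel localization."""

    x: float
    y: float
    amplitude: float
    sigma_px: float
    frame: int
    channel: str = "ch0"


@dataclass
class SpotTable:
    """Detections across frames for one channel (sorted by frame)."""

    spots: list[Spot]
    frame_rate: float = 20.0
    pixel_size_nm: float = 160.0

    def __post_init__(self):
        self.spots = sorted(self.spots, key=lambda s: (s.frame, s.channel, s.y, s.x))

    def __len__(self) -> int:
        return len(self.spots)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"frame": s.frame, "channel": s.channel, "x_px": s.x, "y_px": s.y,
             "amplitude": s.amplitude, "sigma_px": s.sigma_px}
            for s in self.spots
        ])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate: float = 20.0,
                       pixel_size_nm: float = 160.0) -> "SpotTable":
        spots = [
            Spot(x=row.x_px, y=row.y_px, amplitude=row.amplitude,
                 sigma_px=row.sigma_px, frame=int(row.frame), channel=row.channel)
            for row in df.itertuples()
        ]
        return cls(spots=spots, frame_rate=frame_rate, pixel_size_nm=pixel_size_nm)


def _robust_noise(values: np.ndarray) -> float:
    """1.4826 * median absolute deviation."""
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _gaussian2d(params, xs, ys):
    amp, x0, y0, sigma, offset = params
    return offset + amp * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sigma**2))


def _refine_spot(image, px, py, psf_sigma, window_radius=None):
    """Least-squares 2-D Gaussian refinement around an integer peak."""
    h, w = image.shape
    r = window_radius or max(3, int(np.ceil(3 * psf_sigma)))
    x0, x1 = max(px - r, 0), min(px + r + 1, w)
    y0, y1 = max(py - r, 0), min(py + r + 1, h)
    patch = image[y0:y1, x0:x1]
    ys, xs = np.mgrid[y0:y1, x0:x1]
    p0 = (float(image[py, px] - patch.min()), float(px), float(py),
          float(psf_sigma), float(patch.min()))

    def resid(p):
        return (_gaussian2d(p, xs, ys) - patch).ravel()

    try:
        sol = least_squares(resid, p0, max_nfev=200)
    except Exception:
        return None
    amp, x, y, sigma, _ = sol.x
    if amp <= 0 or not (x0 - 1 <= x <= x1) or not (y0 - 1 <= y <= y1):
        return None
    return float(x), float(y), float(amp), float(abs(sigma))


def detect_spots(
    image: np.ndarray,
    threshold_sigmas: float = DEFAULT_THRESHOLD_SIGMAS,
    psf_sigma: float = 1.5,
    frame: int = 0,
    channel: str = "ch0",
    refine: bool = True,
) -> list[Spot]:
    """Detect diffraction-limited spots in one frame.

    Difference-of-Gaussians band-pass, local maxima above
    ``threshold_sigmas`` times the robust (MAD) noise of the band-passed
    image, then sub-pixel 2-D Gaussian least-squares refinement.
    Deterministic. A constant image returns an empty list with a warning.
    """
    if threshold_sigmas <= 0:
        raise InvalidParameterError("threshold_sigmas must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("detect_spots expects a 2-D image")
    if np.ptp(img) == 0:
        warnings.warn("constant image; no spots detected", stacklevel=2)
        return []

    bandpass = ndi.gaussian_filter(img, psf_sigma) - ndi.gaussian_filter(img, 2.0 * psf_sigma)
    noise = _robust_noise(bandpass)
    threshold = threshold_sigmas * noise + 1e-12
    peaks = peak_local_max(
        bandpass,
        min_distance=max(1, int(round(2 * psf_sigma))),
        threshold_abs=threshold,
        exclude_border=max(1, int(round(psf_sigma))),
    )

    spots = []
    for py, px in peaks:
        if refine:
            fit = _refine_spot(img, px, py, psf_sigma)
            if fit is None:
                continue
            x, y, amp, sigma = fit
        else:
            x, y, amp, sigma = float(px), float(py), float(bandpass[py, px]), psf_sigma
        spots.append(Spot(x=x, y=y, amplitude=amp, sigma_px=sigma,
                          frame=frame, channel=channel))
    return spots


def detect_spots_stack(
    stack: np.ndarray,
    threshold_sigmas: float = DEFAULT_THRESHOLD_SIGMAS,
    psf_sigma: float = 1.5,
    channel: str = "ch0",
    frame_rate: float = 20.0,
    refine: bool = True,
) -> SpotTable:
    """Run :func:`detect_spots` on every frame of a stack."""
    spots: list[Spot] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f, frame_img in enumerate(stack):
            spots.extend(detect_spots(frame_img, threshold_sigmas, psf_sigma,
                                      frame=f, channel=channel, refine=refine))
    return SpotTable(spots=spots, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# intensity histograms
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Gaussian mixture fit of a spot-intensity distribution."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: dict


def intensity_histogram_fit(intensities: Sequence[float],
                            max_components: int = 2) -> MixtureFit:
    """Maximum-likelihood 1- and 2-component Gaussian fits, chosen by BIC."""
    x = np.asarray(intensities, dtype=float).reshape(-1, 1)
    if x.size < 50:
        raise InvalidParameterError("need >= 50 intensity values")
    if np.std(x) == 0:
        raise DegenerateDataError("zero-variance intensity data")

    best = None
    bics = {}
    for n in range(1, max_components + 1):
        gm = GaussianMixture(n_components=n, covariance_type="full",
                             random_state=0, n_init=3)
        gm.fit(x)
        bics[n] = float(gm.bic(x))
        if best is None or bics[n] < bics[best[0]]:
            best = (n, gm)
    n, gm = best
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        n_components=n,
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(n, -1)[:, 0])[order],
        weights=gm.weights_[order],
        bic=bics,
    )


# ---------------------------------------------------------------------------
# photobleaching step counting
# ---------------------------------------------------------------------------

@dataclass
class BleachProfile:
    """Downward intensity steps found in one trace."""

    step_count: int
    step_frames: np.ndarray
    step_sizes: np.ndarray        # negative = intensity loss
    segment_means: np.ndarray
    change_points: np.ndarray


def _best_split(y: np.ndarray, min_size: int):
    """Best single change-point by residual sum of squares."""
    n = y.size
    if n < 2 * min_size:
        return None, np.inf
    csum = np.cumsum(y)
    csum2 = np.cumsum(y**2)
    ks = np.arange(min_size, n - min_size + 1)
    left_n = ks
    right_n = n - ks
    left_sum = csum[ks - 1]
    right_sum = csum[-1] - left_sum
    left_rss = csum2[ks - 1] - left_sum**2 / left_n
    right_rss = (csum2[-1] - csum2[ks - 1]) - right_sum**2 / right_n
    total = left_rss + right_rss
    i = int(np.argmin(total))
    return int(ks[i]), float(total[i])


def count_bleach_steps(
    traj: Trajectory | np.ndarray,
    penalty: float | None = None,
    min_segment: int = 3,
) -> BleachProfile:
    """Count discrete photobleaching steps by change-point segmentation.

    Greedy binary segmentation of the intensity trace into piecewise
    constant segments; a split is kept while it improves a
    Bayes-information cost ``n*log(RSS/n) + 2*k*log(n)`` (two parameters
    per breakpoint). Downward jumps between consecutive segment means are
    counted as bleaching steps.
    """
    y = np.asarray(traj.intensities if isinstance(traj, Trajectory) else traj,
                   dtype=float)
    n = y.size
    if n < 20:
        raise InvalidParameterError("need >= 20 frames for step counting")
    if penalty is None:
        penalty = 2.0 * np.log(n)

    def rss(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    change_points: list[int] = []
    segments = [(0, n)]
    improved = True
    while improved:
        improved = False
        best_gain, best_cp, best_seg = 0.0, None, None
        for idx, (a, b) in enumerate(segments):
            seg = y[a:b]
            k, split_rss = _best_split(seg, min_segment)
            if k is None:
                continue
            gain = (b - a) * _safe_log(rss(seg) / (b - a)) \
                - (b - a) * _safe_log(split_rss / (b - a)) - penalty
            if gain > best_gain:
                best_gain, best_cp, best_seg = gain, a + k, idx
        if best_cp is not None:
            a, b = segments[best_seg]
            segments[best_seg:best_seg + 1] = [(a, best_cp), (best_cp, b)]
            change_points.append(best_cp)
            improved = True

    change_points.sort()
    edges = [0] + change_points + [n]
    means = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    diffs = np.diff(means)
    down = diffs < 0
    return BleachProfile(
        step_count=int(down.sum()),
        step_frames=np.asarray(change_points)[down],
        step_sizes=diffs[down],
        segment_means=means,
        change_points=np.asarray(change_points),
    )


def _safe_log(v: float) -> float:
    return float(np.log(max(v, 1e-300)))


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def _merge_positions(table: SpotTable, radius: float) -> np.ndarray:
    """Collapse per-frame detections into unique spot positions."""
    if not table.spots:
        return np.zeros((0, 2))
    pts = np.array([(s.x, s.y) for s in table.spots])
    merged: list[list[float]] = []
    counts: list[int] = []
    for x, y in pts:
        placed = False
        for i, (mx, my) in enumerate(merged):
            if (x - mx) ** 2 + (y - my) ** 2 <= radius**2:
                c = counts[i]
                merged[i] = [(mx * c + x) / (c + 1), (my * c + y) / (c + 1)]
                counts[i] += 1
                placed = True
                break
        if not placed:
            merged.append([x, y])
            counts.append(1)
    return np.asarray(merged)


def colocalization_rate(
    receptor_spots: SpotTable,
    ligand_spots: SpotTable,
    radius: float = DEFAULT_COLOC_RADIUS_PX,
    window: float = DEFAULT_COLOC_WINDOW_S,
    window_mode: str = "any",
) -> float:
    """Fraction of receptor spots with >= 1 ligand detection within ``radius``.

    ``window_mode="first"`` restricts ligand detections to the first
    ``window`` seconds of the acquisition; ``"any"`` (default) accepts a
    detection inside any sliding window of that length, which for
    window <= acquisition span is equivalent to accepting any frame.
    Returns colocalized / total, in [0, 1].
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    if window_mode not in ("any", "first"):
        raise InvalidParameterError("window_mode must be 'any' or 'first'")
    if receptor_spots.frame_rate != ligand_spots.frame_rate:
        raise InvalidParameterError("channels must share a frame rate")

    receptors = _merge_positions(receptor_spots, radius)
    if receptors.shape[0] == 0:
        raise UndefinedRateError("no receptor spots; rate undefined")

    max_frame = window * receptor_spots.frame_rate
    lig = [
        (s.x, s.y) for s in ligand_spots.spots
        if window_mode == "any" or s.frame < max_frame
    ]
    if not lig:
        return 0.0
    tree = cKDTree(np.asarray(lig))
    hits = tree.query_ball_point(receptors, r=radius)
    colocalized = sum(1 for h in hits if h)
    return colocalized / receptors.shape[0]
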