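"""Single-molecule spot detection, sub-pixel fitting, linking, registration.

Detection works by Pearson-normalized cross-correlation between the image
and an 11x11 Gaussian template (sigma = 2 px), thresholded at 0.25 and
labeled into candidate spots.  Each candidate is then refined by a
least-squares fit of a symmetric Gaussian plus an inclined-plane background
(seven parameters: I0, xg, yg, sigma_A, a, b, I_back).  Spots in
consecutive frames are linked when closer than 6 px, shortest connections
first, each spot used at most once.  Trajectories leaving the cell mask or
with unphysical fitted widths (sigma_A outside [1.5, 2.5] px) are removed.
A similarity transform estimated from fiducial beads registers a second
color channel onto the first.

Coordinates are 0-based pixel indices; a spot position is a continuous
(x, y) with pixel centers at integers.  Conversion to micrometres happens
at the statistics boundary via the configured pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

__all__ = [
    "Spot", "Trajectory", "ChannelTransform",
    "gaussian_template", "correlation_map", "detect_spots", "fit_spot",
    "detect_and_fit", "link_frames", "link_trajectories",
    "filter_trajectories", "fit_channel_transform", "track_movie",
]

CORR_THRESHOLD = 0.25
LINK_MAX_DIST = 6.0
SIGMA_BOUNDS = (1.5, 2.5)
ROI_HALF = 5  # template half-width R; fit ROI is (2R+1)^2


@dataclass
class Spot:
    frame: int
    x: float            # sub-pixel, px
    y: float
    i0: float           # fitted peak amplitude, a.u.
    sigma_a: float      # fitted width, px
    a: float            # background slope along x, a.u./px
    b: float            # background slope along y, a.u./px
    i_back: float       # background offset, a.u.
    label: int = -1     # connected-component id from detection


@dataclass
class Trajectory:
    spots: list = field(default_factory=list)
    cell_id: object = None

    @property
    def frames(self) -> np.ndarray:
        return np.asarray([s.frame for s in self.spots])

    @property
    def positions(self) -> np.ndarray:
        """(T, 2) array of (x, y) in pixels."""
        return np.asarray([(s.x, s.y) for s in self.spots])

    @property
    def intensities(self) -> np.ndarray:
        return np.asarray([s.i0 for s in self.spots])

    @property
    def first_intensity(self) -> float:
        return self.spots[0].i0

    def duration(self, dt: float = 0.033) -> float:
        return (len(self.spots) - 1) * dt

    def positions_um(self, pixel_size: float) -> np.ndarray:
        return self.positions * pixel_size

    def __len__(self) -> int:
        return len(self.spots)


def gaussian_template(sigma: float = 2.0, half_width: int = ROI_HALF) -> np.ndarray:
    """Symmetric 2-D Gaussian on a (2R+1)^2 support, maximum at the center."""
    idx = np.arange(-half_width, half_width + 1)
    g = np.exp(-(idx[:, None] ** 2 + idx[None, :] ** 2) / (2.0 * sigma ** 2))
    return g / (np.sqrt(2.0 * np.pi) * sigma)


def correlation_map(image: np.ndarray, template: np.ndarray | None = None):
    """Pearson correlation of every template-sized window with the template.

    Returns ``(corr, valid)``: values in [-1, 1] at interior pixels; the
    border of half the template width, where the window would leave the
    image, is marked invalid (NaN in ``corr``, False in ``valid``).  A
    constant window has undefined correlation and is set to 0.
    """
    if template is None:
        template = gaussian_template()
    image = np.asarray(image, dtype=np.float64)
    k = template.shape[0]
    if image.shape[0] < k or image.shape[1] < k:
        raise ValueError("image smaller than template")
    r = k // 2
    npix = k * k
    tz = template - template.mean()
    t_norm = np.sqrt(np.sum(tz ** 2))

    num = ndimage.correlate(image, tz, mode="constant")
    s1 = ndimage.correlate(image, np.ones_like(template), mode="constant")
    s2 = ndimage.correlate(image ** 2, np.ones_like(template), mode="constant")
    var = np.clip(s2 - s1 ** 2 / npix, 0.0, None)
    denom = t_norm * np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    valid = np.zeros(image.shape, dtype=bool)
    valid[r:image.shape[0] - r, r:image.shape[1] - r] = True
    corr[~valid] = np.nan
    return corr, valid


def detect_spots(corr: np.ndarray, threshold: float = CORR_THRESHOLD):
    """Threshold the correlation map and return labeled candidate centroids.

    Returns ``(centroids, labels)``: centroids is an (N, 2) array of (x, y)
    component centroids; labels the labeled component image.
    """
    binary = np.nan_to_num(corr, nan=-1.0) >= threshold
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.empty((0, 2)), labels
    com = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    centroids = np.asarray([(x, y) for (y, x) in com])
    return centroids, labels


def _spot_model(params, xs, ys):
    i0, xg, yg, sa, a, b, iback = params
    g = i0 * np.exp(-((xs - xg) ** 2 + (ys - yg) ** 2) / (2.0 * sa ** 2))
    return g + a * (xs - xg) + b * (ys - yg) + iback


def fit_spot(image: np.ndarray, centroid, frame: int = 0, label: int = -1,
             roi_half: int = ROI_HALF, sigma_guess: float = 2.0) -> Spot | None:
    """Least-squares Gaussian + inclined-plane fit within the detection ROI.

    Returns None (counted by the caller) for spots too close to the border
    for a full ROI, or when the fit does not converge.
    """
    h, w = image.shape
    cx, cy = float(centroid[0]), float(centroid[1])
    ix, iy = int(round(cx)), int(round(cy))
    if ix < roi_half or iy < roi_half or ix >= w - roi_half or iy >= h - roi_half:
        return None
    sl = np.s_[iy - roi_half:iy + roi_half + 1, ix - roi_half:ix + roi_half + 1]
    patch = np.asarray(image[sl], dtype=np.float64)
    ys, xs = np.mgrid[iy - roi_half:iy + roi_half + 1, ix - roi_half:ix + roi_half + 1]
    back0 = float(np.median(patch))
    amp0 = float(patch.max() - back0)
    p0 = [max(amp0, 1e-6), cx, cy, sigma_guess, 0.0, 0.0, back0]

    def resid(p):
        return (_spot_model(p, xs, ys) - patch).ravel()

    try:
        res = least_squares(resid, p0, method="lm", max_nfev=400)
    except Exception:
        return None
    if not res.success and res.status <= 0:
        return None
    i0, xg, yg, sa, a, b, iback = res.x
    sa = abs(sa)
    if not (ix - roi_half <= xg <= ix + roi_half
            and iy - roi_half <= yg <= iy + roi_half) or sa <= 0:
        return None
    return Spot(frame=frame, x=float(xg), y=float(yg), i0=float(i0),
                sigma_a=float(sa), a=float(a), b=float(b),
                i_back=float(iback), label=label)


def detect_and_fit(image: np.ndarray, frame: int = 0,
                   template: np.ndarray | None = None,
                   threshold: float = CORR_THRESHOLD):
    """Correlate, threshold, and fit every candidate in one frame.

    Returns ``(spots, n_dropped)`` where dropped counts border and
    non-converged candidates.
    """
    corr, _ = correlation_map(image, template)
    centroids, labels = detect_spots(corr, threshold)
    spots, dropped = [], 0
    for i, c in enumerate(centroids):
        s = fit_spot(image, c, frame=frame, label=i + 1)
        if s is None:
            dropped += 1
        else:
            spots.append(s)
    return spots, dropped


# ---------------------------------------------------------------------------
# Linking

def link_frames(prev_xy: np.ndarray, curr_xy: np.ndarray,
                max_dist: float = LINK_MAX_DIST, method: str = "greedy"):
    """One-to-one matching of spots between consecutive frames.

    All candidate pairs closer than ``max_dist`` are enumerated; with the
    default greedy rule they are accepted in ascending distance (ties
    broken by previous-spot then current-spot index), each spot used once.
    ``method="optimal"`` instead minimizes the total matched distance with
    the Hungarian algorithm over the same candidate set.

    Returns ``(pairs, unmatched_prev, unmatched_curr)``.
    """
    prev_xy = np.atleast_2d(np.asarray(prev_xy, dtype=float)) if len(prev_xy) else np.empty((0, 2))
    curr_xy = np.atleast_2d(np.asarray(curr_xy, dtype=float)) if len(curr_xy) else np.empty((0, 2))
    n_prev, n_curr = len(prev_xy), len(curr_xy)
    if n_prev == 0 or n_curr == 0:
        return [], list(range(n_prev)), list(range(n_curr))
    dist = np.hypot(prev_xy[:, None, 0] - curr_xy[None, :, 0],
                    prev_xy[:, None, 1] - curr_xy[None, :, 1])
    candidates = [(dist[i, j], i, j) for i in range(n_prev) for j in range(n_curr)
                  if dist[i, j] < max_dist]
    pairs: list[tuple[int, int]] = []
    if method == "greedy":
        used_p: set[int] = set()
        used_c: set[int] = set()
        for _, i, j in sorted(candidates):
            if i not in used_p and j not in used_c:
                pairs.append((i, j))
                used_p.add(i)
                used_c.add(j)
    elif method == "optimal":
        from scipy.optimize import linear_sum_assignment
        big = 1e9
        cost = np.full((n_prev, n_curr), big)
        for d, i, j in candidates:
            cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < big]
    else:
        raise ValueError(f"unknown linking method {method!r}")
    matched_p = {i for i, _ in pairs}
    matched_c = {j for _, j in pairs}
    return (pairs, [i for i in range(n_prev) if i not in matched_p],
            [j for j in range(n_curr) if j not in matched_c])


def link_trajectories(frames_of_spots, max_dist: float = LINK_MAX_DIST,
                      method: str = "greedy", cell_id=None):
    """Chain per-frame spot lists into trajectories (consecutive frames only).

    Unmatched spots in frame t start new trajectories; unmatched spots in
    frame t-1 terminate theirs.  No gap closing.
    """
    open_tracks: dict[int, Trajectory] = {}
    done: list[Trajectory] = []
    prev_spots: list[Spot] = []
    for spots in frames_of_spots:
        if prev_spots:
            pairs, unmatched_prev, unmatched_curr = link_frames(
                [(s.x, s.y) for s in prev_spots], [(s.x, s.y) for s in spots],
                max_dist=max_dist, method=method)
        else:
            pairs, unmatched_prev, unmatched_curr = [], [], list(range(len(spots)))
        new_open: dict[int, Trajectory] = {}
        for i, j in pairs:
            tr = open_tracks[i]
            tr.spots.append(spots[j])
            new_open[j] = tr
        for i in unmatched_prev:
            done.append(open_tracks[i])
        for j in unmatched_curr:
            new_open[j] = Trajectory(spots=[spots[j]], cell_id=cell_id)
        open_tracks = new_open
        prev_spots = spots
    done.extend(open_tracks.values())
    return done


def filter_trajectories(trajectories, cell_mask: np.ndarray | None = None,
                        sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
                        per_spot: bool = False):
    """Remove trajectories outside the cell mask or with bad spot sizes.

    The sigma_A criterion applies to the per-trajectory mean width by
    default (``per_spot=True`` rejects on any single spot instead).
    Returns ``(kept, removal_log)``.
    """
    lo, hi = sigma_bounds
    kept = []
    log = {"outside_mask": 0, "sigma_bounds": 0, "kept": 0}
    for tr in trajectories:
        if cell_mask is not None:
            pos = tr.positions
            cols = np.clip(np.round(pos[:, 0]).astype(int), 0, cell_mask.shape[1] - 1)
            rows = np.clip(np.round(pos[:, 1]).astype(int), 0, cell_mask.shape[0] - 1)
            if not np.all(cell_mask[rows, cols] > 0):
                log["outside_mask"] += 1
                continue
        sig = np.asarray([s.sigma_a for s in tr.spots])
        bad = (np.any((sig < lo) | (sig > hi)) if per_spot
               else not (lo <= float(sig.mean()) <= hi))
        if bad:
            log["sigma_bounds"] += 1
            continue
        kept.append(tr)
    log["kept"] = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# Two-color registration

@dataclass
class ChannelTransform:
    """Similarity transform (translation, rotation, scale) mapping ch2 -> ch1."""

    matrix: np.ndarray        # 3x3 homogeneous
    residual_rms: float

    def apply(self, positions: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        hom = np.column_stack([pos, np.ones(len(pos))])
        out = hom @ self.matrix.T
        return out[:, :2]

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    @property
    def scale(self) -> float:
        return float(np.hypot(self.matrix[0, 0], self.matrix[1, 0]))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2]


def fit_channel_transform(fiducials_ch1: np.ndarray,
                          fiducials_ch2: np.ndarray) -> ChannelTransform:
    """Least-squares similarity transform from paired fiducial positions."""
    from skimage.transform import SimilarityTransform

    dst = np.asarray(fiducials_ch1, dtype=float)
    src = np.asarray(fiducials_ch2, dtype=float)
    if len(src) < 3 or len(dst) != len(src):
        raise ValueError("need >= 3 paired fiducials")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("fiducials are collinear")
    tform = SimilarityTransform()
    if not tform.estimate(src, dst):
        raise ValueError("transform estimation failed")
    resid = tform(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return ChannelTransform(matrix=np.asarray(tform.params), residual_rms=rms)


# ---------------------------------------------------------------------------
# Convenience: full movie -> trajectories

def track_movie(frames: np.ndarray, threshold: float = CORR_THRESHOLD,
                max_dist: float = LINK_MAX_DIST, cell_mask=None,
                sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
                method: str = "greedy"):
    """Detect, fit, link and filter a whole movie.

    Returns ``(trajectories, diagnostics)``.
    """
    per_frame = []
    dropped = 0
    for t, frame in enumerate(np.asarray(frames)):
        spots, d = detect_and_fit(frame, frame=t, threshold=threshold)
        per_frame.append(spots)
        dropped += d
    trajectories = link_trajectories(per_frame, max_dist=max_dist, method=method)
    kept, log = filter_trajectories(trajectories, cell_mask=cell_mask,
                                    sigma_bounds=sigma_bounds)
    log["dropped_fits"] = dropped
    log["n_spots"] = int(sum(len(s) for s in per_frame))
    log["n_trajectories_raw"] = len(trajectories)
    return kept, log


def spots_to_frame(spots) -> pd.DataFrame:
    return pd.DataFrame([{"frame": s.frame, "x": s.x, "y": s.y, "I0": s.i0,
                          "sigmaA": s.sigma_a, "a": s.a, "b": s.b,
                          "Iback": s.i_back} for s in spots])


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    rows = []
    for tid, tr in enumerate(trajectories):
        for s in tr.spots:
            rows.append({"track": tid, "frame": s.frame, "x": s.x, "y": s.y,
                         "intensity": s.i0})
    return pd.DataFrame(rows)
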