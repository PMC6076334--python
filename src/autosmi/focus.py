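"""Two-step autofocus: coarse classifier scan, then sharpness maximization.

The coarse step drives a long Z scan (750 um at 2.5 um steps) and asks a
trained encoder-decoder classifier whether the bright-field iris image
looks in focus; the scan stops at the first position whose evaluation value
(the spatial mean of the output probability map) exceeds 0.5.  Training
labels call an image "in focus" within 4 um of the true focus.

The fine step scans a short range (2200 position units of the objective
feedback system, about 3.5 um, in steps of 20 units, about 32 nm) and at
each position computes the iris-edge sharpness

    E = N(I_max1) * N(I_max2) / N(I_min)^2

from a 512-bin brightness histogram of 21x21 ROIs straddling the iris
edge: the lower-half iris image is binarized by the Otsu method, each ROI
column keeps the first window (scanning top to bottom) whose white
fraction drops to 50% or less, the pooled ROI histogram is bisected at its
Otsu threshold, both sides are smoothed by a 20-bin moving average
(shrinking at the boundaries), and the two peaks and the valley between
them give E.  E > 1 marks a sharp edge.  A Gaussian fit of E versus
position yields the peak position, to which a predetermined hardware
offset (default 0) is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .nn import EncoderDecoderNet, train_adam

__all__ = [
    "SharpnessHistogram", "FocusResult",
    "otsu_threshold", "find_edge_rois", "sharpness_E", "histogram_E",
    "train_focus_classifier", "evaluation_value",
    "coarse_focus", "fine_focus", "two_step_autofocus",
    "UM_PER_PFS", "PFS_RANGE", "PFS_STEP",
]

ROI_SIZE = 21
N_BINS = 512
SMOOTH_BINS = 20
UM_PER_PFS = 3.5 / 2200.0   # objective feedback units to um
PFS_RANGE = 2200.0
PFS_STEP = 20.0


@dataclass
class SharpnessHistogram:
    bin_centers: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    split_bin: int
    imax1: int         # bin index of the left peak
    imax2: int         # bin index of the right peak
    imin: int          # bin index of the valley between the peaks
    e: float


@dataclass
class FocusResult:
    success: bool
    position: float | None = None       # final axis position
    peak: float | None = None           # fitted sharpness peak (before offset)
    profile: list = field(default_factory=list)   # (position, score) pairs
    used_fallback: bool = False
    message: str = ""


def otsu_threshold(image: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold (Otsu), exact.

    The split is searched over every distinct image value (no histogram
    binning), so it is exactly optimal for discrete images; the returned
    threshold lies strictly between the two classes and binarizing with
    ``image >= t`` reproduces the optimal split.
    """
    values, counts = np.unique(np.asarray(image, dtype=np.float64).ravel(),
                               return_counts=True)
    if values.size < 2:
        raise ValueError("constant image has no Otsu threshold")
    w = np.cumsum(counts)                      # class-0 weight per split
    s = np.cumsum(counts * values)             # class-0 value sum per split
    w0, s0 = w[:-1], s[:-1]                    # split after value i
    w1 = w[-1] - w0
    m0 = s0 / w0
    m1 = (s[-1] - s0) / w1
    var = w0 * w1 * (m0 - m1) ** 2
    i = int(np.argmax(var))
    return 0.5 * (values[i] + values[i + 1])


def find_edge_rois(binary: np.ndarray, roi: int = ROI_SIZE,
                   stride: int | None = None, max_white: float = 0.5):
    """Top-left corners of edge ROIs, one per horizontal band.

    For each non-overlapping column band the window slides from the top;
    the first position where the white fraction drops to ``max_white`` or
    below is kept.  Bands with no qualifying window are skipped.
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    stride = stride or roi
    if h < roi or w < roi:
        return []
    csum = np.cumsum(np.cumsum(binary.astype(np.int64), axis=0), axis=1)
    padded = np.zeros((h + 1, w + 1), dtype=np.int64)
    padded[1:, 1:] = csum

    def white_count(r, c):
        return (padded[r + roi, c + roi] - padded[r, c + roi]
                - padded[r + roi, c] + padded[r, c])

    out = []
    limit = max_white * roi * roi
    for c in range(0, w - roi + 1, stride):
        for r in range(0, h - roi + 1):
            if white_count(r, c) <= limit:
                out.append((r, c))
                break
    return out


def _smooth_shrinking(values: np.ndarray, window: int = SMOOTH_BINS) -> np.ndarray:
    """Moving average whose window shrinks at the array boundaries."""
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def histogram_E(counts: np.ndarray, split: int, smooth: int = SMOOTH_BINS,
                centers: np.ndarray | None = None) -> SharpnessHistogram:
    """Peak/valley sharpness score of a bisected brightness histogram.

    Each side of ``split`` is smoothed by a ``smooth``-bin moving average
    (window shrinking at the boundaries); the left and right peaks and the
    valley strictly between them give E = N(Imax1) N(Imax2) / N(Imin)^2.
    E is +inf when the valley count is zero (documented sentinel).
    """
    counts = np.asarray(counts, dtype=np.float64)
    n_bins = len(counts)
    split = min(max(int(split), 1), n_bins - 1)
    if centers is None:
        centers = np.arange(n_bins, dtype=float)
    smoothed = np.empty_like(counts)
    smoothed[:split] = _smooth_shrinking(counts[:split], smooth)
    smoothed[split:] = _smooth_shrinking(counts[split:], smooth)
    imax1 = int(np.argmax(smoothed[:split]))
    imax2 = split + int(np.argmax(smoothed[split:]))
    inner = smoothed[imax1 + 1:imax2]
    imin = imax1 + 1 + int(np.argmin(inner)) if len(inner) else split
    n_min = smoothed[imin]
    e = np.inf if n_min <= 0 else float(smoothed[imax1] * smoothed[imax2] / n_min ** 2)
    return SharpnessHistogram(bin_centers=centers, counts=counts,
                              smoothed=smoothed, split_bin=split,
                              imax1=imax1, imax2=imax2, imin=imin, e=e)


def sharpness_E(image: np.ndarray, roi: int = ROI_SIZE, n_bins: int = N_BINS,
                smooth: int = SMOOTH_BINS):
    """Sharpness score E of a lower-half iris image.

    Returns ``(E, SharpnessHistogram)``.  Raises if no edge ROI is found.
    """
    image = np.asarray(image, dtype=np.float64)
    thr = otsu_threshold(image)
    binary = image >= thr
    rois = find_edge_rois(binary, roi=roi)
    if not rois:
        raise ValueError("no iris-edge ROI found")
    pixels = np.concatenate([image[r:r + roi, c:c + roi].ravel()
                             for r, c in rois])
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise ValueError("edge ROIs are constant")
    counts, edges = np.histogram(pixels, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    split_val = otsu_threshold(pixels)
    split = int(np.searchsorted(centers, split_val))
    hist = histogram_E(counts, split, smooth=smooth, centers=centers)
    return hist.e, hist


# ---------------------------------------------------------------------------
# Coarse step (classifier)

def _normalize(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    return (image - image.mean()) / (image.std() + 1e-9)


def train_focus_classifier(images: np.ndarray, labels: np.ndarray,
                           *, epochs: int = 60, lr: float = 1e-3,
                           seed: int = 0, widths=(8, 16, 32)) -> EncoderDecoderNet:
    """Train the coarse in-focus classifier on labeled iris images.

    ``labels`` are scalars in {0, 1}; each becomes a constant target map.
    """
    images = np.asarray([_normalize(im) for im in images])
    labels = np.asarray(labels, dtype=float)
    targets = np.broadcast_to(labels[:, None, None], images.shape).copy()
    net = EncoderDecoderNet(widths=widths, seed=seed)
    train_adam(net, images, targets, epochs=epochs, lr=lr, seed=seed)
    net.trained = True
    return net


def evaluation_value(classifier: EncoderDecoderNet, image: np.ndarray) -> float:
    """Scalar focus score: spatial mean of the classifier's probability map."""
    return float(np.mean(classifier.forward(_normalize(image))))


def coarse_focus(stage, classifier: EncoderDecoderNet,
                 threshold: float = 0.5) -> FocusResult:
    """Step the axis upward until the evaluation value exceeds the threshold.

    ``stage`` is an iterable of ``(z, image)`` pairs in ascending z (a
    generator works, so images can be produced lazily).  Returns a failure
    status when the range is exhausted.
    """
    profile = []
    for z, image in stage:
        val = evaluation_value(classifier, image)
        profile.append((float(z), val))
        if val > threshold:
            return FocusResult(success=True, position=float(z), profile=profile)
    return FocusResult(success=False, profile=profile,
                       message="scan range exhausted without crossing threshold")


# ---------------------------------------------------------------------------
# Fine step (sharpness peak)

def _gauss(z, amp, z0, width, base):
    return amp * np.exp(-((z - z0) ** 2) / (2.0 * width ** 2)) + base


def fine_focus(stage, offset: float = 0.0) -> FocusResult:
    """Gaussian fit of the sharpness profile E(z); returns peak + offset.

    ``stage`` is an iterable of ``(z, image)`` pairs covering the fine scan
    window.  If the Gaussian fit fails, the argmax position is used and the
    result is flagged (``used_fallback``).
    """
    profile = []
    for z, image in stage:
        try:
            e, _ = sharpness_E(image)
        except ValueError:
            e = 0.0
        profile.append((float(z), e))
    zs = np.asarray([p[0] for p in profile])
    es = np.asarray([p[1] for p in profile])
    finite = np.isfinite(es)  # +inf sentinels excluded from the fit
    if not finite.any():
        return FocusResult(success=False, profile=profile,
                           message="no sharpness score computable")
    zs_f, es_f = zs[finite], es[finite]
    i_max = int(np.argmax(es_f))
    try:
        span = zs_f.max() - zs_f.min()
        p0 = [es_f[i_max] - es_f.min(), zs_f[i_max], 0.15 * span, es_f.min()]
        popt, _ = curve_fit(_gauss, zs_f, es_f, p0=p0, maxfev=5000)
        z0 = float(popt[1])
        if not (zs_f.min() - span <= z0 <= zs_f.max() + span):
            raise RuntimeError("fitted peak far outside the scan window")
        used_fallback = False
    except Exception:
        z0 = float(zs_f[i_max])
        used_fallback = True
    z0 = float(np.clip(z0, zs_f.min(), zs_f.max()))
    return FocusResult(success=True, position=z0 + offset, peak=z0,
                       profile=profile, used_fallback=used_fallback)


def two_step_autofocus(render_coarse, classifier: EncoderDecoderNet,
                       coarse_zs: np.ndarray, render_fine=None,
                       fine_halfrange_um: float = PFS_RANGE / 2 * UM_PER_PFS,
                       fine_step_um: float = PFS_STEP * UM_PER_PFS,
                       offset: float = 0.0,
                       quality_e: float = 100.0) -> FocusResult:
    """Full two-step procedure on a simulated axis.

    ``render_coarse(z)`` returns the full iris image at axis position z (um)
    for the classifier; ``render_fine(z)`` (default: same function) returns
    the lower-half iris image for the sharpness score.  The coarse scan
    walks ``coarse_zs`` ascending with the 0.5 stopping rule; the fine scan
    then covers the feedback-system window centered on the coarse result.
    """
    render_fine = render_fine or render_coarse
    coarse = coarse_focus(((z, render_coarse(z)) for z in coarse_zs), classifier)
    if not coarse.success:
        return coarse
    # The coarse stop can trigger a couple of microns before the slab, so
    # the fine window may miss the sharpness peak entirely.  Two guards,
    # each allowed a few rescans: (a) when the best E in the window sits at
    # the out-of-focus noise floor, shift the window along the E trend;
    # (b) when the fitted peak lands on a window edge, re-center there.
    center = coarse.position
    fine = None
    for _ in range(4):
        fine_zs = np.arange(center - fine_halfrange_um,
                            center + fine_halfrange_um + 1e-9, fine_step_um)
        fine = fine_focus(((z, render_fine(z)) for z in fine_zs), offset=offset)
        if not fine.success:
            break
        zs_p = np.asarray([p[0] for p in fine.profile])
        es_p = np.asarray([p[1] for p in fine.profile])
        finite = np.isfinite(es_p)
        has_infinite_peak = np.any(np.isinf([p[1] for p in fine.profile]))
        if has_infinite_peak or (finite.any() and es_p[finite].max() >= quality_e):
            if fine.peak is None:
                break
            at_edge = (fine.peak <= fine_zs[0] + fine_step_um
                       or fine.peak >= fine_zs[-1] - fine_step_um)
            if not at_edge:
                break
            center = fine.peak
        else:
            # no sharp focus in the window: follow the E trend
            if finite.sum() >= 2:
                slope = np.polyfit(zs_p[finite], es_p[finite], 1)[0]
            else:
                slope = 0.0
            direction = 1.0 if slope >= 0 else -1.0
            center += direction * 2.0 * fine_halfrange_um
    fine.profile = coarse.profile + fine.profile
    return fine
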