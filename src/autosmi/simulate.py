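"""Synthetic microscopy data with exported ground truth.

Everything the rest of the toolkit consumes can be generated here:

* 2-D single-molecule trajectories — free Brownian motion, static mixtures
  of diffusion states, and confined diffusion inside a reflecting square;
* rendered single-molecule movies — Gaussian point-spread functions on a
  planar background with camera noise, n-mer spot intensities drawn from a
  Gaussian with mean ``n*mu`` and variance ``n*sigma**2``;
* bright-field iris focus stacks whose blur grows monotonically with
  defocus, for training and exercising the two-step autofocus;
* SRIC-like cell scenes with pixel-accurate segmentation masks;
* per-cell dose-response tables with log-normal cell-to-cell scatter.

Each generator takes an explicit seed (or rng) and the same seed produces
bit-identical output.  Ground truth (state labels, true positions, true
oligomer sizes, true pharmacological parameters) is returned alongside the
data so recovery tests can compare estimates against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import ImageStack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trajectories",
    "render_movie",
    "render_frame",
    "simulate_spot_field",
    "render_iris",
    "simulate_focus_stack",
    "focus_labels",
    "simulate_sric_scene",
    "simulate_response_tables",
]


@dataclass
class SimulationConfig:
    """Physical and camera parameters shared by the generators.

    The frame interval defaults to 33 ms and the PSF width to 2 pixels.
    The pixel size defaults to 0.1 um/px; every physical quantity is
    computed through it, so other cameras are a one-line change.
    """

    pixel_size: float = 0.1          # um per pixel
    frame_interval: float = 0.033    # s
    field_size: tuple[int, int] = (512, 512)   # (H, W) pixels
    n_frames: int = 30
    psf_sigma: float = 2.0           # pixels
    monomer_mean: float = 1000.0     # a.u., mean single-fluorophore intensity
    monomer_sd: float = 200.0        # a.u.
    background_offset: float = 100.0  # a.u.
    background_slope: tuple[float, float] = (0.0, 0.0)  # a.u./px in (x, y)
    noise_model: str = "poisson-gaussian"   # or "gaussian"
    read_noise_sd: float = 10.0      # a.u., additive Gaussian read noise
    rng_seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.monomer_mean <= 0:
            raise ValueError("monomer_mean must be > 0")
        if self.monomer_sd < 0:
            raise ValueError("monomer_sd must be >= 0")
        if self.noise_model not in ("gaussian", "poisson-gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruth:
    """Simulator-side truth carried alongside every generated dataset."""

    states: list = field(default_factory=list)         # [(D, fraction), ...]
    state_labels: np.ndarray | None = None             # per-track state index
    positions: np.ndarray | None = None                # (n_tracks, T, 2) um
    confinement: float | None = None                   # square side C, um
    oligomer_sizes: np.ndarray | None = None           # per-track n
    spot_intensities: np.ndarray | None = None         # per-track true I0
    params: dict = field(default_factory=dict)         # EC50, h, IC50, mu, ...

    def to_frame(self) -> pd.DataFrame:
        """Per-track table (state label, oligomer size, intensity)."""
        n = len(self.state_labels) if self.state_labels is not None else (
            len(self.oligomer_sizes) if self.oligomer_sizes is not None else 0)
        data = {"track": np.arange(n)}
        if self.state_labels is not None:
            data["state"] = self.state_labels
        if self.oligomer_sizes is not None:
            data["oligomer_size"] = self.oligomer_sizes
        if self.spot_intensities is not None:
            data["intensity"] = self.spot_intensities
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Trajectories

def _reflect(x: np.ndarray, side: float) -> np.ndarray:
    """Fold coordinates into [0, side] with mirror reflection at the walls."""
    period = 2.0 * side
    x = np.mod(x, period)
    return np.where(x > side, period - x, x)


def simulate_trajectories(config: SimulationConfig,
                          states: list[tuple[float, float]],
                          confinement: float | None = None,
                          n_tracks: int = 100,
                          n_frames: int | None = None,
                          switching_rate: float = 0.0,
                          rng: np.random.Generator | None = None):
    """Simulate 2-D random walks drawn from a static mixture of states.

    Parameters
    ----------
    states : list of ``(D, fraction)`` pairs; D in um^2/s; fractions must
        sum to 1 (tolerance 1e-9).
    confinement : side C (um) of a reflecting square, or None for free
        diffusion.
    switching_rate : optional per-frame probability of re-drawing the state
        from the mixture (Markov switching extension; off by default, the
        mixture is static per track).

    Returns ``(positions, truth)`` where positions is (n_tracks, T, 2) in um.
    Each step has per-axis variance ``2*D*dt`` so the mean squared planar
    displacement per step is ``4*D*dt``.
    """
    if rng is None:
        rng = config.rng()
    n_frames = n_frames or config.n_frames
    d_values = np.asarray([s[0] for s in states], dtype=float)
    fractions = np.asarray([s[1] for s in states], dtype=float)
    if np.any(d_values < 0):
        raise ValueError("diffusion coefficients must be >= 0")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"state fractions must sum to 1, got {fractions.sum()!r}")
    if confinement is not None and confinement <= 0:
        raise ValueError("confinement side must be > 0")

    dt = config.frame_interval
    labels = rng.choice(len(states), size=n_tracks, p=fractions)
    if switching_rate > 0:
        lab_t = np.empty((n_tracks, n_frames), dtype=int)
        lab_t[:, 0] = labels
        for t in range(1, n_frames):
            switch = rng.random(n_tracks) < switching_rate
            redraw = rng.choice(len(states), size=n_tracks, p=fractions)
            lab_t[:, t] = np.where(switch, redraw, lab_t[:, t - 1])
    else:
        lab_t = np.repeat(labels[:, None], n_frames, axis=1)

    if confinement is not None:
        box = confinement
        start = rng.uniform(0.0, box, size=(n_tracks, 2))
    else:
        h, w = config.field_size
        start = rng.uniform([0.0, 0.0], [w * config.pixel_size, h * config.pixel_size],
                            size=(n_tracks, 2))

    sigma_step = np.sqrt(2.0 * d_values * dt)        # per-axis step SD
    steps = rng.standard_normal((n_tracks, n_frames - 1, 2))
    steps *= sigma_step[lab_t[:, 1:]][..., None]
    positions = np.empty((n_tracks, n_frames, 2))
    positions[:, 0] = start
    if confinement is not None:
        pos = start.copy()
        for t in range(1, n_frames):
            pos = _reflect(pos + steps[:, t - 1], confinement)
            positions[:, t] = pos
    else:
        positions[:, 1:] = start[:, None, :] + np.cumsum(steps, axis=1)

    truth = GroundTruth(states=list(states), state_labels=labels,
                        positions=positions, confinement=confinement,
                        params={"switching_rate": switching_rate})
    return positions, truth


# ---------------------------------------------------------------------------
# Movie rendering

def _add_gaussian(frame: np.ndarray, x: float, y: float, amp: float,
                  sigma: float) -> bool:
    """Accumulate a symmetric Gaussian; returns False if fully off-field."""
    h, w = frame.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    cx0, cx1 = max(x0, 0), min(x1, w)
    cy0, cy1 = max(y0, 0), min(y1, h)
    if cx0 >= cx1 or cy0 >= cy1:
        return False
    xs = np.arange(cx0, cx1)
    ys = np.arange(cy0, cy1)
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma ** 2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma ** 2))
    frame[cy0:cy1, cx0:cx1] += amp * gy[:, None] * gx[None, :]
    return True


def _background(config: SimulationConfig) -> np.ndarray:
    h, w = config.field_size
    ax, by = config.background_slope
    xs = np.arange(w)[None, :]
    ys = np.arange(h)[:, None]
    return config.background_offset + ax * xs + by * ys


def _apply_noise(frame: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "none":
        return frame
    if config.noise_model == "gaussian":
        return frame + rng.normal(0.0, config.read_noise_sd, frame.shape)
    shot = rng.poisson(np.clip(frame, 0, None)).astype(np.float64)
    return shot + rng.normal(0.0, config.read_noise_sd, frame.shape)


def render_frame(positions_px: np.ndarray, amplitudes: np.ndarray,
                 config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one frame from (x, y) pixel positions and peak amplitudes."""
    if rng is None:
        rng = config.rng()
    frame = _background(config).astype(np.float64)
    for (x, y), amp in zip(np.atleast_2d(positions_px), np.atleast_1d(amplitudes)):
        _add_gaussian(frame, float(x), float(y), float(amp), config.psf_sigma)
    return _apply_noise(frame, config, rng)


def render_movie(positions_um: np.ndarray, oligomer_sizes, config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 ground_truth_csv=None):
    """Render trajectories into a movie.

    positions_um : (n_tracks, T, 2) trajectory positions in um.
    oligomer_sizes : per-track n-mer size (n >= 1); the spot intensity of a
        track is drawn once from Normal(n*mu, n*sigma^2) and clipped at a
        small positive floor.

    Emitters that wander outside the field are clipped from the rendering
    (with a warning counter in the returned truth) but stay in the ground
    truth.  Returns ``(ImageStack, GroundTruth)``.
    """
    import warnings

    if rng is None:
        rng = config.rng()
    positions_um = np.asarray(positions_um, dtype=float)
    n_tracks, n_frames, _ = positions_um.shape
    sizes = np.broadcast_to(np.asarray(oligomer_sizes, dtype=int), (n_tracks,)).copy()
    if np.any(sizes < 1):
        raise ValueError("oligomer sizes must be >= 1")

    amps = rng.normal(sizes * config.monomer_mean,
                      np.sqrt(sizes.astype(float)) * config.monomer_sd)
    amps = np.clip(amps, 1e-6, None)

    h, w = config.field_size
    pos_px = positions_um / config.pixel_size
    frames = np.empty((n_frames, h, w), dtype=np.float64)
    n_clipped = 0
    for t in range(n_frames):
        frame = _background(config).astype(np.float64)
        for i in range(n_tracks):
            x, y = pos_px[i, t]
            if not _add_gaussian(frame, x, y, amps[i], config.psf_sigma):
                n_clipped += 1
        frames[t] = _apply_noise(frame, config, rng)
    if n_clipped:
        warnings.warn(f"{n_clipped} emitter-frames fell outside the field "
                      "and were clipped (kept in ground truth)")

    stack = ImageStack(frames=frames, pixel_size=config.pixel_size,
                       frame_interval=config.frame_interval)
    truth = GroundTruth(positions=positions_um, oligomer_sizes=sizes,
                        spot_intensities=amps,
                        params={"n_clipped": n_clipped,
                                "monomer_mean": config.monomer_mean,
                                "monomer_sd": config.monomer_sd})
    if ground_truth_csv is not None:
        truth.to_frame().to_csv(ground_truth_csv, index=False)
    return stack, truth


def simulate_spot_field(density_per_um2: float, config: SimulationConfig,
                        rng: np.random.Generator | None = None):
    """One snapshot with monomeric spots at a given density (spots/um^2)."""
    if rng is None:
        rng = config.rng()
    h, w = config.field_size
    area = h * w * config.pixel_size ** 2
    n = rng.poisson(density_per_um2 * area)
    pos = rng.uniform([0, 0], [w, h], size=(max(n, 0), 2))
    amps = np.clip(rng.normal(config.monomer_mean, config.monomer_sd, size=n),
                   1e-6, None)
    return render_frame(pos, amps, config, rng=rng), pos


# ---------------------------------------------------------------------------
# Focus stacks (iris images)

def render_iris(size: tuple[int, int] = (256, 256), blur_sigma: float = 0.5,
                noise_sd: float = 2.0, rng: np.random.Generator | None = None,
                lower_half: bool = False, radius_frac: float = 0.42,
                inside: float = 200.0, outside: float = 40.0) -> np.ndarray:
    """A dark/bright circular iris edge, optionally blurred and noisy.

    ``lower_half=True`` renders only the lower half of the iris (the part
    the fine-focus sharpness score inspects), with the circle center on the
    top edge of the image.
    """
    if rng is None:
        rng = np.random.default_rng()
    h, w = size
    ys, xs = np.mgrid[0:h, 0:w]
    if lower_half:
        cy, cx = 0.0, w / 2.0
        radius = radius_frac * min(2 * h, w)
    else:
        cy, cx = h / 2.0, w / 2.0
        radius = radius_frac * min(h, w)
    r = np.hypot(ys - cy, xs - cx)
    img = np.where(r <= radius, inside, outside).astype(np.float64)
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def defocus_blur_sigma(dz_um: float, base: float = 0.6, slope: float = 2.5,
                       cap: float = 25.0) -> float:
    """Blur kernel width (px), monotonically increasing with |defocus|."""
    return min(base + slope * abs(dz_um), cap)


def simulate_focus_stack(z_range: float = 750.0, z_step: float = 2.5,
                         true_focus: float | None = None, noise_sd: float = 2.0,
                         size: tuple[int, int] = (64, 64),
                         rng: np.random.Generator | None = None,
                         lower_half: bool = False):
    """A Z-stack of iris images over ``[0, z_range]`` um at ``z_step`` um.

    The sharpest image sits at ``true_focus`` (drawn uniformly inside the
    central 80% of the range when not given).  Returns
    ``(zs, images, true_focus)``.
    """
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    zs = np.arange(0.0, z_range, z_step)
    if true_focus is None:
        true_focus = float(rng.uniform(0.1 * z_range, 0.9 * z_range))
    images = [render_iris(size=size, blur_sigma=defocus_blur_sigma(z - true_focus),
                          noise_sd=noise_sd, rng=rng, lower_half=lower_half)
              for z in zs]
    return zs, np.asarray(images), true_focus


def focus_labels(zs: np.ndarray, true_focus: float, slab_um: float = 4.0) -> np.ndarray:
    """Training labels: 1 within ``slab_um`` of the in-focus position, else 0."""
    return (np.abs(np.asarray(zs) - true_focus) <= slab_um).astype(float)


def simulate_focus_training_set(true_focus: float = 300.0, z_range: float = 750.0,
                                near_halfrange: float = 20.0, near_step: float = 0.5,
                                far_step: float = 7.5, noise_sd: float = 2.0,
                                size: tuple[int, int] = (32, 32),
                                rng: np.random.Generator | None = None):
    """Labeled iris images for training the coarse in-focus classifier.

    Densely sampled positions around the focus (the in-focus slab and its
    flanks) plus a sparse sweep of the full coarse range, so the classifier
    sees both the 0/1 transition and strongly defocused images.  Returns
    ``(zs, images, labels)`` with labels 1 inside the +/-4 um slab.
    """
    if rng is None:
        rng = np.random.default_rng()
    zs = np.concatenate([
        np.arange(true_focus - near_halfrange, true_focus + near_halfrange, near_step),
        np.arange(0.0, z_range, far_step),
    ])
    images = np.asarray([
        render_iris(size=size, blur_sigma=defocus_blur_sigma(z - true_focus),
                    noise_sd=noise_sd, rng=rng) for z in zs])
    return zs, images, focus_labels(zs, true_focus)


# ---------------------------------------------------------------------------
# SRIC cell scenes

def simulate_sric_scene(n_cells: int, field: tuple[int, int] = (128, 128),
                        rng: np.random.Generator | None = None,
                        blur_sigma: float = 0.0):
    """Textured elliptical "cells" on a structured background.

    Returns ``(image, mask)`` where the binary mask is the exact union of
    the generated ellipses.  ``blur_sigma`` optionally defocuses the image
    (the mask stays sharp), for training nets robust to slight blur.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    h, w = field
    ys, xs = np.mgrid[0:h, 0:w]
    # structured background: smooth illumination gradient plus speckle
    gx, gy = rng.uniform(-0.1, 0.1, 2)
    image = 100.0 + gx * xs + gy * ys + rng.normal(0, 3.0, (h, w))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_cells):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        a = rng.uniform(0.08, 0.18) * min(h, w)
        b = rng.uniform(0.6, 1.0) * a
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xs - cx) * ct + (ys - cy) * st
        v = -(xs - cx) * st + (ys - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        texture = 60.0 + 8.0 * np.sin(0.6 * u + 0.4 * v) + rng.normal(0, 4.0, (h, w))
        image = np.where(inside, 180.0 + texture - 60.0, image)
        mask |= inside
    if blur_sigma > 0:
        image = gaussian_filter(image, blur_sigma)
    return image, mask.astype(float)


# ---------------------------------------------------------------------------
# Dose-response tables

def simulate_response_tables(concentrations, truth: dict, sigma, n_cells: int = 18,
                             inhibitor_concentrations=None,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cell MSD(66 ms) values scattered log-normally around the model.

    ``truth`` holds ``msd_max``, ``msd_min`` (um^2), ``ec50`` (nM) and
    either ``h`` (Hill dose-response) or ``ic50`` (nM; noncompetitive
    inhibition — used when ``inhibitor_concentrations`` is given).
    ``sigma`` is the log-normal scale, scalar or per condition.  Values are
    drawn as ``MSD * exp(sigma*Z - sigma^2/2)`` so the mean of each
    condition equals the model curve; ``sigma=0`` reproduces the curve
    exactly.
    """
    from .stats import hill_msd, inhibition_msd

    if rng is None:
        rng = np.random.default_rng()
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be >= 0")

    rows = []
    if inhibitor_concentrations is None:
        conds = [(l, None) for l in concentrations]
    else:
        conds = [(l, i) for l in concentrations
                 for i in np.asarray(inhibitor_concentrations, dtype=float)]
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (len(conds),))
    if np.any(sig < 0):
        raise ValueError("sigma must be >= 0")
    for (lig, inh), s in zip(conds, sig):
        if inh is None:
            m = hill_msd(lig, truth["msd_max"], truth["msd_min"],
                         truth["ec50"], truth["h"])
        else:
            m = inhibition_msd(lig, inh, truth["msd_max"], truth["msd_min"],
                               truth["ec50"], truth["ic50"])
        if s > 0:
            vals = m * np.exp(s * rng.standard_normal(n_cells) - s ** 2 / 2.0)
        else:
            vals = np.full(n_cells, m)
        for c, v in enumerate(vals):
            row = {"ligand_nM": lig, "cell": c, "msd": float(v)}
            if inh is not None:
                row["inhibitor_nM"] = inh
            rows.append(row)
    return pd.DataFrame(rows)
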