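"""Synthetic single-molecule trajectories, movies and FRAP series.

The generator emulates a stroboscopic HILO acquisition of a two-state
(bound/free) nuclear protein: molecules are assigned a state once, move by
Brownian motion in 3D, are observed with Gaussian localization error while
their axial position stays within the detection slab, and disappear on
photobleaching (geometric lifetime).  Ground truth (state label, true
diffusion coefficient, FRAP kinetics) is carried alongside every dataset
and is never consumed by the inference stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import special

from .config import ImagingConfig
from .frap import FRAPSeries

log = logging.getLogger("chromodyn")

#: diffusion coefficient below which a molecule counts as chromatin-bound
BOUND_THRESHOLD = 0.1  # um^2/s

#: mean photobleaching lifetime in frames (geometric)
DEFAULT_BLEACH_MEAN_FRAMES = 8.0


@dataclasses.dataclass(frozen=True)
class TwoStateParams:
    """Ground-truth kinetic parameters of a two-state mixture.

    ``f_bound`` is the fraction of molecules in the bound state,
    ``d_bound``/``d_free`` their diffusion coefficients in um^2/s.  With
    ``switching`` enabled a molecule flips state between consecutive
    frames with probability ``switch_prob`` (off by default: the grid
    inference assigns one coefficient per trajectory).
    """

    f_bound: float
    d_bound: float = 0.02
    d_free: float = 3.0
    switching: bool = False
    switch_prob: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_bound <= 1.0:
            raise ValueError("f_bound must be in [0, 1]")
        if self.d_bound < 0 or self.d_free < 0:
            raise ValueError("diffusion coefficients must be nonnegative")
        if self.d_bound >= self.d_free and self.d_free > 0:
            raise ValueError("d_bound must be below d_free")


@dataclasses.dataclass(frozen=True)
class FRAPKinetics:
    """Ground-truth single-exponential FRAP recovery parameters.

    The post-bleach chromocenter signal is
    ``I(t) = plateau - (plateau - depth) * exp(-t / tau)`` with t = 0 at
    the first post-bleach frame.  ``acq_bleach_rate`` is the per-second
    decay of the whole-nucleus signal from acquisition photobleaching;
    ``noise_cv`` the coefficient of variation of the multiplicative
    measurement noise; ``background_level`` an additive intensity offset.
    """

    plateau: float
    depth: float
    tau: float
    acq_bleach_rate: float = -math.log(0.8) / 600.0  # 20% loss over 10 min
    noise_cv: float = 0.03
    background_level: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth < self.plateau <= 1.0:
            raise ValueError("need 0 <= depth < plateau <= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclasses.dataclass(frozen=True)
class Preset:
    """A named experimental condition with SMT and (optionally) FRAP truth."""

    name: str
    two_state: TwoStateParams
    frap: FRAPKinetics | None = None


_LN2 = math.log(2.0)

#: study conditions: bound fractions and free-state coefficients per condition,
#: FRAP half-times converted to exponential time constants via t_half = tau*ln2
PRESETS: dict[str, Preset] = {
    "WT": Preset("WT", TwoStateParams(f_bound=0.64, d_free=3.0),
                 FRAPKinetics(plateau=0.92, depth=0.45, tau=26.0 / _LN2)),
    "G118E": Preset("G118E", TwoStateParams(f_bound=0.39, d_free=2.5),
                    FRAPKinetics(plateau=0.97, depth=0.55, tau=13.0 / _LN2)),
    "H2B": Preset("H2B", TwoStateParams(f_bound=0.79, d_free=2.0)),
    "NLS": Preset("NLS", TwoStateParams(f_bound=0.11, d_free=12.0)),
}


@dataclasses.dataclass
class GroundTruth:
    """Per-trajectory truth carried alongside a simulated dataset."""

    params: object
    per_trajectory: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {"params": dataclasses.asdict(self.params)}
        if self.per_trajectory is not None:
            payload["per_trajectory"] = self.per_trajectory.to_dict("list")
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# trajectories


def simulate_trajectories(params: TwoStateParams, cfg: ImagingConfig,
                          n_cells: int, traj_per_cell: int, seed: int, *,
                          bleach_mean_frames: float = DEFAULT_BLEACH_MEAN_FRAMES,
                          density_per_frame: float = 1.0,
                          margin_um: float = 2.0,
                          max_frames_per_molecule: int = 400):
    """Simulate two-state Brownian trajectories observed through a slab.

    Each molecule draws its state from Bernoulli(f_bound) and performs 3D
    Brownian motion; observed x/y positions carry i.i.d. Gaussian error of
    ``cfg.loc_error`` per axis.  A molecule is observed from activation
    until it bleaches (geometric lifetime, mean ``bleach_mean_frames``) or
    its axial position leaves +/- focal_depth/2; molecules observed for
    fewer than 2 localizations are discarded from the trajectory table but
    retained in the ground truth with ``observed = False``.  Activation
    times are staggered so the mean density is ``density_per_frame``
    localizations per frame.

    Returns ``(trajectories, truth)``: a DataFrame with columns
    cell_id, trajectory, frame, x_um, y_um, x_true_um, y_true_um,
    intensity, and a :class:`GroundTruth` whose ``per_trajectory`` table
    has one row per simulated molecule (observed or not).
    """
    if n_cells < 1 or traj_per_cell < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    dt, dz, sigma = cfg.frame_interval, cfg.focal_depth, cfg.loc_error
    half = dz / 2.0
    roi = cfg.roi_um
    margin = min(margin_um, roi / 4.0)

    rows, truth_rows = [], []
    for c in range(n_cells):
        cell_id = f"cell{c:03d}"
        n = traj_per_cell
        bound = rng.random(n) < params.f_bound
        d0 = np.where(bound, params.d_bound, params.d_free)
        life = rng.geometric(1.0 / bleach_mean_frames, n)
        life = np.minimum(life, max_frames_per_molecule)
        m = int(life.max())  # frames per molecule, padded

        if params.switching and params.switch_prob > 0:
            flips = rng.random((n, m - 1)) < params.switch_prob
            parity = np.cumsum(flips, axis=1) % 2 == 1
            state = np.repeat(bound[:, None], m - 1, axis=1) ^ parity
            d_step = np.where(state, params.d_bound, params.d_free)
        else:
            d_step = np.repeat(d0[:, None], m - 1, axis=1)
        step_sd = np.sqrt(2.0 * d_step * dt)

        z0 = rng.uniform(-half, half, n)
        z = z0[:, None] + np.cumsum(rng.standard_normal((n, m - 1)) * step_sd,
                                    axis=1)
        out = np.abs(z) > half
        exited = out.any(axis=1)
        # number of localizations before slab exit (frame 0 is inside)
        slab_locs = np.where(exited, out.argmax(axis=1) + 1, m)
        n_locs = np.minimum(life, slab_locs)

        x0 = rng.uniform(margin, roi - margin, n)
        y0 = rng.uniform(margin, roi - margin, n)
        x = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(
            rng.standard_normal((n, m - 1)) * step_sd, axis=1)], axis=1)
        y = np.concatenate([y0[:, None], y0[:, None] + np.cumsum(
            rng.standard_normal((n, m - 1)) * step_sd, axis=1)], axis=1)
        x_obs = x + rng.normal(0.0, sigma, x.shape)
        y_obs = y + rng.normal(0.0, sigma, y.shape)

        total_locs = int(n_locs.sum())
        n_frames = max(1, int(np.ceil(total_locs / density_per_frame)))
        start = rng.integers(0, n_frames, n)

        keep = n_locs >= 2
        for i in np.flatnonzero(keep):
            k = int(n_locs[i])
            rows.append(pd.DataFrame({
                "cell_id": cell_id,
                "trajectory": i,
                "frame": start[i] + np.arange(k),
                "x_um": x_obs[i, :k],
                "y_um": y_obs[i, :k],
                "x_true_um": x[i, :k],
                "y_true_um": y[i, :k],
                "intensity": 300.0,
            }))
        truth_rows.append(pd.DataFrame({
            "cell_id": cell_id,
            "trajectory": np.arange(n),
            "bound": bound,
            "d_true": d0,
            "n_locs": n_locs,
            "observed": keep,
        }))

    cols = ["cell_id", "trajectory", "frame", "x_um", "y_um",
            "x_true_um", "y_true_um", "intensity"]
    traj = (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=cols))
    truth = GroundTruth(params=params,
                        per_trajectory=pd.concat(truth_rows,
                                                 ignore_index=True))
    return traj, truth


def write_trajectories_csv(traj: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory table (trajectory, frame, x_um, y_um, intensity,
    cell_id) to CSV."""
    cols = ["trajectory", "frame", "x_um", "y_um", "intensity", "cell_id"]
    traj[cols].to_csv(path, index=False)


def read_trajectories_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# movie rendering


def _integrated_gaussian_profile(edges: np.ndarray, center: float,
                                 sigma: float) -> np.ndarray:
    """Integral of a unit Gaussian over unit pixels given their edges."""
    z = (edges - center) / (math.sqrt(2.0) * sigma)
    cdf = 0.5 * (1.0 + special.erf(z))
    return np.diff(cdf)


def render_movie(traj: pd.DataFrame, cfg: ImagingConfig,
                 photons_per_spot: float, bg_photons: float, seed: int, *,
                 noise: bool = True, n_frames: int | None = None,
                 pos_cols: tuple[str, str] = ("x_true_um", "y_true_um")
                 ) -> np.ndarray:
    """Render localizations as pixel-integrated Gaussian spots.

    Each localization contributes a 2D Gaussian of standard deviation
    ``cfg.psf_sigma`` pixels integrated over pixels, with expected total
    photon count ``photons_per_spot``, on a uniform background of
    ``bg_photons`` per pixel.  Per-pixel Poisson noise is applied unless
    ``noise=False``.  Returns an unsigned 16-bit (frames, N, N) stack.
    """
    npx = cfg.roi_pixels
    if pos_cols[0] not in traj.columns:
        pos_cols = ("x_um", "y_um")
    xs = traj[pos_cols[0]].to_numpy() / cfg.pixel_size
    ys = traj[pos_cols[1]].to_numpy() / cfg.pixel_size
    if len(xs) and (xs.min() < 0 or ys.min() < 0
                    or xs.max() > npx or ys.max() > npx):
        raise ValueError("trajectory coordinates outside the ROI")
    frames = traj["frame"].to_numpy(int) if len(traj) else np.array([], int)
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 1
    movie = np.full((n_frames, npx, npx), float(bg_photons))
    edges = np.arange(npx + 1, dtype=float)
    for f, xc, yc in zip(frames, xs, ys):
        if f >= n_frames:
            continue
        px = _integrated_gaussian_profile(edges, xc, cfg.psf_sigma)
        py = _integrated_gaussian_profile(edges, yc, cfg.psf_sigma)
        movie[f] += photons_per_spot * np.outer(py, px)
    if noise:
        movie = np.random.default_rng(seed).poisson(movie).astype(float)
    return np.clip(np.round(movie), 0, 65535).astype(np.uint16)


def write_movie_tiff(movie: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), movie, photometric="minisblack")


# ---------------------------------------------------------------------------
# FRAP


def frap_true_curve(kin: FRAPKinetics, t_post: np.ndarray) -> np.ndarray:
    """Noise-free post-bleach recovery I(t), t = 0 at first post-bleach frame."""
    t = np.asarray(t_post, float)
    return kin.plateau - (kin.plateau - kin.depth) * np.exp(-t / kin.tau)


def simulate_frap(kin: FRAPKinetics, n_cells: int, seed: int, *,
                  n_pre: int = 5, n_frames: int = 100,
                  frame_interval: float = 6.15, scale: float = 1000.0,
                  expr_cv: float = 0.4, nucleus_ratio: float = 0.5):
    """Simulate FRAP intensity series for ``n_cells`` cells.

    The ground-truth chromocenter signal is 1 for the ``n_pre`` pre-bleach
    frames and follows the single-exponential recovery afterwards; the
    whole-nucleus signal decays as ``exp(-acq_bleach_rate * t)`` from the
    first frame.  Per-cell absolute brightness varies lognormally
    (``expr_cv``), providing the expression proxy used for high/low
    stratification.  Multiplicative Gaussian measurement noise of
    coefficient of variation ``noise_cv`` is applied to every series.

    Returns ``(cells, truth)`` with ``cells`` a list of
    :class:`~chromodyn.frap.FRAPSeries`.
    """
    if n_pre < 1 or n_frames <= n_pre:
        raise ValueError("need n_pre >= 1 and n_frames > n_pre")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * frame_interval
    t_post = np.arange(n_frames - n_pre) * frame_interval
    signal = np.ones(n_frames)
    signal[n_pre:] = frap_true_curve(kin, t_post)
    decay = np.exp(-kin.acq_bleach_rate * times)

    cells, scales = [], []
    for c in range(n_cells):
        s = scale * rng.lognormal(0.0, expr_cv)
        scales.append(s)
        chromo = signal * decay * s + kin.background_level
        nucleus = decay * s * nucleus_ratio + kin.background_level
        background = np.full(n_frames, kin.background_level)
        if kin.noise_cv > 0:
            chromo = chromo * (1 + rng.normal(0, kin.noise_cv, n_frames))
            nucleus = nucleus * (1 + rng.normal(0, kin.noise_cv, n_frames))
            background = background * (1 + rng.normal(0, kin.noise_cv,
                                                      n_frames))
        cells.append(FRAPSeries(times=times, chromo_raw=chromo,
                                nucleus_raw=nucleus,
                                background_raw=background, n_pre=n_pre,
                                cell_id=f"cell{c:03d}"))
    truth = GroundTruth(params=kin,
                        per_trajectory=pd.DataFrame({
                            "cell_id": [s.cell_id for s in cells],
                            "scale": scales}))
    return cells, truth


def frap_toy_movie(kin: FRAPKinetics, seed: int, *, n_pre: int = 5,
                   n_frames: int = 40, frame_interval: float = 6.15,
                   size: int = 48, n_z: int = 3, scale: float = 200.0,
                   drift_px: float = 0.15):
    """Render a small (T, Z, Y, X) movie of a drifting chromocenter.

    Intended only to exercise :func:`~chromodyn.frap.project_and_measure`;
    no attempt is made at realistic chromocenter morphology.  Returns
    ``(stack, chromo_mask, nucleus_mask, background_mask, times)`` where
    the chromocenter mask is the union of the disk over its whole track.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * frame_interval
    t_post = np.arange(n_frames - n_pre) * frame_interval
    signal = np.ones(n_frames)
    signal[n_pre:] = frap_true_curve(kin, t_post)
    decay = np.exp(-kin.acq_bleach_rate * times)

    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = size / 2.0
    nucleus_r, chromo_r = size * 0.42, size * 0.08
    nucleus = (xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_r ** 2
    centers = np.cumsum(rng.normal(0, drift_px, (n_frames, 2)), axis=0)
    centers += np.array([cx - size * 0.15, cy])
    stack = np.empty((n_frames, n_z, size, size))
    union = np.zeros((size, size), bool)
    for f in range(n_frames):
        dist = np.hypot(xx - centers[f, 0], yy - centers[f, 1])
        # anti-aliased disk: soft one-pixel edge keeps the integrated
        # area smooth as the center drifts between pixels
        disk = np.clip(chromo_r + 0.5 - dist, 0.0, 1.0)
        union |= disk > 0
        frame = np.full((size, size), kin.background_level / n_z)
        frame[nucleus] += scale * decay[f] * 0.3 / n_z
        frame += disk * (scale * decay[f] * signal[f] / n_z)
        for z in range(n_z):
            stack[f, z] = frame
    if kin.noise_cv > 0:
        stack *= 1 + rng.normal(0, kin.noise_cv, stack.shape)
    background_mask = np.zeros((size, size), bool)
    background_mask[1:4, 1:4] = True
    return stack, union, nucleus, background_mask, times
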