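"""State-array inference of the diffusion-coefficient spectrum.

Each trajectory's jump sequence is scored against a fixed log-spaced grid
of diffusion coefficients under the likelihood of regular Brownian motion
with localization error (RBME): per axis, the jumps are zero-mean
multivariate normal with tridiagonal covariance

    C_ii     = 2 D dt + 2 sigma^2
    C_i,i+-1 = -sigma^2

(the off-diagonal term arises because consecutive jumps share one noisy
localization).  An expectation-maximization fixed point then estimates
the occupation of each grid point.  Because slow molecules stay in the
detection slab longer than fast ones, raw occupations are biased toward
slow states when counted per jump; they are converted to per-molecule
occupations by dividing by the expected number of observed jumps per
activated molecule at each grid coefficient.  The chromatin-bound
fraction is the total occupation strictly below 0.1 um^2/s.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve_banded, cholesky_banded

from .config import ImagingConfig
from .simulate import BOUND_THRESHOLD, DEFAULT_BLEACH_MEAN_FRAMES

log = logging.getLogger("chromodyn")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclasses.dataclass(frozen=True)
class DiffusionGrid:
    """Log-spaced diffusion-coefficient grid sharing sigma with the imaging
    configuration.  The default 100 points from 1e-2 to 1e2 um^2/s never
    include 0.1 exactly, so bound-fraction thresholding is unambiguous."""

    coefficients: np.ndarray = dataclasses.field(
        default_factory=lambda: np.logspace(-2, 2, 100))
    loc_error: float = 0.035

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, float)
        object.__setattr__(self, "coefficients", c)
        if c.ndim != 1 or len(c) < 2 or np.any(np.diff(c) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.isclose(c, BOUND_THRESHOLD, rtol=1e-12, atol=0)):
            raise ValueError("grid must not contain the bound threshold")


@dataclasses.dataclass
class DiffusionSpectrum:
    """Per-cell and aggregate posterior occupations over a diffusion grid."""

    grid: np.ndarray
    cell_ids: list
    occupations: np.ndarray      # (n_cells, K), rows sum to 1
    n_jumps: np.ndarray          # (n_cells,)
    n_trajectories: np.ndarray   # (n_cells,)
    aggregate: np.ndarray        # (K,), jump-count-weighted mean over cells

    def bound_fractions(self, threshold: float = BOUND_THRESHOLD) -> np.ndarray:
        mask = self.grid < threshold
        return self.occupations[:, mask].sum(axis=1)

    def aggregate_bound_fraction(self, threshold: float = BOUND_THRESHOLD
                                 ) -> float:
        return float(self.aggregate[self.grid < threshold].sum())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "n_trajectories": self.n_trajectories,
            "n_jumps": self.n_jumps,
            "bound_fraction": self.bound_fractions(),
        })


def bound_fraction(occupations: np.ndarray, grid: np.ndarray,
                   threshold: float = BOUND_THRESHOLD) -> float:
    """Total occupation at grid coefficients strictly below ``threshold``."""
    occupations = np.asarray(occupations, float)
    if abs(occupations.sum() - 1.0) > 1e-6:
        raise ValueError("occupations must be normalized")
    return float(occupations[np.asarray(grid) < threshold].sum())


# ---------------------------------------------------------------------------
# RBME likelihood


def _banded_cholesky(n: int, D: float, sigma: float, dt: float):
    ab = np.zeros((2, n))
    ab[0, 1:] = -sigma ** 2
    ab[1, :] = 2.0 * D * dt + 2.0 * sigma ** 2
    c = cholesky_banded(ab, lower=False)
    logdet = 2.0 * float(np.log(c[1]).sum())
    return c, logdet


def rbme_loglik(jumps: np.ndarray, D: float, sigma: float, dt: float) -> float:
    """Exact RBME log-likelihood of a jump sequence, O(n) via the
    tridiagonal covariance.

    ``jumps`` is an (n, 2) array of consecutive-frame displacements in um
    (a 1D array is treated as a single axis).
    """
    if D < 0 or sigma < 0:
        raise ValueError("D and sigma must be nonnegative")
    jumps = np.asarray(jumps, float)
    if jumps.ndim == 1:
        jumps = jumps[:, None]
    n, n_axes = jumps.shape
    if n < 1:
        raise ValueError("need at least one jump")
    c, logdet = _banded_cholesky(n, D, sigma, dt)
    sol = cho_solve_banded((c, False), jumps)
    quad = float((sol * jumps).sum())
    return -0.5 * (n_axes * n * _LOG_2PI + n_axes * logdet + quad)


def _loglik_matrix(jump_arrays: list, grid: np.ndarray, sigma: float,
                   dt: float) -> np.ndarray:
    """(n_traj, K) RBME log-likelihoods, trajectories grouped by length."""
    K = len(grid)
    L = np.empty((len(jump_arrays), K))
    by_len = defaultdict(list)
    for idx, j in enumerate(jump_arrays):
        by_len[len(j)].append(idx)
    for n, idxs in by_len.items():
        X = np.stack([jump_arrays[i] for i in idxs])       # (m, n, 2)
        m = len(idxs)
        R = X.transpose(1, 0, 2).reshape(n, 2 * m)
        for k, D in enumerate(grid):
            c, logdet = _banded_cholesky(n, float(D), sigma, dt)
            sol = cho_solve_banded((c, False), R)
            quad = (sol * R).sum(axis=0).reshape(m, 2).sum(axis=1)
            L[idxs, k] = -0.5 * (2 * n * _LOG_2PI + 2 * logdet + quad)
    return L


# ---------------------------------------------------------------------------
# observed-jump weights (defocalization, optionally with photobleaching)

_weight_cache: dict = {}


def defocalization_weight(D: float, dt: float, dz: float,
                          max_jumps: int = 100, *,
                          bleach_mean_frames: float | None = None,
                          n_molecules: int = 100_000,
                          mc_seed: int = 13) -> float:
    """Expected number of observed jumps per activated molecule.

    Monte-Carlo estimate (fixed internal seed) of the mean number of
    consecutive-frame jumps recorded before a Brownian molecule with
    coefficient ``D``, started uniformly inside the slab +/- dz/2, exits
    the slab, capped at ``max_jumps``.  With ``bleach_mean_frames`` set,
    observation is additionally truncated by a geometric photobleaching
    lifetime of that mean, which is how the inference uses it: the
    expected jump count then correctly weights slow states whose slab
    residence far exceeds the fluorophore lifetime.
    """
    return float(defocalization_weights(
        np.array([D]), dt, dz, max_jumps,
        bleach_mean_frames=bleach_mean_frames, n_molecules=n_molecules,
        mc_seed=mc_seed)[0])


def defocalization_weights(grid: np.ndarray, dt: float, dz: float,
                           max_jumps: int = 100, *,
                           bleach_mean_frames: float | None = None,
                           n_molecules: int = 100_000,
                           mc_seed: int = 13) -> np.ndarray:
    """Vectorized :func:`defocalization_weight` over a coefficient grid.

    A single set of standard-normal paths is shared across grid points
    (scaled by sqrt(2 D dt)), and results are cached per parameter set.
    """
    grid = np.asarray(grid, float)
    key = (tuple(np.round(grid, 12)), round(dt, 12), round(dz, 12),
           max_jumps, bleach_mean_frames, n_molecules, mc_seed)
    if key in _weight_cache:
        return _weight_cache[key]
    rng = np.random.default_rng(mc_seed)
    half = dz / 2.0
    z0 = rng.uniform(-half, half, n_molecules)
    paths = np.cumsum(rng.standard_normal((n_molecules, max_jumps)), axis=1)
    if bleach_mean_frames is not None:
        life = rng.geometric(1.0 / bleach_mean_frames, n_molecules)
    else:
        life = np.full(n_molecules, max_jumps + 1)
    weights = np.empty(len(grid))
    for k, D in enumerate(grid):
        z = z0[:, None] + np.sqrt(2.0 * D * dt) * paths
        out = np.abs(z) > half
        exited = out.any(axis=1)
        slab_locs = np.where(exited, out.argmax(axis=1) + 1, max_jumps + 1)
        n_locs = np.minimum(slab_locs, life)
        jumps = np.clip(n_locs - 1, 0, max_jumps)
        weights[k] = jumps.mean()
    _weight_cache[key] = weights
    return weights


# ---------------------------------------------------------------------------
# state-array inference


def _split_jumps(jumps: np.ndarray, cap: int) -> list:
    return [jumps[i: i + cap] for i in range(0, len(jumps), cap)]


def _extract_jump_arrays(traj: pd.DataFrame, cap: int) -> list:
    """Per-trajectory (n, 2) jump arrays, long trajectories split at cap."""
    arrays = []
    df = traj.sort_values(["trajectory", "frame"], kind="stable")
    for _, sub in df.groupby("trajectory", sort=False):
        pos = sub[["x_um", "y_um"]].to_numpy()
        frames = sub["frame"].to_numpy()
        jumps = np.diff(pos, axis=0)
        jumps = jumps[np.diff(frames) == 1]
        if len(jumps) >= 1:
            arrays.extend(_split_jumps(jumps, cap))
    return arrays


def _em_occupations(L: np.ndarray, w: np.ndarray, state_weights: np.ndarray,
                    max_iter: int, tol: float) -> np.ndarray:
    """Maximum-likelihood EM over trajectories, reported per molecule.

    The EM fixed point maximizes the proper mixture likelihood in which
    each trajectory is one observation (its log-likelihood already
    carries all of its jumps; weighting the E-step by jump count would
    double-count that information and over-sharpen long trajectories).
    At convergence the responsibilities are aggregated with jump-count
    weights w_t to give the occupation of observed jumps, which is then
    divided by the expected observed jumps per molecule at each grid
    coefficient to give the per-molecule occupation.  With max_iter = 0
    the uniform initialization is returned unchanged.
    """
    K = L.shape[1]
    rho = np.full(K, 1.0 / K)
    expL = np.exp(L - L.max(axis=1, keepdims=True))
    if max_iter == 0:
        return rho
    for _ in range(max_iter):
        r = expL * rho
        r /= r.sum(axis=1, keepdims=True)
        new = r.mean(axis=0)
        done = np.abs(new - rho).max() < tol
        rho = new
        if done:
            break
    r = expL * rho
    r /= r.sum(axis=1, keepdims=True)
    counts = w @ r
    pi = counts / state_weights
    return pi / pi.sum()


def state_array_infer(traj: pd.DataFrame,
                      grid: DiffusionGrid | None = None,
                      cfg: ImagingConfig = ImagingConfig(), *,
                      max_iter: int = 1000, tol: float = 1e-6,
                      defocalization: bool = True,
                      bleach_mean_frames: float | None = DEFAULT_BLEACH_MEAN_FRAMES,
                      max_jumps_per_traj: int = 100,
                      sample_size: int = 1_000_000,
                      subsample_seed: int = 0) -> DiffusionSpectrum:
    """Infer per-cell diffusion spectra and bound fractions.

    For each cell, trajectory jump sequences are scored on the grid with
    the RBME likelihood and occupations are estimated by iterating

        r_tk ∝ pi_k exp(L_tk),   pi_k ∝ (sum_t w_t r_tk) / weight_k

    from a uniform prior, where w_t is the jump count of trajectory t and
    weight_k the expected observed jumps per molecule at D_k (slab exit
    plus photobleaching truncation).  Cells are aggregated by a
    jump-count-weighted mean of their occupation vectors.  Total jumps
    per call are capped at ``sample_size`` by seeded uniform subsampling
    of trajectories.
    """
    if grid is None:
        grid = DiffusionGrid(loc_error=cfg.loc_error)
    coeffs = grid.coefficients
    sigma = grid.loc_error
    dt = cfg.frame_interval

    if "cell_id" not in traj.columns:
        traj = traj.assign(cell_id="cell000")

    if defocalization:
        state_w = defocalization_weights(
            coeffs, dt, cfg.focal_depth, max_jumps_per_traj,
            bleach_mean_frames=bleach_mean_frames)
        state_w = np.maximum(state_w, 1e-9)
    else:
        state_w = np.ones(len(coeffs))

    cell_ids, occs, n_jumps_list, n_traj_list = [], [], [], []
    for cell_id, sub in traj.groupby("cell_id", sort=True):
        arrays = _extract_jump_arrays(sub, max_jumps_per_traj)
        if not arrays:
            log.warning("cell %s: no trajectory with >= 1 jump; skipped",
                        cell_id)
            continue
        total = sum(len(a) for a in arrays)
        if total > sample_size:
            rng = np.random.default_rng(subsample_seed)
            order = rng.permutation(len(arrays))
            picked, running = [], 0
            for i in order:
                picked.append(i)
                running += len(arrays[i])
                if running >= sample_size:
                    break
            arrays = [arrays[i] for i in sorted(picked)]
        L = _loglik_matrix(arrays, coeffs, sigma, dt)
        w = np.array([len(a) for a in arrays], float)
        pi = _em_occupations(L, w, state_w, max_iter, tol)
        pi = pi / pi.sum()
        cell_ids.append(cell_id)
        occs.append(pi)
        n_jumps_list.append(w.sum())
        n_traj_list.append(len(arrays))
    if not cell_ids:
        raise ValueError("no cell with a usable trajectory")
    occupations = np.asarray(occs)
    n_jumps = np.asarray(n_jumps_list)
    aggregate = (occupations * n_jumps[:, None]).sum(axis=0) / n_jumps.sum()
    aggregate /= aggregate.sum()
    return DiffusionSpectrum(grid=coeffs, cell_ids=cell_ids,
                             occupations=occupations, n_jumps=n_jumps,
                             n_trajectories=np.asarray(n_traj_list),
                             aggregate=aggregate)


def per_trajectory_mle(traj: pd.DataFrame,
                       cfg: ImagingConfig = ImagingConfig()) -> pd.DataFrame:
    """Model-free per-trajectory diffusion estimate.

    D_hat = max(0, <squared 2D jump> / (4 dt) - sigma^2 / dt); the
    histogram of D_hat across trajectories is a sanity check on the
    spectrum's modes, not an input to it.
    """
    dt, sigma = cfg.frame_interval, cfg.loc_error
    group_cols = ["cell_id", "trajectory"] if "cell_id" in traj.columns \
        else ["trajectory"]
    df = traj.sort_values(group_cols + ["frame"], kind="stable")
    rows = []
    for key, sub in df.groupby(group_cols, sort=False):
        pos = sub[["x_um", "y_um"]].to_numpy()
        jumps = np.diff(pos, axis=0)[np.diff(sub["frame"].to_numpy()) == 1]
        if len(jumps) < 1:
            continue
        msd = float((jumps ** 2).sum(axis=1).mean())
        d_hat = max(0.0, msd / (4.0 * dt) - sigma ** 2 / dt)
        rows.append((*np.atleast_1d(key), len(jumps), d_hat))
    return pd.DataFrame(rows, columns=group_cols + ["n_jumps", "d_mle"])
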