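"""Frame-to-frame trajectory linking and jump-length statistics.

Localizations in consecutive frames are connected by minimum-total-
distance bipartite matching within a search radius, with no gap closing:
a trajectory that finds no match terminates, and a molecule reappearing
later starts a new trajectory.  Singleton localizations are retained
(they count toward per-cell detection totals) but are excluded from
kinetic analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import ImagingConfig

log = logging.getLogger("chromodyn")

_INFEASIBLE = 1e9


@dataclasses.dataclass(frozen=True)
class LinkSettings:
    """Euclidean linker settings; max_blinks is fixed at 0 (no gap closing)."""

    search_radius: float = 1.0  # um
    max_blinks: int = 0

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if self.max_blinks != 0:
            raise ValueError("only max_blinks = 0 (no gap closing) is supported")


def link(locs: pd.DataFrame, settings: LinkSettings = LinkSettings()
         ) -> pd.DataFrame:
    """Assign a ``trajectory`` id to every localization.

    ``locs`` must carry columns frame, x_um, y_um (already in um).  For
    each consecutive frame pair, candidate pairs within the search radius
    are matched by minimizing the total distance over a maximum-cardinality
    bipartite matching; unmatched localizations start new trajectories.
    Every input localization belongs to exactly one trajectory.
    """
    if "cell_id" in locs.columns and locs["cell_id"].nunique() > 1:
        parts, offset = [], 0
        for _, sub in locs.groupby("cell_id", sort=True):
            linked = link(sub.drop(columns="cell_id"), settings)
            linked["cell_id"] = sub["cell_id"].iloc[0]
            linked["trajectory"] += offset
            offset = linked["trajectory"].max() + 1
            parts.append(linked)
        return pd.concat(parts, ignore_index=True)
    locs = locs.sort_values(["frame"], kind="stable").reset_index(drop=True)
    n = len(locs)
    traj_id = np.full(n, -1, dtype=int)
    if n == 0:
        out = locs.copy()
        out["trajectory"] = traj_id
        return out
    frames = locs["frame"].to_numpy()
    xy = locs[["x_um", "y_um"]].to_numpy()

    next_id = 0
    # active trajectories: list of (row index of last localization, traj id)
    active_rows: np.ndarray = np.array([], dtype=int)
    active_frame = None
    for f in np.unique(frames):
        rows = np.flatnonzero(frames == f)
        if active_frame is not None and f == active_frame + 1 and len(active_rows):
            d = cdist(xy[active_rows], xy[rows])
            cost = np.where(d <= settings.search_radius, d, _INFEASIBLE)
            ri, ci = linear_sum_assignment(cost)
            matched_cols = set()
            for i, j in zip(ri, ci):
                if d[i, j] <= settings.search_radius:
                    traj_id[rows[j]] = traj_id[active_rows[i]]
                    matched_cols.add(j)
            new_active = [rows[j] for j in range(len(rows))]
            for j in range(len(rows)):
                if j not in matched_cols:
                    traj_id[rows[j]] = next_id
                    next_id += 1
            active_rows = np.asarray(new_active, dtype=int)
        else:
            for r in rows:
                traj_id[r] = next_id
                next_id += 1
            active_rows = rows
        active_frame = f
    out = locs.copy()
    out["trajectory"] = traj_id
    return out


def trajectory_lengths(traj: pd.DataFrame) -> pd.Series:
    return traj.groupby("trajectory")["frame"].size()


def jump_lengths(traj: pd.DataFrame, cfg: ImagingConfig = ImagingConfig(), *,
                 bin_width: float = 0.02, r_max: float = 1.0):
    """Euclidean displacements between consecutive frames, in um.

    Returns ``(jumps, bin_edges, hist)`` where ``hist`` is the density-
    normalized histogram of jump lengths on ``bin_width`` bins up to
    ``r_max``.  Raises if no trajectory has >= 2 localizations.
    """
    group_cols = ["cell_id", "trajectory"] if "cell_id" in traj.columns \
        else ["trajectory"]
    df = traj.sort_values(group_cols + ["frame"], kind="stable")
    dx = df.groupby(group_cols)["x_um"].diff()
    dy = df.groupby(group_cols)["y_um"].diff()
    dframe = df.groupby(group_cols)["frame"].diff()
    ok = dframe == 1
    jumps = np.hypot(dx[ok].to_numpy(), dy[ok].to_numpy())
    if jumps.size == 0:
        raise ValueError("no trajectory with >= 2 localizations")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist, _ = np.histogram(jumps, bins=edges, density=True)
    return jumps, edges, hist


def jump_length_cdf(r, fractions, diffusivities,
                    cfg: ImagingConfig = ImagingConfig()) -> np.ndarray:
    """Closed-form jump-length CDF of a Brownian mixture with localization
    error: P(jump <= R) = sum_i f_i (1 - exp(-R^2 / (4 D_i dt + 4 sigma^2)))."""
    r = np.asarray(r, float)
    fractions = np.asarray(fractions, float)
    diffusivities = np.asarray(diffusivities, float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    scale2 = 4.0 * diffusivities * cfg.frame_interval + 4.0 * cfg.loc_error ** 2
    return np.sum(fractions[:, None]
                  * (1.0 - np.exp(-r[None, :] ** 2 / scale2[:, None])),
                  axis=0)
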