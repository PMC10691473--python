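"""Expression-level coupling statistics.

The number of single-molecule detections per cell is proportional to the
number of labeled protein copies and serves as a per-cell expression
proxy.  These routines quantify how strongly chromatin binding depends on
expression: Pearson correlation between detections and bound fraction, a
seeded random-pairing null for that correlation, high/low-expression
stratification of FRAP curves, and per-animal bound-fraction summaries
with rank-sum group comparisons.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .frap import FRAPSeries, average_and_summarize

log = logging.getLogger("chromodyn")


@dataclasses.dataclass(frozen=True)
class CellRecord:
    """Per-cell pairing of expression proxy and inferred bound fraction."""

    cell_id: str
    n_detections: int
    bound_fraction: float
    condition: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.n_detections < 0:
            raise ValueError("n_detections must be nonnegative")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must be in [0, 1]")


def records_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def _validate_xy(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a sample")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _validate_xy(x, y)
    return float(stats.pearsonr(x, y).statistic)


@dataclasses.dataclass(frozen=True)
class PairingNull:
    observed: float
    null: np.ndarray
    null_mean: float
    p_two_sided: float


def random_pairing_null(x, y, n_shuffles: int = 10_000,
                        seed: int = 0) -> PairingNull:
    """Null distribution of the correlation under random re-pairing.

    Shuffles the pairing of y against x (uniform permutations, seeded)
    and recomputes the correlation for each replicate.  The empirical
    two-sided p-value uses the add-one rule.
    """
    x, y = _validate_xy(x, y)
    if n_shuffles < 100:
        raise ValueError("need n_shuffles >= 100")
    obs = pearson(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    perms = rng.random((n_shuffles, n)).argsort(axis=1)
    null = (yz[perms] @ xz) / n
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_shuffles + 1.0)
    return PairingNull(observed=obs, null=null,
                       null_mean=float(null.mean()), p_two_sided=float(p))


def stratify_expression(cells: Sequence[FRAPSeries],
                        corrected: np.ndarray, k: int = 10):
    """Split FRAP cells into top-k and bottom-k expressers.

    Cells are ranked by absolute pre-bleach chromocenter intensity; ties
    break by position in the input sequence.  Returns a dict with, for
    each of "high" and "low": member indices, mean curve, SD and a
    recovery summary.
    """
    corrected = np.atleast_2d(np.asarray(corrected, float))
    if len(cells) != corrected.shape[0]:
        raise ValueError("one corrected curve per cell required")
    if len(cells) < 2 * k:
        raise ValueError(f"need at least {2 * k} cells")
    intens = np.array([c.initial_chromo_intensity for c in cells])
    order = np.argsort(-intens, kind="stable")
    groups = {"high": order[:k], "low": order[-k:][::-1]}
    out = {}
    times = cells[0].times
    n_pre = cells[0].n_pre
    for name, idx in groups.items():
        mean, sd, summ = average_and_summarize(corrected[idx], times, n_pre)
        out[name] = {"indices": idx, "mean_curve": mean, "sd_curve": sd,
                     "summary": summ}
    return out


def per_animal_summary(records: pd.DataFrame, group_col: str = "condition",
                       groups: tuple[str, str] | None = None,
                       alternative: str = "greater"):
    """Per-animal mean bound fractions plus a per-cell rank-sum test.

    ``records`` needs columns animal_id, bound_fraction and ``group_col``.
    The Mann-Whitney U test compares per-cell bound fractions between the
    two conditions (default alternative "greater": first group larger).
    Returns ``(per_animal, U, p)``.
    """
    if records.empty:
        raise ValueError("empty records")
    per_animal = (records.groupby([group_col, "animal_id"])["bound_fraction"]
                  .mean().reset_index())
    if groups is None:
        labels = list(dict.fromkeys(records[group_col]))
        if len(labels) != 2:
            raise ValueError("specify the two groups to compare")
        groups = (labels[0], labels[1])
    a = records.loc[records[group_col] == groups[0], "bound_fraction"]
    b = records.loc[records[group_col] == groups[1], "bound_fraction"]
    if a.empty or b.empty:
        raise ValueError("both groups must be nonempty")
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return per_animal, float(res.statistic), float(res.pvalue)
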