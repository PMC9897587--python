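"""Descriptive circular statistics, variable transforms and group contrasts.

Group-level inference uses seeded label-permutation tests on one aggregated
value per participant x condition (mean difference, or circular-mean
difference for phase angles), rather than mixed-effects model fitting.
Variables bounded at zero (reaction time, coefficient of variation) are
compared on the log scale; the phase-locking value, bounded in (0, 1), on
the logit scale — matching the conventional transforms for these
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import (
    InvalidArgumentError,
    UndefinedDirectionError,
    UndefinedStatisticError,
)

__all__ = [
    "GroupContrast",
    "circular_mean",
    "transform",
    "inverse_transform",
    "permutation_test",
    "correlate",
]

LOGIT_EPS = 1e-6


def circular_mean(angles_deg: np.ndarray | list[float]) -> float:
    """Direction of the resultant vector of the angles, in [-180, 180).

    Raises UndefinedDirectionError when the angles balance exactly (zero
    resultant), in which case no mean direction exists.
    """
    ang = np.asarray(angles_deg, dtype=float)
    if ang.size == 0:
        raise UndefinedStatisticError("circular mean of an empty set")
    z = np.mean(np.exp(1j * np.deg2rad(ang)))
    if np.abs(z) < 1e-12:
        raise UndefinedDirectionError(
            "angles are perfectly balanced; mean direction undefined"
        )
    mean = float(np.rad2deg(np.angle(z)))
    return mean if mean < 180.0 else -180.0


def transform(values: np.ndarray | list[float], kind: str) -> tuple[np.ndarray, int]:
    """Elementwise log or logit transform.

    logit inputs are clipped into [eps, 1-eps] (eps = 1e-6) before the
    transform; the number of clipped values is returned alongside.  log
    of a non-positive value is an error (no silent clipping on that scale).
    """
    x = np.asarray(values, dtype=float)
    if kind == "log":
        if np.any(x <= 0):
            raise InvalidArgumentError("log transform requires positive values")
        return np.log(x), 0
    if kind == "logit":
        if np.any((x < 0) | (x > 1)):
            raise InvalidArgumentError("logit transform requires values in [0, 1]")
        clipped = np.clip(x, LOGIT_EPS, 1 - LOGIT_EPS)
        n_clipped = int(np.sum(clipped != x))
        return np.log(clipped / (1 - clipped)), n_clipped
    raise InvalidArgumentError(f"unknown transform {kind!r}")


def inverse_transform(values: np.ndarray | list[float], kind: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if kind == "log":
        return np.exp(x)
    if kind == "logit":
        return 1.0 / (1.0 + np.exp(-x))
    raise InvalidArgumentError(f"unknown transform {kind!r}")


@dataclass(frozen=True)
class GroupContrast:
    """Result of a two-group permutation contrast."""

    statistic_name: str
    observed_difference: float
    n_permutations: int
    p_value: float
    transform_applied: str = "none"
    n_clipped: int = 0
    seed: int | None = None


def _circ_mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    d = circular_mean(a) - circular_mean(b)
    return float((d + 180.0) % 360.0 - 180.0)


def permutation_test(
    group_a: np.ndarray | list[float],
    group_b: np.ndarray | list[float],
    statistic: str = "mean_diff",
    n_perm: int = 9999,
    seed: int = 0,
    transform_kind: str = "none",
) -> GroupContrast:
    """Two-sided label-permutation test of a two-group difference.

    statistic: "mean_diff" (difference of arithmetic means, optionally on a
    log/logit scale via transform_kind) or "circular_mean_diff" (difference
    of circular means of angle data in degrees, wrapped to [-180, 180)).
    p = (1 + #{|T*| >= |T|}) / (1 + n_perm), never exactly zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    if n_perm < 999:
        raise InvalidArgumentError("use at least 999 permutations")

    n_clipped = 0
    if transform_kind != "none":
        if statistic == "circular_mean_diff":
            raise InvalidArgumentError("transforms do not apply to angle data")
        a, ca = transform(a, transform_kind)
        b, cb = transform(b, transform_kind)
        n_clipped = ca + cb

    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)

    if statistic == "mean_diff":
        observed = float(a.mean() - b.mean())
        if np.ptp(pooled) == 0:  # degenerate: all values identical
            return GroupContrast(statistic, observed, n_perm, 1.0,
                                 transform_kind, n_clipped, seed)
        # vectorized label shuffles
        perms = np.empty(n_perm)
        idx = np.arange(pooled.size)
        for i in range(n_perm):
            rng.shuffle(idx)
            pa = pooled[idx[:n_a]]
            perms[i] = pa.mean() - (pooled.sum() - pa.sum()) / (pooled.size - n_a)
    elif statistic == "circular_mean_diff":
        observed = _circ_mean_diff(a, b)
        perms = np.empty(n_perm)
        idx = np.arange(pooled.size)
        for i in range(n_perm):
            rng.shuffle(idx)
            perms[i] = _circ_mean_diff(pooled[idx[:n_a]], pooled[idx[n_a:]])
    else:
        raise InvalidArgumentError(f"unknown statistic {statistic!r}")

    p = float((1 + np.sum(np.abs(perms) >= abs(observed))) / (1 + n_perm))
    return GroupContrast(statistic, observed, n_perm, p, transform_kind,
                         n_clipped, seed)


def correlate(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise InvalidArgumentError("x and y must have equal length")
    if xa.size < 3:
        raise UndefinedStatisticError("correlation needs at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    if method == "pearson":
        res = sstats.pearsonr(xa, ya)
    elif method == "spearman":
        res = sstats.spearmanr(xa, ya)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
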