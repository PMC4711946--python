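"""Permutation tests for comparing normalized component areas between groups.

Sample sizes in vessel-wall studies are small, so classical parametric
assumptions (normality, equal variances) cannot be verified.  The tests
here build the null distribution of a statistic by resampling group labels
without replacement.  With m Monte-Carlo resamples and b of them at least
as extreme as the observed statistic, the p-value estimate is

    p = (b + 1) / (m + 1)

which can never be exactly zero.  A binomial confidence interval quantifies
the Monte-Carlo uncertainty of the estimate.  The resampling is split into
fixed-size chunks, each driven by an RNG substream derived from
(seed, chunk index), so results are a pure function of the inputs and the
seed — independent of how many workers execute the chunks.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats as sps

from .config import PermutationConfig

logger = logging.getLogger(__name__)

EXHAUSTIVE_CAP = 1_000_000

STATISTICS = ("mean_difference", "median_difference", "F")


def n_combinations(n_1: int, n_2: int) -> int:
    """Number of distinct group-membership assignments for two groups.

    Exact integer value of (n_1+n_2)! / (n_1!·n_2!).
    """
    if n_1 < 0 or n_2 < 0:
        raise ValueError("group sizes must be non-negative")
    return math.comb(n_1 + n_2, n_1)


def eq7_pvalue(b: int, m: int) -> float:
    """Monte-Carlo permutation p-value (b+1)/(m+1); strictly positive."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= b <= m:
        raise ValueError(f"b must lie in [0, m]; got b={b}, m={m}")
    return (b + 1) / (m + 1)


def _observed(x1: np.ndarray, x2: np.ndarray, statistic: str) -> float:
    if statistic == "mean_difference":
        return float(x1.mean() - x2.mean())
    if statistic == "median_difference":
        return float(np.median(x1) - np.median(x2))
    if statistic == "F":
        return _f_stat(x1, x2)
    raise ValueError(f"unknown statistic: {statistic!r}")


def _f_stat(x1: np.ndarray, x2: np.ndarray) -> float:
    """One-way ANOVA F for two groups: between- over within-group variance."""
    n1, n2 = len(x1), len(x2)
    gm = (x1.sum() + x2.sum()) / (n1 + n2)
    ss_between = n1 * (x1.mean() - gm) ** 2 + n2 * (x2.mean() - gm) ** 2
    ss_within = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    df_b, df_w = 1, n1 + n2 - 2
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return float((ss_between / df_b) / (ss_within / df_w))


def _perm_stats(perm: np.ndarray, n1: int, statistic: str) -> np.ndarray:
    """Vectorized statistic over rows of permuted pooled data."""
    g1, g2 = perm[:, :n1], perm[:, n1:]
    if statistic == "mean_difference":
        return g1.mean(axis=1) - g2.mean(axis=1)
    if statistic == "median_difference":
        return np.median(g1, axis=1) - np.median(g2, axis=1)
    if statistic == "F":
        n2 = perm.shape[1] - n1
        gm = perm.mean(axis=1)
        m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
        ss_b = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
        ss_w = ((g1 - m1[:, None]) ** 2).sum(axis=1) + (
            (g2 - m2[:, None]) ** 2
        ).sum(axis=1)
        df_w = n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ss_w == 0, np.where(ss_b > 0, np.inf, 0.0), ss_b / (ss_w / df_w))
        return f
    raise ValueError(f"unknown statistic: {statistic!r}")


def _is_extreme(t_perm: np.ndarray, t_obs: float, tail: str) -> np.ndarray:
    # ties count as "at least as extreme"; the tiny relative slack keeps a
    # genuine tie from being dropped when the permuted statistic is summed
    # in a different floating-point order than the observed one
    tol = 1e-12 * max(1.0, abs(t_obs))
    if tail == "two_tailed":
        return np.abs(t_perm) >= abs(t_obs) - tol
    return t_perm >= t_obs - tol


def _chunk_exceedances(
    pool: np.ndarray, n1: int, orient: float, t_obs: float, statistic: str,
    tail: str, seed: int, chunk_idx: int, chunk_m: int,
) -> int:
    """Exceedance count of one resampling chunk; deterministic substream.

    ``pool`` is in canonical order and ``orient`` flips sign-bearing
    statistics back to the caller's group orientation.
    """
    rng = np.random.default_rng([seed, chunk_idx])
    perm = rng.permuted(np.tile(pool, (chunk_m, 1)), axis=1)
    t = _perm_stats(perm, n1, statistic)
    if statistic != "F":
        t = orient * t
    return int(_is_extreme(t, t_obs, tail).sum())


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a (Monte-Carlo) permutation test."""

    observed: float
    b: int
    m: int
    p_value: float
    ci: tuple[float, float]
    statistic: str
    tail: str
    seed: int
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.p_value != (self.b + 1) / (self.m + 1):
            raise ValueError("p_value must equal (b+1)/(m+1)")


def permutation_test(
    values_1, values_2, cfg: PermutationConfig | None = None
) -> PermutationResult:
    """Monte-Carlo permutation test comparing two groups.

    The two groups are pooled; each of the m resamples draws n_1 values
    without replacement for pseudo-group 1 (the rest form pseudo-group 2)
    and recomputes the statistic.  b counts resamples at least as extreme
    as observed (|T_perm| ≥ |T_obs| two-tailed, T_perm ≥ T_obs one-tailed);
    the p-value is (b+1)/(m+1).
    """
    cfg = cfg or PermutationConfig()
    x1 = np.asarray(values_1, dtype=float).ravel()
    x2 = np.asarray(values_2, dtype=float).ravel()
    if x1.size < 1 or x2.size < 1:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("group values must be finite")
    t_obs = _observed(x1, x2, cfg.statistic)

    # canonical internal group order: the resampled pool (and hence b for a
    # two-tailed test) is then bit-identical under swapping the group labels
    if (x2.size, tuple(x2)) < (x1.size, tuple(x1)):
        ga, gb, orient = x2, x1, -1.0
    else:
        ga, gb, orient = x1, x2, 1.0
    pool = np.concatenate([ga, gb])

    if np.all(pool == pool[0]):
        warnings.warn("degenerate data: all pooled values identical; p = 1")
        b = cfg.m
    else:
        n_chunks = (cfg.m + cfg.chunk_size - 1) // cfg.chunk_size
        sizes = [
            min(cfg.chunk_size, cfg.m - i * cfg.chunk_size) for i in range(n_chunks)
        ]
        args = [
            (pool, ga.size, orient, t_obs, cfg.statistic, cfg.tail, cfg.seed, i, s)
            for i, s in enumerate(sizes)
        ]
        if cfg.n_workers == 1 or n_chunks == 1:
            parts = [_chunk_exceedances(*a) for a in args]
        else:
            parts = Parallel(n_jobs=cfg.n_workers, prefer="threads")(
                delayed(_chunk_exceedances)(*a) for a in args
            )
        b = int(sum(parts))

    p = eq7_pvalue(b, cfg.m)
    ci = pvalue_ci(p, cfg.m, cfg.ci_level)
    return PermutationResult(
        observed=t_obs, b=b, m=cfg.m, p_value=p, ci=ci,
        statistic=cfg.statistic, tail=cfg.tail, seed=cfg.seed,
        n_workers=cfg.n_workers,
    )


def exhaustive_permutation_test(
    values_1, values_2, statistic: str = "mean_difference", tail: str = "two_tailed"
) -> float:
    """Exact permutation p-value by enumerating every group assignment.

    Feasible for modest sample sizes; raises when the combination count
    exceeds one million (use the Monte-Carlo test instead).
    """
    x1 = np.asarray(values_1, dtype=float).ravel()
    x2 = np.asarray(values_2, dtype=float).ravel()
    total = n_combinations(x1.size, x2.size)
    if total > EXHAUSTIVE_CAP:
        raise ValueError(
            f"{total} assignments exceed the exhaustive cap of {EXHAUSTIVE_CAP}; "
            "use the Monte-Carlo permutation_test"
        )
    pool = np.concatenate([x1, x2])
    n = pool.size
    t_obs = _observed(x1, x2, statistic)
    count = 0
    idx_all = frozenset(range(n))
    for comb in itertools.combinations(range(n), x1.size):
        g1 = pool[list(comb)]
        g2 = pool[list(idx_all.difference(comb))]
        t = _observed(g1, g2, statistic)
        if _is_extreme(np.array([t]), t_obs, tail)[0]:
            count += 1
    return count / total


def pvalue_ci(
    p_hat: float, m: int, level: float = 0.95, method: str = "normal"
) -> tuple[float, float]:
    """Confidence interval for a Monte-Carlo p-value estimate.

    Treats the exceedance count as binomial.  The default is the normal
    approximation p̂ ± z·sqrt(p̂(1−p̂)/m) clipped to [0,1]; ``method="exact"``
    gives the Clopper–Pearson interval instead.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if method == "normal":
        z = sps.norm.ppf((1 + level) / 2)
        half = z * math.sqrt(p_hat * (1 - p_hat) / m)
        return (max(0.0, p_hat - half), min(1.0, p_hat + half))
    if method == "exact":
        k = round(p_hat * m)
        ci = sps.binomtest(k, m).proportion_ci(confidence_level=level, method="exact")
        return (float(ci.low), float(ci.high))
    raise ValueError(f"unknown CI method: {method!r}")


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed from a master seed and arbitrary string tokens."""
    h = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return (seed * 1_000_003 + h) % 2**31


def compare_groups(
    table: pd.DataFrame,
    cfg: PermutationConfig | None = None,
    components: tuple[str, ...] = ("ratio_SMF", "ratio_ECM"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Pairwise permutation tests between all groups, per component.

    ``table`` holds one row per sample with a group label and the
    normalized component ratios.  Returns one row per (component,
    unordered group pair) with the observed statistic, b, m, p-value and
    CI.  No multiple-testing correction is applied across the matrix.
    """
    cfg = cfg or PermutationConfig()
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    for c in components:
        if c not in table.columns:
            raise ValueError(f"missing component column {c!r}")
    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g in groups:
        if (table[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    rows = []
    for comp in components:
        for g1, g2 in itertools.combinations(groups, 2):
            v1 = table.loc[table[group_col] == g1, comp].to_numpy()
            v2 = table.loc[table[group_col] == g2, comp].to_numpy()
            cell_cfg = PermutationConfig(
                m=cfg.m, statistic=cfg.statistic, tail=cfg.tail,
                seed=derive_seed(cfg.seed, comp, g1, g2),
                n_workers=cfg.n_workers, chunk_size=cfg.chunk_size,
                ci_level=cfg.ci_level,
            )
            res = permutation_test(v1, v2, cell_cfg)
            rows.append(
                {
                    "component": comp, "group_1": g1, "group_2": g2,
                    "observed": res.observed, "b": res.b, "m": res.m,
                    "p_value": res.p_value, "ci_low": res.ci[0],
                    "ci_high": res.ci[1], "statistic": res.statistic,
                    "tail": res.tail, "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)
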