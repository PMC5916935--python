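"""Permutation Welch testing and permutation FDR for group comparisons.

For every (gene, level) quantified in at least three samples of each
group, the PCa and BPH normalized log2 H/L values are compared with a
two-sample Welch (unequal-variance) t statistic whose null distribution
is obtained by relabeling samples. When the number of distinct
relabelings C(n, n_x) is small enough the enumeration is exhaustive and
the p-value is exact; otherwise a seeded Monte Carlo sample of
relabelings is used with the standard +1/+1 correction. The false
discovery rate is the permutation plug-in estimate: the expected number
of null p-values at or below each observed p, over the number of
observed p-values at or below it, clipped to [0, 1] and monotonized.
"""

from __future__ import annotations

import itertools
import math
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

DEFAULT_N_PERM = 10_000
#: Exhaustive enumeration is used whenever C(n, nx) does not exceed this.
#: C(17, 7) = 19,448, so the full study design is enumerated exactly.
DEFAULT_PERM_CAP = 100_000
DEFAULT_N_PERM_FDR = 200
DEFAULT_ALPHA = 0.05
DEFAULT_FDR_BOUND = 0.01
#: Fold-change inclusion gate: |mean log2 H/L| >= log2(1.5).
DEFAULT_FC_LOG2 = 0.585
MIN_N_PER_GROUP = 3

#: Relative tolerance for counting |t_perm| >= |t_obs| ties, so that
#: splits that are floating-point re-orderings of the observed one count
#: as ties rather than falling just below the threshold.
_TIE_RTOL = 1e-12

LEVELS = ("UNB", "AAL", "PHA", "GLOBAL")


def welch_t(x, y) -> float:
    """Welch's unequal-variance t statistic, mean(x) − mean(y) direction.

    Degenerate inputs: if both sample variances are zero the statistic is
    0 for equal means and ±inf for unequal means (the permutation layer
    handles the infinite sentinel through ordinary comparisons).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("welch_t requires at least two values per group")
    num = x.mean() - y.mean()
    denom = math.sqrt(x.var(ddof=1) / nx + y.var(ddof=1) / ny)
    if denom == 0.0:
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    return float(num / denom)


@lru_cache(maxsize=64)
def _comb_matrix(n: int, k: int) -> np.ndarray:
    """All C(n, k) index combinations as an (C, k) int array (cached)."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _split_t(values: np.ndarray, x_idx: np.ndarray, nx: int) -> np.ndarray:
    """Welch t for many splits at once.

    ``x_idx`` is an (m, nx) matrix of x-group index sets into ``values``;
    the y group is the complement. Vectorized via group sums/sums of
    squares; tiny negative variances from cancellation are clipped to 0.
    """
    v = values
    n = v.size
    ny = n - nx
    total_s = v.sum()
    total_q = (v * v).sum()
    sx = v[x_idx].sum(axis=1)
    qx = (v * v)[x_idx].sum(axis=1)
    sy = total_s - sx
    qy = total_q - qx
    mx = sx / nx
    my = sy / ny
    vx = np.clip((qx - sx * mx) / (nx - 1), 0.0, None)
    vy = np.clip((qy - sy * my) / (ny - 1), 0.0, None)
    num = mx - my
    denom = np.sqrt(vx / nx + vy / ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    zero = denom == 0.0
    if zero.any():
        t[zero] = np.where(num[zero] == 0.0, 0.0, np.copysign(np.inf, num[zero]))
    return t


def permutation_null(
    x,
    y,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    cap: int = DEFAULT_PERM_CAP,
) -> tuple[np.ndarray, bool]:
    """Null distribution of |t| under group-label relabeling.

    Returns ``(abs_t, exhaustive)``. When C(nx+ny, nx) <= ``cap`` every
    relabeling is enumerated (the observed labeling included); otherwise
    ``n_perm`` seeded random relabelings are drawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.size
    pooled = np.concatenate([x, y])
    n = pooled.size
    n_comb = math.comb(n, nx)
    if n_comb <= cap:
        t = _split_t(pooled, _comb_matrix(n, nx), nx)
        return np.abs(t), True
    rng = np.random.default_rng(seed)
    # n_perm random relabelings: argsort of uniform noise is a uniform permutation
    perms = np.argsort(rng.random((n_perm, n)), axis=1)[:, :nx]
    t = _split_t(pooled, perms, nx)
    return np.abs(t), False


def _tie_threshold(abs_t_obs: float) -> float:
    if not math.isfinite(abs_t_obs):
        return abs_t_obs
    return abs_t_obs - _TIE_RTOL * max(1.0, abs_t_obs)


def permutation_pvalue(
    x,
    y,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    cap: int = DEFAULT_PERM_CAP,
) -> float:
    """Two-sided permutation p-value for the Welch statistic.

    Exhaustive enumeration gives the exact p = #{|t_perm| >= |t_obs|} /
    C(n, nx); the Monte Carlo estimate is (#{|t_perm| >= |t_obs|} + 1) /
    (n_perm + 1), which never returns zero.
    """
    abs_obs = abs(welch_t(x, y))
    null, exhaustive = permutation_null(x, y, n_perm=n_perm, seed=seed, cap=cap)
    count = int(np.count_nonzero(null >= _tie_threshold(abs_obs)))
    if exhaustive:
        return count / null.size
    return (count + 1) / (null.size + 1)


def eligibility_filter(matrix, min_n: int = MIN_N_PER_GROUP) -> pd.DataFrame:
    """Per-(gene, level) group sample counts and the n >= 3 eligibility flag.

    ``matrix`` is a :class:`~glycodiff.rollup.QuantMatrix` (or its long
    DataFrame). A feature is eligible for permutation testing when it was
    quantified in at least ``min_n`` samples in both groups.
    """
    df = getattr(matrix, "data", matrix)
    counts = (
        df.groupby(["gene", "level", "group"])["sample_id"]
        .nunique()
        .unstack("group")
        .fillna(0)
        .astype(int)
    )
    for g in ("BPH", "PCa"):
        if g not in counts.columns:
            counts[g] = 0
    out = counts.rename(columns={"BPH": "n_bph", "PCa": "n_pca"}).reset_index()
    out["eligible"] = (out["n_bph"] >= min_n) & (out["n_pca"] >= min_n)
    return out[["gene", "level", "n_bph", "n_pca", "eligible"]]


def permutation_fdr(
    observed_p, permuted_p, monotone: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation plug-in FDR for each observed p-value.

    For each threshold t equal to an observed p-value:
    ``FDR(t) = mean_b #{permuted_p[b, :] <= t} / max(1, #{observed_p <= t})``,
    clipped to [0, 1]. The first return is the monotonized estimate
    (nondecreasing in t, enforced by a running minimum from the largest
    threshold down); the second is the raw unmonotonized value.

    ``permuted_p`` has shape (B, m): B permutation rounds of the same m
    features, generated under the same relabeling scheme as the tests.
    """
    obs = np.asarray(observed_p, dtype=float)
    if obs.size == 0:
        return np.array([]), np.array([])
    perm = np.asarray(permuted_p, dtype=float)
    if perm.ndim != 2:
        raise ValueError("permuted_p must be a (B, m) matrix")
    n_rounds = perm.shape[0]
    flat = np.sort(perm.ravel())
    obs_sorted = np.sort(obs)
    order = np.argsort(obs, kind="stable")
    p_sorted = obs[order]
    n_rejected = np.searchsorted(obs_sorted, p_sorted, side="right")
    expected_false = np.searchsorted(flat, p_sorted, side="right") / n_rounds
    raw_sorted = np.clip(expected_false / np.maximum(1, n_rejected), 0.0, 1.0)
    mono_sorted = np.minimum.accumulate(raw_sorted[::-1])[::-1]
    fdr = np.empty_like(obs)
    raw = np.empty_like(obs)
    fdr[order] = mono_sorted if monotone else raw_sorted
    raw[order] = raw_sorted
    return fdr, raw


def _null_pvalues(sorted_null: np.ndarray, stats: np.ndarray, exhaustive: bool,
                  ) -> np.ndarray:
    """p-values of statistics evaluated against a feature's own null."""
    m = sorted_null.size
    with np.errstate(invalid="ignore"):
        thresh = stats - _TIE_RTOL * np.maximum(1.0, np.abs(stats))
    thresh[~np.isfinite(stats)] = stats[~np.isfinite(stats)]
    count = m - np.searchsorted(sorted_null, thresh, side="left")
    if exhaustive:
        return count / m
    return (count + 1) / (m + 1)


def compare_groups(
    matrix,
    seed: int,
    n_perm: int = DEFAULT_N_PERM,
    cap: int = DEFAULT_PERM_CAP,
    n_perm_fdr: int = DEFAULT_N_PERM_FDR,
    alpha: float = DEFAULT_ALPHA,
    fdr_bound: float = DEFAULT_FDR_BOUND,
    fc_log2: float = DEFAULT_FC_LOG2,
    fdr_scope: str = "per_level",
    min_n: int = MIN_N_PER_GROUP,
) -> pd.DataFrame:
    """Full group comparison over a normalized quantitation matrix.

    One row per (gene, level) with group means and sample counts, the
    difference of means delta = mean_pca − mean_bph, the permutation
    Welch p-value, the permutation FDR (per level by default, pooled
    across levels with ``fdr_scope="pooled"``), the fold-change inclusion
    flag (|PCa group mean log2 H/L| >= ``fc_log2``), and the p <= alpha
    significance marker. Ineligible features (n < 3 in either group)
    carry means when computable but no p-value or FDR.

    Permutations relabel only the samples observed for each feature, so
    per-feature missingness is respected.
    """
    if fdr_scope not in ("per_level", "pooled"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    df = getattr(matrix, "data", matrix)
    rng = np.random.default_rng(seed)

    records = []
    null_draws: dict[int, np.ndarray] = {}  # row index -> n_perm_fdr null p's
    grouped = df.groupby(["gene", "level"], sort=True)
    for (gene, level), sub in grouped:
        bph = sub.loc[sub["group"] == "BPH", "log2_hl"].to_numpy()
        pca = sub.loc[sub["group"] == "PCa", "log2_hl"].to_numpy()
        n_bph, n_pca = bph.size, pca.size
        mean_bph = float(bph.mean()) if n_bph else np.nan
        mean_pca = float(pca.mean()) if n_pca else np.nan
        delta = mean_pca - mean_bph if n_bph and n_pca else np.nan
        eligible = n_bph >= min_n and n_pca >= min_n
        rec = {
            "gene": gene,
            "level": level,
            "n_bph": n_bph,
            "n_pca": n_pca,
            "mean_bph": mean_bph,
            "mean_pca": mean_pca,
            "delta": delta,
            "t_stat": np.nan,
            "p_value": np.nan,
            "p_welch": np.nan,
            "eligible": eligible,
            "fc_flag": bool(abs(mean_pca) >= fc_log2) if n_pca else False,
        }
        if eligible:
            t_obs = welch_t(pca, bph)
            null, exhaustive = permutation_null(
                pca, bph, n_perm=n_perm, seed=int(rng.integers(2**31)), cap=cap
            )
            count = int(np.count_nonzero(null >= _tie_threshold(abs(t_obs))))
            p = count / null.size if exhaustive else (count + 1) / (null.size + 1)
            rec["t_stat"] = t_obs
            rec["p_value"] = p
            with warnings.catch_warnings():
                # degenerate near-constant features trip scipy's precision
                # warning; the permutation p is the primary output anyway
                warnings.simplefilter("ignore", RuntimeWarning)
                rec["p_welch"] = float(
                    _scipy_stats.ttest_ind(pca, bph, equal_var=False).pvalue
                )
            # draw one null statistic per FDR round from this feature's
            # own relabeling distribution, converted to a p-value
            sorted_null = np.sort(null)
            draws = sorted_null[rng.integers(0, null.size, n_perm_fdr)]
            null_draws[len(records)] = _null_pvalues(sorted_null, draws, exhaustive)
        records.append(rec)

    out = pd.DataFrame.from_records(records)
    if out.empty:
        out = pd.DataFrame(
            columns=["gene", "level", "n_bph", "n_pca", "mean_bph", "mean_pca",
                     "delta", "t_stat", "p_value", "p_welch", "fdr", "fdr_raw",
                     "fdr_pass", "eligible", "fc_flag", "significant"]
        )
        return out
    out["fdr"] = np.nan
    out["fdr_raw"] = np.nan

    if null_draws:
        if fdr_scope == "per_level":
            scopes = [
                out.index[(out["level"] == lv) & out["eligible"]].to_numpy()
                for lv in out["level"].unique()
            ]
        else:
            scopes = [out.index[out["eligible"]].to_numpy()]
        for idx in scopes:
            if idx.size == 0:
                continue
            obs_p = out.loc[idx, "p_value"].to_numpy()
            perm_p = np.column_stack([null_draws[i] for i in idx])
            fdr, raw = permutation_fdr(obs_p, perm_p)
            out.loc[idx, "fdr"] = fdr
            out.loc[idx, "fdr_raw"] = raw

    out["fdr_pass"] = out["fdr"] <= fdr_bound
    out["significant"] = out["eligible"] & (out["p_value"] <= alpha)
    return out
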