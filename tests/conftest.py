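"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import glycodiff as gd

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------- oracles

def welch_t_oracle(x, y) -> float:
    """Plain-python Welch t, independent of the vectorized implementation."""
    nx, ny = len(x), len(y)
    mx, my = statistics.fmean(x), statistics.fmean(y)
    vx = statistics.variance(x) if nx > 1 else 0.0
    vy = statistics.variance(y) if ny > 1 else 0.0
    denom = math.sqrt(vx / nx + vy / ny)
    if denom == 0.0:
        return 0.0 if mx == my else math.copysign(math.inf, mx - my)
    return (mx - my) / denom


def brute_force_perm_p(x, y) -> float:
    """Exhaustive two-sided permutation p by direct enumeration."""
    pooled = list(x) + list(y)
    nx, n = len(x), len(x) + len(y)
    t_obs = abs(welch_t_oracle(x, y))
    thresh = t_obs if math.isinf(t_obs) else t_obs - 1e-12 * max(1.0, t_obs)
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(welch_t_oracle(xs, ys)) >= thresh:
            count += 1
    return count / total


def trapezoid_oracle(y, t) -> float:
    """Piecewise-trapezoid area by an explicit python loop."""
    return sum(
        0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i]) for i in range(len(t) - 1)
    )


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_effect_design() -> gd.CohortDesign:
    """Small cohort with one fraction-specific injected effect."""
    return gd.CohortDesign(
        n_proteins=20,
        effects=(gd.EffectSpec("G0003", "PHA", 1.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_design() -> gd.CohortDesign:
    """Zero-noise, zero-missingness cohort for exact identities."""
    return gd.CohortDesign(
        n_proteins=12,
        noise_sd=0.0,
        missing_rate=0.0,
        effects=(gd.EffectSpec("G0002", "AAL", 1.5, group_baseline_log2=0.4),),
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_design):
    return gd.generate_cohort(clean_design)


def quant_matrix_from_values(values: dict) -> gd.QuantMatrix:
    """Build a QuantMatrix directly from {(gene, level): {sample: value}}.

    Sample ids starting with 'PCa' are PCa, the rest BPH.
    """
    rows = []
    for (gene, level), per_sample in values.items():
        for sample, val in per_sample.items():
            rows.append(
                {
                    "gene": gene,
                    "level": level,
                    "sample_id": sample,
                    "group": "PCa" if sample.startswith("PCa") else "BPH",
                    "log2_hl": float(val),
                    "n_peptides": 1,
                }
            )
    return gd.QuantMatrix(pd.DataFrame(rows))


def comparison_row(gene, level, p_value, eligible=True, delta=0.0,
                   n_bph=5, n_pca=5):
    return {
        "gene": gene, "level": level, "n_bph": n_bph, "n_pca": n_pca,
        "mean_bph": 0.0, "mean_pca": delta, "delta": delta,
        "t_stat": 0.0, "p_value": p_value if eligible else np.nan,
        "eligible": eligible,
    }
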