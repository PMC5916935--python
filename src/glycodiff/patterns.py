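"""Glycoform expression-pattern classification and plotting tables.

Each gene's cross-fraction significance profile is assigned to one of six
patterns (p <= 0.05 per level):

  A  quantitated in all three M-LAC fractions and significant in all three;
  B  significant in every fraction it was quantitated in (not all three);
  C  significant only at the global protein level;
  D  significant in multiple (>= 2) fractions, without satisfying A or B;
  E  significant in exactly one fraction and at the global level;
  F  significant in exactly one fraction but not at the global level;

with precedence A > B > D > E > F > C > NONE (most specific first).
Group A is defined on the fractions alone; a gene significant in all
three fractions but not globally is still A and is flagged
``global_discordant`` for transparency (opposing fraction trends can
cancel at the global level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FRACTIONS = ("UNB", "AAL", "PHA")
LEVELS = ("UNB", "AAL", "PHA", "GLOBAL")
GROUP_LABELS = ("A", "B", "C", "D", "E", "F", "NONE")


@dataclass(frozen=True)
class PatternAssignment:
    """Pattern label for one gene, with the evidence behind it."""

    gene: str
    group_label: str
    significant_levels: tuple[str, ...]
    quantitated_fractions: tuple[str, ...]
    deltas: dict
    global_discordant: bool = False


def classify_pattern(comparisons: pd.DataFrame, alpha: float = 0.05
                     ) -> PatternAssignment:
    """Classify one gene's comparisons into a pattern group.

    ``comparisons`` holds that gene's rows of the group-comparison table
    (levels UNB/AAL/PHA/GLOBAL). Quantitated fractions are those with an
    eligible comparison; significance is p <= alpha among eligible levels.
    """
    genes = comparisons["gene"].unique()
    if len(genes) != 1:
        raise ValueError("classify_pattern expects comparisons for exactly one gene")
    gene = genes[0]
    elig = comparisons[comparisons["eligible"].astype(bool)]
    sig = elig[elig["p_value"] <= alpha]
    sig_levels = tuple(lv for lv in LEVELS if lv in set(sig["level"]))
    quant_fracs = tuple(f for f in FRACTIONS if f in set(elig["level"]))
    sig_fracs = tuple(f for f in FRACTIONS if f in sig_levels)
    global_sig = "GLOBAL" in sig_levels
    deltas = dict(zip(comparisons["level"], comparisons["delta"]))

    if not len(elig):
        log.warning("gene %s has no eligible levels; pattern NONE", gene)
        label = "NONE"
    elif len(quant_fracs) == 3 and len(sig_fracs) == 3:
        label = "A"
    elif quant_fracs and len(sig_fracs) == len(quant_fracs):
        label = "B"
    elif len(sig_fracs) >= 2:
        label = "D"
    elif len(sig_fracs) == 1 and global_sig:
        label = "E"
    elif len(sig_fracs) == 1:
        label = "F"
    elif global_sig:
        label = "C"
    else:
        label = "NONE"

    discordant = label == "A" and "GLOBAL" in set(elig["level"]) and not global_sig
    return PatternAssignment(
        gene=gene,
        group_label=label,
        significant_levels=sig_levels,
        quantitated_fractions=quant_fracs,
        deltas=deltas,
        global_discordant=discordant,
    )


def classify_patterns(comparisons: pd.DataFrame, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Pattern table: one row per gene with >= 1 eligible level."""
    rows = []
    for gene, sub in comparisons.groupby("gene", sort=True):
        if not sub["eligible"].any():
            continue
        a = classify_pattern(sub, alpha=alpha)
        rows.append(
            {
                "gene": a.gene,
                "group_label": a.group_label,
                "significant_levels": ",".join(a.significant_levels),
                "quantitated_fractions": ",".join(a.quantitated_fractions),
                "global_discordant": a.global_discordant,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "group_label", "significant_levels",
                       "quantitated_fractions", "global_discordant"]
    )


def delta_table(comparisons: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene, per-level difference of means ordered for plotting.

    Delta = mean log2 H/L in PCa minus mean log2 H/L in BPH, with an
    asterisk flag marking p <= alpha. Genes are ordered by pattern group,
    then name; levels in fixed UNB/AAL/PHA/GLOBAL order.
    """
    patterns = classify_patterns(comparisons, alpha=alpha)
    order = {g: (lbl, g) for g, lbl in zip(patterns["gene"], patterns["group_label"])}
    df = comparisons[comparisons["eligible"].astype(bool)].copy()
    df = df[df["gene"].isin(order)]
    df["group_label"] = df["gene"].map(lambda g: order[g][0])
    df["significant"] = df["p_value"] <= alpha
    df["level"] = pd.Categorical(df["level"], categories=LEVELS, ordered=True)
    df = df.sort_values(["group_label", "gene", "level"]).reset_index(drop=True)
    return df[["gene", "group_label", "level", "delta", "p_value", "significant"]]


def heatmap_matrix(matrix, min_n: int = 3) -> dict[str, pd.DataFrame]:
    """Gene-by-level mean log2 H/L tables per group, heat-map ready.

    Includes genes quantified in at least ``min_n`` samples of both
    groups at the global level; rows are ordered by the PCa global mean
    log2 H/L, descending. Cells are NaN (blank) when the group has fewer
    than ``min_n`` samples for that (gene, level) or never detected it.
    """
    df = getattr(matrix, "data", matrix)
    agg = (
        df.groupby(["gene", "level", "group"])["log2_hl"]
        .agg(["mean", "size"])
        .reset_index()
    )
    agg.loc[agg["size"] < min_n, "mean"] = np.nan

    glob = agg[agg["level"] == "GLOBAL"].pivot(
        index="gene", columns="group", values="mean"
    )
    for g in ("BPH", "PCa"):
        if g not in glob.columns:
            glob[g] = np.nan
    keep = glob.dropna(subset=["BPH", "PCa"]).index
    gene_order = glob.loc[keep, "PCa"].sort_values(ascending=False).index

    out = {}
    for g in ("PCa", "BPH"):
        sub = agg[agg["group"] == g].pivot(index="gene", columns="level",
                                           values="mean")
        sub = sub.reindex(index=gene_order, columns=list(LEVELS))
        sub.columns.name = None
        out[g] = sub
    return out
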