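"""Peptide-evidence filtering, gene grouping, protein rollup, normalization.

Peptide H/L ratios are averaged (arithmetic mean on the linear ratio
scale) for each gene group within each M-LAC fraction, giving up to three
fraction-level quantitation values per protein per sample; the global
protein level is the mean over all quantified peptides pooled across
fractions. Ratios are then log2-transformed and median-centered per
sample, the median being taken across all fraction-level values of that
sample; the same per-sample offset is subtracted from the global entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LEVELS = ("UNB", "AAL", "PHA", "GLOBAL")

#: Identification-confidence gates (strict): ProteinProphet-style protein
#: group probability and PeptideProphet-style peptide probability.
PROTEIN_PROB_MIN = 0.9
PEPTIDE_PROB_MIN = 0.6

EVIDENCE_COLUMNS = [
    "sample_id", "group", "fraction", "protein_group", "gene", "peptide",
    "protein_prob", "peptide_prob", "hl_ratio",
]


def confidence_filter(
    evidence: pd.DataFrame,
    protein_prob_min: float = PROTEIN_PROB_MIN,
    peptide_prob_min: float = PEPTIDE_PROB_MIN,
) -> pd.DataFrame:
    """Retain rows with protein_prob > 0.9 AND peptide_prob > 0.6 (strict)."""
    keep = (evidence["protein_prob"] > protein_prob_min) & (
        evidence["peptide_prob"] > peptide_prob_min
    )
    return evidence.loc[keep].reset_index(drop=True)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, a: str) -> str:
        self.parent.setdefault(a, a)
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:  # path compression
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def assemble_gene_groups(evidence: pd.DataFrame) -> pd.DataFrame:
    """Merge rows sharing any gene name into gene groups.

    The ``gene`` column may hold one name or a ``;``-separated candidate
    set. Rows whose name sets intersect (directly or transitively) form
    one group, represented by the lexicographically smallest name in the
    group — a deterministic stand-in for "one gene name was picked". Rows
    with no gene annotation are routed to an ``UNASSIGNED`` bucket and
    logged.
    """
    df = evidence.copy()
    name_sets = [
        [n.strip() for n in str(g).split(";") if n.strip()]
        if not (g is None or (isinstance(g, float) and np.isnan(g)))
        else []
        for g in df["gene"]
    ]
    uf = _UnionFind()
    for names in name_sets:
        for other in names[1:]:
            uf.union(names[0], other)
    members: dict[str, list[str]] = {}
    for names in name_sets:
        for n in names:
            members.setdefault(uf.find(n), []).append(n)
    rep = {root: min(ms) for root, ms in members.items()}

    n_unassigned = sum(1 for names in name_sets if not names)
    if n_unassigned:
        log.warning("%d evidence rows lack gene annotation; bucketed as UNASSIGNED",
                    n_unassigned)
    df["gene"] = [
        rep[uf.find(names[0])] if names else "UNASSIGNED" for names in name_sets
    ]
    return df


def per_fraction_ratio(ratios) -> float:
    """Mean peptide H/L for one (gene, sample, fraction)."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("per_fraction_ratio requires at least one peptide ratio")
    return float(arr.mean())


def global_ratio(ratios) -> float:
    """Mean H/L over all quantified peptides of a gene in one sample,
    pooled across fractions (not the mean of fraction means)."""
    return per_fraction_ratio(ratios)


@dataclass
class QuantMatrix:
    """Normalized log2 H/L values indexed by (gene, level, sample).

    ``data`` is long-format with columns gene, level (UNB/AAL/PHA/GLOBAL),
    sample_id, group, log2_hl, n_peptides. A GLOBAL entry exists for every
    (gene, sample) that has any fraction entry; after normalization the
    median of each sample's pooled fraction-level values is zero.
    """

    data: pd.DataFrame

    def pivot(self, level: str) -> pd.DataFrame:
        sub = self.data[self.data["level"] == level]
        return sub.pivot(index="gene", columns="sample_id", values="log2_hl")

    def sample_groups(self) -> pd.Series:
        return (
            self.data[["sample_id", "group"]]
            .drop_duplicates()
            .set_index("sample_id")["group"]
        )

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "QuantMatrix":
        return cls(pd.read_csv(path, sep="\t"))


def log2_median_center(protein_ratios: pd.DataFrame) -> QuantMatrix:
    """log2-transform and median-center per-sample protein-level ratios.

    Input: long-format linear-scale rollup with columns gene, level,
    sample_id, group, hl_mean, n_peptides. Each value becomes
    ``log2(hl_mean) - median(log2 of that sample's fraction-level
    values)``; the same offset applies to the sample's GLOBAL entries.

    Raises
    ------
    ValueError
        If any ratio is nonpositive (log2 undefined), naming the row.
    """
    df = protein_ratios.copy()
    bad = df[~(df["hl_mean"] > 0)]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"nonpositive H/L ratio {r['hl_mean']!r} for gene={r['gene']} "
            f"level={r['level']} sample={r['sample_id']}"
        )
    df["log2_hl"] = np.log2(df["hl_mean"].to_numpy())
    frac = df[df["level"] != "GLOBAL"]
    offsets = frac.groupby("sample_id")["log2_hl"].median()
    # a sample with only GLOBAL entries cannot occur by construction, but
    # fall back to its own median rather than fail
    fallback = df.groupby("sample_id")["log2_hl"].median()
    offsets = offsets.reindex(fallback.index).fillna(fallback)
    df["log2_hl"] = df["log2_hl"] - df["sample_id"].map(offsets).to_numpy()
    out = df[["gene", "level", "sample_id", "group", "log2_hl", "n_peptides"]]
    return QuantMatrix(out.reset_index(drop=True))


def rollup_protein_ratios(
    evidence: pd.DataFrame, global_mode: str = "pooled"
) -> pd.DataFrame:
    """Linear-scale rollup: per-fraction and global mean H/L per gene/sample.

    ``global_mode`` selects how the global protein level is formed:
    ``"pooled"`` (default) averages all quantified peptides regardless of
    fraction; ``"mean_of_means"`` averages the fraction-level means.
    """
    if global_mode not in ("pooled", "mean_of_means"):
        raise ValueError(f"unknown global_mode {global_mode!r}")
    frac = (
        evidence.groupby(["gene", "sample_id", "group", "fraction"], sort=True)[
            "hl_ratio"
        ]
        .agg(hl_mean="mean", n_peptides="size")
        .reset_index()
        .rename(columns={"fraction": "level"})
    )
    if global_mode == "pooled":
        glob = (
            evidence.groupby(["gene", "sample_id", "group"], sort=True)["hl_ratio"]
            .agg(hl_mean="mean", n_peptides="size")
            .reset_index()
        )
    else:
        glob = (
            frac.groupby(["gene", "sample_id", "group"], sort=True)
            .agg(hl_mean=("hl_mean", "mean"), n_peptides=("n_peptides", "sum"))
            .reset_index()
        )
    glob["level"] = "GLOBAL"
    out = pd.concat([frac, glob], ignore_index=True)
    return out[["gene", "level", "sample_id", "group", "hl_mean", "n_peptides"]]


def build_quant_matrix(
    evidence: pd.DataFrame,
    protein_prob_min: float = PROTEIN_PROB_MIN,
    peptide_prob_min: float = PEPTIDE_PROB_MIN,
    global_mode: str = "pooled",
) -> tuple[QuantMatrix, dict[str, int]]:
    """Full rollup: confidence filter, gene grouping, averaging, centering.

    Returns the normalized matrix and a dict of bookkeeping counts
    (rows in, rows dropped by the confidence filter, rows retained).
    """
    n_in = len(evidence)
    retained = confidence_filter(evidence, protein_prob_min, peptide_prob_min)
    grouped = assemble_gene_groups(retained)
    ratios = rollup_protein_ratios(grouped, global_mode=global_mode)
    qm = log2_median_center(ratios)
    counts = {
        "evidence_rows_in": n_in,
        "confidence_filter_dropped": n_in - len(retained),
        "evidence_rows_retained": len(retained),
        "quant_entries": len(qm.data),
    }
    return qm, counts
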