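"""Synthetic serum glycoproteomics cohort generator.

Emulates the study design the analysis pipeline assumes: two case groups
(7 benign prostatic hyperplasia, 10 prostate cancer samples by default),
each isotopically quantified against a common reference pool, with protein
glycoforms partitioned across three multi-lectin affinity chromatography
(M-LAC) fractions — unbound flow-through (UNB), Aleuria aurantia lectin
bound (AAL, core-fucosylated), and Phaseolus vulgaris L/E bound (PHA,
highly branched complex-type). The generator injects known global or
fraction-specific log2 effects, records them as ground truth, and emits
peptide-evidence tables (and optionally raw paired elution profiles) so
every downstream stage is testable without the undeposited raw data.

Latent model: each (sample, gene, fraction) draws a latent log2 H/L from
Normal(baseline + group effect, noise_sd); each peptide observation adds
independent Normal(0, noise_sd) measurement noise on the log2 scale. Only
cysteine-containing peptides are quantifiable (the acrylamide label sits
on cysteine); peptides drawn with zero cysteines are generated but
excluded from quantifiable output. The reference pool is implicit — H/L
already encodes case-versus-reference — so no reference rows are emitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from glycodiff.quant import ElutionPair

FRACTIONS = ("UNB", "AAL", "PHA")
LEVELS = ("UNB", "AAL", "PHA", "GLOBAL")
GROUPS = ("BPH", "PCa")

#: SD of per-(gene, fraction) baseline log2 shifts versus the reference
#: pool for genes without an injected effect.
BASELINE_SD = 1.0

#: Fraction of proteins / peptides drawn below the identification
#: confidence gates, emulating residual low-confidence search output.
LOW_CONF_PROTEIN_RATE = 0.05
LOW_CONF_PEPTIDE_RATE = 0.10

_AMINO = np.array(list("ADEFGHIKLMNPQRSTVWY"))  # no C; cysteines placed explicitly


@dataclass(frozen=True)
class EffectSpec:
    """One injected differential-expression effect.

    ``scope`` is either ``"GLOBAL"`` (the effect applies in every fraction
    the gene occupies) or one M-LAC fraction name (the effect applies only
    within that fraction). ``delta_log2`` is the true PCa − BPH group-mean
    difference on the log2 H/L scale; ``group_baseline_log2`` is the shift
    of both groups versus the reference pool.
    """

    gene: str
    scope: str
    delta_log2: float
    group_baseline_log2: float = 0.0

    def __post_init__(self) -> None:
        if self.scope not in LEVELS:
            raise ValueError(f"scope must be one of {LEVELS}, got {self.scope!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study conditions: 7 BPH and 10 PCa samples,
    three M-LAC fractions, and a protein count in the range the platform
    quantifies from immunodepleted serum.
    """

    n_bph: int = 7
    n_pca: int = 10
    fractions: tuple[str, ...] = FRACTIONS
    n_proteins: int = 250
    peptides_per_protein: tuple[int, int] = (2, 6)
    cys_per_peptide: tuple[int, int] = (0, 3)
    frac_presence_probs: tuple[float, ...] = (0.80, 0.65, 0.65)
    missing_rate: float = 0.20
    noise_sd: float = 0.50
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bph < 0 or self.n_pca < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if len(self.fractions) == 0:
            raise ValueError("fraction list must be nonempty")
        if len(self.frac_presence_probs) != len(self.fractions):
            raise ValueError("frac_presence_probs must match fractions")
        if any(not 0 <= p <= 1 for p in self.frac_presence_probs):
            raise ValueError("frac_presence_probs entries must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a valid range with lo >= 1")
        lo, hi = self.cys_per_peptide
        if lo < 0 or hi < lo:
            raise ValueError("cys_per_peptide must be a valid range with lo >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"BPH_{i + 1}" for i in range(self.n_bph)] + [
            f"PCa_{i + 1}" for i in range(self.n_pca)
        ]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_proteins)]


@dataclass
class SyntheticTruth:
    """Ground truth for one generated cohort.

    ``latent`` holds one row per (sample, gene, occupied fraction) with the
    pre-noise latent log2 H/L; every emitted peptide-evidence row is
    traceable to exactly one latent row via (sample_id, gene, fraction).
    """

    effects: tuple[EffectSpec, ...]
    latent: pd.DataFrame

    def write_tsv(self, effects_path, latent_path) -> None:
        pd.DataFrame([vars(e) for e in self.effects] or None,
                     columns=["gene", "scope", "delta_log2", "group_baseline_log2"],
                     ).to_csv(effects_path, sep="\t", index=False)
        self.latent.to_csv(latent_path, sep="\t", index=False)


def _layout(design: CohortDesign, rng: np.random.Generator):
    """Draw the cohort skeleton: proteins, peptides, fraction occupancy."""
    genes = design.gene_names
    effect_by_gene = {e.gene: e for e in design.effects}
    unknown = set(effect_by_gene) - set(genes)
    if unknown:
        raise ValueError(f"effects reference unknown genes: {sorted(unknown)}")

    # fraction occupancy per protein; every protein occupies >= 1 fraction,
    # and an effect gene always occupies its scoped fraction
    occ = rng.random((design.n_proteins, len(design.fractions))) < np.asarray(
        design.frac_presence_probs
    )
    for i in np.flatnonzero(~occ.any(axis=1)):
        occ[i, rng.integers(len(design.fractions))] = True
    frac_index = {f: j for j, f in enumerate(design.fractions)}
    for i, g in enumerate(genes):
        eff = effect_by_gene.get(g)
        if eff is not None and eff.scope in frac_index:
            occ[i, frac_index[eff.scope]] = True

    # effect genes are guaranteed quantifiable (confident protein group,
    # >= 1 cysteine peptide): an injected truth that could never be
    # observed would break the end-to-end identity the truth record exists
    # to support
    has_effect = np.array([g in effect_by_gene for g in genes])
    protein_low = (rng.random(design.n_proteins) < LOW_CONF_PROTEIN_RATE) & ~has_effect
    protein_prob = np.where(
        protein_low,
        rng.uniform(0.5, 0.9, design.n_proteins),
        rng.uniform(0.905, 1.0, design.n_proteins),
    )

    lo, hi = design.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, design.n_proteins)
    peptides = []
    c_lo, c_hi = design.cys_per_peptide
    for i, g in enumerate(genes):
        for k in range(n_pep[i]):
            n_cys = int(rng.integers(c_lo, c_hi + 1))
            if has_effect[i] and k == 0:
                n_cys = max(1, n_cys)
            length = int(rng.integers(8, 18))
            seq = "".join(rng.choice(_AMINO, size=length))
            # place cysteines deterministically from the draw, K terminus (tryptic)
            seq = "C" * n_cys + seq + "K"
            pep_low = (rng.random() < LOW_CONF_PEPTIDE_RATE) and not (
                has_effect[i] and k == 0
            )
            peptide_prob = (
                float(rng.uniform(0.2, 0.6)) if pep_low else float(rng.uniform(0.605, 1.0))
            )
            peptides.append(
                {
                    "gene": g,
                    "protein_group": f"ACC{i + 1:04d}",
                    "peptide": seq,
                    "n_cys": n_cys,
                    "protein_prob": float(protein_prob[i]),
                    "peptide_prob": peptide_prob,
                    "charge": int(rng.integers(2, 4)),
                    "theoretical_mass": float(rng.uniform(800.0, 3000.0)),
                }
            )
    return pd.DataFrame(peptides), occ, effect_by_gene


def _latents(design: CohortDesign, occ: np.ndarray, effect_by_gene: dict,
             rng: np.random.Generator) -> pd.DataFrame:
    """Per-(sample, gene, fraction) latent log2 H/L before peptide noise."""
    genes = design.gene_names
    samples = design.sample_ids
    is_pca = np.array([s.startswith("PCa") for s in samples])

    rows = []
    for i, g in enumerate(genes):
        eff = effect_by_gene.get(g)
        for j, f in enumerate(design.fractions):
            if not occ[i, j]:
                continue
            if eff is not None:
                base = eff.group_baseline_log2
                applies = eff.scope == "GLOBAL" or eff.scope == f
                delta = eff.delta_log2 if applies else 0.0
            else:
                base = float(rng.normal(0.0, BASELINE_SD))
                delta = 0.0
            noise = rng.normal(0.0, design.noise_sd, len(samples))
            latent = base + delta * is_pca + noise
            for s, grp_pca, lat in zip(samples, is_pca, latent):
                rows.append(
                    {
                        "sample_id": s,
                        "group": "PCa" if grp_pca else "BPH",
                        "gene": g,
                        "fraction": f,
                        "latent_log2": float(lat),
                    }
                )
    return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a peptide-evidence table and its ground truth.

    Returns one evidence row per surviving (sample, peptide, fraction)
    observation, with ``hl_ratio = 2**(latent + noise)``; only peptides
    with at least one cysteine appear. All randomness flows from
    ``design.seed``: the same design yields byte-identical tables.
    """
    rng = np.random.default_rng(design.seed)
    pep_df, occ, effect_by_gene = _layout(design, rng)
    latent_df = _latents(design, occ, effect_by_gene, rng)
    truth = SyntheticTruth(effects=tuple(design.effects), latent=latent_df)

    latent_lookup = {
        (r.sample_id, r.gene, r.fraction): r.latent_log2
        for r in latent_df.itertuples()
    }
    gene_index = {g: i for i, g in enumerate(design.gene_names)}
    frac_list = list(design.fractions)

    rows = []
    for pep in pep_df.itertuples():
        if pep.n_cys < 1:
            continue  # no label site: not quantifiable
        gi = gene_index[pep.gene]
        for j, f in enumerate(frac_list):
            if not occ[gi, j]:
                continue
            for s in design.sample_ids:
                if rng.random() < design.missing_rate:
                    continue
                log2_obs = latent_lookup[(s, pep.gene, f)] + rng.normal(
                    0.0, design.noise_sd
                )
                rows.append(
                    {
                        "sample_id": s,
                        "group": "PCa" if s.startswith("PCa") else "BPH",
                        "fraction": f,
                        "protein_group": pep.protein_group,
                        "gene": pep.gene,
                        "peptide": pep.peptide,
                        "protein_prob": pep.protein_prob,
                        "peptide_prob": pep.peptide_prob,
                        "n_cys": pep.n_cys,
                        "hl_ratio": float(2.0 ** log2_obs),
                    }
                )
    evidence = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "fraction", "protein_group", "gene", "peptide",
            "protein_prob", "peptide_prob", "n_cys", "hl_ratio",
        ],
    )
    return evidence, truth


def generate_elution_pairs(
    design: CohortDesign,
    grid_points: int = 41,
    profile_noise_scale: float = 0.1,
) -> tuple[list[ElutionPair], SyntheticTruth]:
    """Generate raw paired elution profiles with known true H/L ratios.

    Each would-be peptide observation becomes one light/heavy profile pair:
    a Gaussian elution peak on a fixed retention grid, with the heavy
    profile equal to ``true_ratio`` times the light shape up to
    multiplicative point noise of SD ``profile_noise_scale * noise_sd``.
    Zero-cysteine peptides are emitted too (they exercise the label-site
    requirement downstream). Precursor mass errors are drawn with SD 8 ppm,
    so a small tail falls outside the 20 ppm accuracy gate.
    """
    rng = np.random.default_rng(design.seed)
    pep_df, occ, effect_by_gene = _layout(design, rng)
    latent_df = _latents(design, occ, effect_by_gene, rng)
    truth = SyntheticTruth(effects=tuple(design.effects), latent=latent_df)

    latent_lookup = {
        (r.sample_id, r.gene, r.fraction): r.latent_log2
        for r in latent_df.itertuples()
    }
    gene_index = {g: i for i, g in enumerate(design.gene_names)}
    grid = np.linspace(10.0, 12.0, grid_points)
    point_sd = profile_noise_scale * design.noise_sd

    pairs: list[ElutionPair] = []
    k = 0
    for pep in pep_df.itertuples():
        gi = gene_index[pep.gene]
        for j, f in enumerate(design.fractions):
            if not occ[gi, j]:
                continue
            for s in design.sample_ids:
                if rng.random() < design.missing_rate:
                    continue
                log2_true = latent_lookup[(s, pep.gene, f)] + rng.normal(
                    0.0, design.noise_sd
                )
                true_ratio = float(2.0 ** log2_true)
                center = float(rng.uniform(10.6, 11.4))
                width = float(rng.uniform(0.10, 0.25))
                amp = float(rng.lognormal(10.0, 1.0))
                shape = amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
                light = shape * np.clip(
                    1.0 + rng.normal(0.0, point_sd, grid_points), 0.0, None
                )
                heavy = true_ratio * shape * np.clip(
                    1.0 + rng.normal(0.0, point_sd, grid_points), 0.0, None
                )
                ppm_err = float(rng.normal(0.0, 8.0))
                k += 1
                pairs.append(
                    ElutionPair(
                        pair_id=f"EP{k:06d}",
                        retention_grid=grid,
                        light_intensity=light,
                        heavy_intensity=heavy,
                        charge=pep.charge,
                        n_cys=pep.n_cys,
                        observed_precursor_mass=pep.theoretical_mass
                        * (1.0 + ppm_err * 1e-6),
                        theoretical_precursor_mass=pep.theoretical_mass,
                        true_ratio=true_ratio,
                        meta={
                            "sample_id": s,
                            "group": "PCa" if s.startswith("PCa") else "BPH",
                            "fraction": f,
                            "protein_group": pep.protein_group,
                            "gene": pep.gene,
                            "peptide": pep.peptide,
                            "protein_prob": pep.protein_prob,
                            "peptide_prob": pep.peptide_prob,
                        },
                    )
                )
    return pairs, truth


_CLINICAL_TSV = """\
sample_id\tsample_type\tage\tpsa_ng_ml\tpercent_g4_5\ttotal_cancer_volume_cc\tgleason
PCa_1\tPCa\t56\t10.20\t70\t4.37\t4+3=7
PCa_2\tPCa\t66\t3.92\t90\t8.55\t4+3=7
PCa_3\tPCa\t50\t15.48\t80\t9.00\t4+3=7
PCa_4\tPCa\t58\t6.36\t60\t9.03\t4+3=7
PCa_5\tPCa\t60\t21.30\t90\t4.93\t4+3=7
PCa_6\tPCa\t70\t3.27\t70\t6.00\t4+3=7
PCa_7\tPCa\t46\t30.13\t90\t1.00\t4+3=7
PCa_8\tPCa\t68\t16.11\t95\t29.39\t4+3=7
PCa_9\tPCa\t64\t13.40\t60\t7.20\t4+3=7
PCa_10\tPCa\t56\t8.71\t50\t4.56\t4+3=7
BPH_1\tBPH\t62\t3.14\tN/A\tN/A\tN/A
BPH_2\tBPH\t73\t4.20\tN/A\tN/A\tN/A
BPH_3\tBPH\t69\t11.16\tN/A\tN/A\tN/A
BPH_4\tBPH\t71\t13.80\tN/A\tN/A\tN/A
BPH_5\tBPH\t56\t7.67\tN/A\tN/A\tN/A
BPH_6\tBPH\t44\t3.42\tN/A\tN/A\tN/A
BPH_7\tBPH\t61\t8.21\tN/A\tN/A\tN/A
"""


def clinical_fixture() -> pd.DataFrame:
    """Clinical characteristics of the 17-sample cohort.

    Ten prostate cancer samples (all pathological Gleason 4+3=7, cancer
    volume >= 1 cc) with age, PSA, percent Gleason pattern 4/5 and total
    cancer volume, plus seven benign prostatic hyperplasia samples whose
    cancer-specific fields are N/A.
    """
    return pd.read_csv(
        io.StringIO(_CLINICAL_TSV), sep="\t", na_values=["N/A"]
    )


def with_seed(design: CohortDesign, seed: int) -> CohortDesign:
    """Copy of ``design`` with a different seed (designs are frozen)."""
    return replace(design, seed=seed)
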