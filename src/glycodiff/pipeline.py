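"""End-to-end orchestration: simulate → quantify → roll up → test → classify.

A run is described by a :class:`RunConfig` (optionally loaded from a YAML
key-value file), executes with all randomness seeded, and writes
tab-separated tables — quantitation matrix, group comparisons, pattern
assignments, delta table, heat-map matrices — plus a JSON manifest
recording the configuration, seed, package version, row counts and every
exclusion count, so no observation is dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from glycodiff import quant, rollup, stats
from glycodiff.patterns import classify_patterns, delta_table, heatmap_matrix
from glycodiff.simulate import CohortDesign, EffectSpec, generate_cohort, \
    generate_elution_pairs

log = logging.getLogger(__name__)

#: Chromatographic depth recorded in the manifest: each M-LAC fraction is
#: further split into 13 reversed-phase fractions before LC-MS/MS, giving
#: 13 x 3 = 39 fraction slots per sample. The RP dimension affects depth
#: of sampling only, not the statistical model, so it is metadata here.
RP_FRACTIONS = 13


class PipelineError(Exception):
    exit_code = 1


class MissingInputError(PipelineError):
    exit_code = 2


class SchemaError(PipelineError):
    exit_code = 3


class OutputError(PipelineError):
    exit_code = 4


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "end_to_end"  # simulate | analyze | end_to_end
    design: CohortDesign = field(default_factory=CohortDesign)
    evidence_path: str | None = None
    out_dir: str = "glycodiff_run"
    n_perm: int = stats.DEFAULT_N_PERM
    perm_cap: int = stats.DEFAULT_PERM_CAP
    n_perm_fdr: int = stats.DEFAULT_N_PERM_FDR
    alpha: float = stats.DEFAULT_ALPHA
    fdr_bound: float = stats.DEFAULT_FDR_BOUND
    fc_log2: float = stats.DEFAULT_FC_LOG2
    global_mode: str = "pooled"
    fdr_scope: str = "per_level"
    via_elution_pairs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "end_to_end"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_bound < 1:
            raise ValueError("alpha and fdr_bound must lie in (0, 1)")
        if self.fc_log2 < 0:
            raise ValueError("fc_log2 must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise MissingInputError(f"config file not found: {path}") from exc
        design_raw = raw.pop("design", {})
        effects = tuple(
            EffectSpec(**e) for e in design_raw.pop("effects", [])
        )
        for key in ("fractions", "peptides_per_protein", "cys_per_peptide",
                    "frac_presence_probs"):
            if key in design_raw:
                design_raw[key] = tuple(design_raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=CohortDesign(effects=effects, **design_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["effects"] = [dataclasses.asdict(e) for e in self.design.effects]
        return d


def _load_evidence(path) -> pd.DataFrame:
    if path is None:
        raise MissingInputError("analyze mode requires evidence_path")
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"evidence file not found: {p}")
    df = pd.read_csv(p, sep="\t")
    required = {"sample_id", "group", "fraction", "gene", "protein_prob",
                "peptide_prob", "hl_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"evidence table missing columns: {sorted(missing)}")
    bad_groups = set(df["group"].unique()) - {"BPH", "PCa"}
    if bad_groups:
        raise SchemaError(f"unknown group labels: {sorted(bad_groups)}")
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute one run; returns the manifest (also written to out_dir).

    Identical config + seed produce byte-identical output tables.
    """
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OutputError(f"output directory not writable: {out}") from exc

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("glycodiff")
    root.addHandler(fh)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "glycodiff_version": __import__("glycodiff").__version__,
        "rp_fractions": RP_FRACTIONS,
        "mlac_fractions": len(config.design.fractions),
        "fraction_slots_per_sample": RP_FRACTIONS * len(config.design.fractions),
        "exclusions": {},
        "row_counts": {},
    }

    try:
        design = replace(config.design, seed=config.seed)
        if config.mode in ("simulate", "end_to_end"):
            if config.via_elution_pairs:
                pairs, truth = generate_elution_pairs(design)
                quant.write_elution_pairs(
                    pairs, out / "elution_profiles.tsv", out / "elution_meta.tsv"
                )
                evidence, dropped = quant.pairs_to_evidence(pairs)
                manifest["exclusions"].update(dropped)
                manifest["row_counts"]["elution_pairs"] = len(pairs)
            else:
                evidence, truth = generate_cohort(design)
            evidence.to_csv(out / "peptide_evidence.tsv", sep="\t", index=False)
            truth.write_tsv(out / "truth_effects.tsv", out / "truth_latent.tsv")
            log.info("simulated %d evidence rows for %d samples",
                     len(evidence), len(design.sample_ids))
        else:
            evidence = _load_evidence(config.evidence_path)
        manifest["row_counts"]["peptide_evidence"] = len(evidence)

        if config.mode == "simulate":
            _write_manifest(manifest, out)
            return manifest

        qm, counts = rollup.build_quant_matrix(
            evidence, global_mode=config.global_mode
        )
        manifest["exclusions"]["confidence_filter"] = counts[
            "confidence_filter_dropped"
        ]
        manifest["row_counts"]["quant_entries"] = counts["quant_entries"]
        qm.write_tsv(out / "quant_matrix.tsv")

        comparisons = stats.compare_groups(
            qm,
            seed=config.seed,
            n_perm=config.n_perm,
            cap=config.perm_cap,
            n_perm_fdr=config.n_perm_fdr,
            alpha=config.alpha,
            fdr_bound=config.fdr_bound,
            fc_log2=config.fc_log2,
            fdr_scope=config.fdr_scope,
        )
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        n_elig = int(comparisons["eligible"].sum())
        manifest["row_counts"]["comparisons"] = len(comparisons)
        manifest["row_counts"]["eligible_comparisons"] = n_elig
        manifest["exclusions"]["ineligible_n_lt_3"] = len(comparisons) - n_elig
        log.info("tested %d eligible (gene, level) features", n_elig)

        pattern_df = classify_patterns(comparisons, alpha=config.alpha)
        pattern_df.to_csv(out / "patterns.tsv", sep="\t", index=False)
        deltas = delta_table(comparisons, alpha=config.alpha)
        deltas.to_csv(out / "delta_table.tsv", sep="\t", index=False)
        heat = heatmap_matrix(qm)
        for grp, table in heat.items():
            table.to_csv(out / f"heatmap_{grp.lower()}.tsv", sep="\t")
        manifest["row_counts"]["patterns"] = len(pattern_df)
        manifest["row_counts"]["heatmap_genes"] = len(heat["PCa"])

        _write_manifest(manifest, out)
        return manifest
    finally:
        root.removeHandler(fh)
        fh.close()


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
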