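"""Isotope-pair peptide quantitation.

Cysteine residues of case samples are alkylated with heavy (13C3)
acrylamide and the common reference pool with light (12C3) acrylamide, so
the labeled forms of a peptide co-elute but are offset in m/z by a nominal
3 Da per labeled cysteine, divided by charge. The heavy/light (H/L)
abundance ratio of a peptide is the ratio of the areas under the heavy and
light extracted elution profiles. Observations whose precursor mass
deviates from theory by 20 ppm or more are excluded from quantitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Nominal mass difference per labeled cysteine (heavy minus light), Da.
PER_LABEL_SHIFT_DA = 3.0

#: Exact monoisotopic 13C3 - 12C3 difference, Da. Available for mass
#: bookkeeping; the nominal 3 Da value is the default throughout.
PER_LABEL_SHIFT_MONOISOTOPIC_DA = 3 * 1.003355

#: Default precursor mass-accuracy gate (strict), ppm.
DEFAULT_MAX_PPM = 20.0


class UnquantifiablePeptideError(ValueError):
    """Peptide carries no cysteine label site and cannot be quantified."""


class ZeroLightAreaError(ValueError):
    """Light elution profile integrates to zero; the H/L ratio is undefined."""


@dataclass
class ElutionPair:
    """Paired light/heavy extracted elution profiles for one labeled peptide.

    Parameters
    ----------
    retention_grid : array of float
        Strictly increasing retention times, minutes.
    light_intensity, heavy_intensity : array of float
        Nonnegative intensities on ``retention_grid``.
    charge : int
        Precursor charge state (>= 1).
    n_cys : int
        Number of labeled cysteines (>= 1 for a quantifiable pair).
    observed_precursor_mass, theoretical_precursor_mass : float
        Neutral precursor masses in Da, used by the ppm accuracy gate.
    true_ratio : float, optional
        Generating H/L ratio when the pair is synthetic; ``None`` for data.
    meta : dict
        Provenance (sample, group, fraction, gene, peptide, probabilities).
    """

    pair_id: str
    retention_grid: np.ndarray
    light_intensity: np.ndarray
    heavy_intensity: np.ndarray
    charge: int
    n_cys: int
    observed_precursor_mass: float
    theoretical_precursor_mass: float
    true_ratio: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.retention_grid = np.asarray(self.retention_grid, dtype=float)
        self.light_intensity = np.asarray(self.light_intensity, dtype=float)
        self.heavy_intensity = np.asarray(self.heavy_intensity, dtype=float)
        n = self.retention_grid.size
        if self.light_intensity.size != n or self.heavy_intensity.size != n:
            raise ValueError("intensity arrays must match the retention grid length")
        if n >= 2 and not np.all(np.diff(self.retention_grid) > 0):
            raise ValueError("retention_grid must be strictly increasing")
        if np.any(self.light_intensity < 0) or np.any(self.heavy_intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


def expected_heavy_shift(
    n_cys: int, charge: int, per_label_da: float = PER_LABEL_SHIFT_DA
) -> float:
    """m/z offset (Th) between the heavy and light forms of a peptide.

    Each labeled cysteine adds ``per_label_da`` (nominally 3 Da) to the
    heavy form, so the spectrum shift is ``per_label_da * n_cys / charge``.

    Raises
    ------
    UnquantifiablePeptideError
        If ``n_cys`` is 0: no label site, the peptide cannot be quantified.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if n_cys < 0:
        raise ValueError("n_cys must be nonnegative")
    if n_cys == 0:
        raise UnquantifiablePeptideError(
            "peptide has no cysteine and therefore no isotope label site"
        )
    return per_label_da * n_cys / charge


def integrate_pair(pair: ElutionPair) -> float:
    """H/L ratio: heavy elution area over light elution area.

    Areas are trapezoidal integrals of each profile across the full
    retention grid.

    Raises
    ------
    UnquantifiablePeptideError
        If the pair has no labeled cysteine.
    ZeroLightAreaError
        If the light profile integrates to zero (ratio undefined; the
        observation is dropped upstream with a logged reason).
    """
    if pair.n_cys < 1:
        raise UnquantifiablePeptideError(
            f"pair {pair.pair_id}: no cysteine label site"
        )
    light_area = float(np.trapezoid(pair.light_intensity, pair.retention_grid))
    heavy_area = float(np.trapezoid(pair.heavy_intensity, pair.retention_grid))
    if light_area <= 0:
        raise ZeroLightAreaError(
            f"pair {pair.pair_id}: light elution area is zero, H/L undefined"
        )
    return heavy_area / light_area


def ppm_filter(
    observed_mass: float,
    theoretical_mass: float,
    max_ppm: float = DEFAULT_MAX_PPM,
) -> bool:
    """Keep/drop decision on precursor mass accuracy.

    Keeps the observation iff the fractional delta mass
    ``|observed - theoretical| / theoretical * 1e6`` is strictly below
    ``max_ppm``.
    """
    if theoretical_mass <= 0:
        raise ValueError("theoretical_mass must be positive")
    ppm = abs(observed_mass - theoretical_mass) / theoretical_mass * 1e6
    return ppm < max_ppm


def pairs_to_evidence(
    pairs: list[ElutionPair], max_ppm: float = DEFAULT_MAX_PPM
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quantify a collection of elution pairs into a peptide-evidence table.

    Applies, in order: the cysteine-label requirement, the strict ppm
    precursor accuracy gate, and the nonzero-light-area requirement.
    Returns the evidence table plus counts of exclusions by reason so no
    observation is dropped silently.
    """
    rows = []
    dropped = {"no_cysteine": 0, "ppm_filter": 0, "zero_light_area": 0}
    for pair in pairs:
        if pair.n_cys < 1:
            dropped["no_cysteine"] += 1
            continue
        if not ppm_filter(
            pair.observed_precursor_mass, pair.theoretical_precursor_mass, max_ppm
        ):
            dropped["ppm_filter"] += 1
            continue
        try:
            ratio = integrate_pair(pair)
        except ZeroLightAreaError:
            dropped["zero_light_area"] += 1
            continue
        rows.append({**pair.meta, "pair_id": pair.pair_id, "hl_ratio": ratio})
    columns = [
        "sample_id", "group", "fraction", "protein_group", "gene", "peptide",
        "protein_prob", "peptide_prob", "pair_id", "hl_ratio",
    ]
    evidence = pd.DataFrame(rows)
    if not evidence.empty:
        evidence = evidence[[c for c in columns if c in evidence.columns]]
    return evidence, dropped


def write_elution_pairs(pairs: list[ElutionPair], profile_path, meta_path) -> None:
    """Write pairs as long-format TSV plus a sidecar metadata TSV."""
    prof_rows = []
    meta_rows = []
    for p in pairs:
        for t, lo, hi in zip(p.retention_grid, p.light_intensity, p.heavy_intensity):
            prof_rows.append((p.pair_id, t, lo, hi))
        meta_rows.append(
            {
                "pair_id": p.pair_id,
                "charge": p.charge,
                "n_cys": p.n_cys,
                "observed_precursor_mass": p.observed_precursor_mass,
                "theoretical_precursor_mass": p.theoretical_precursor_mass,
                "true_ratio": "" if p.true_ratio is None else p.true_ratio,
                **p.meta,
            }
        )
    pd.DataFrame(
        prof_rows, columns=["pair_id", "retention_min", "light", "heavy"]
    ).to_csv(profile_path, sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def read_elution_pairs(profile_path, meta_path) -> list[ElutionPair]:
    """Read pairs written by :func:`write_elution_pairs`."""
    prof = pd.read_csv(profile_path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t")
    meta_cols = {
        "pair_id", "charge", "n_cys", "observed_precursor_mass",
        "theoretical_precursor_mass", "true_ratio",
    }
    pairs = []
    grouped = prof.groupby("pair_id", sort=False)
    for rec in meta.to_dict("records"):
        chunk = grouped.get_group(rec["pair_id"])
        true_ratio = rec.get("true_ratio")
        if true_ratio is not None and pd.isna(true_ratio):
            true_ratio = None
        pairs.append(
            ElutionPair(
                pair_id=str(rec["pair_id"]),
                retention_grid=chunk["retention_min"].to_numpy(),
                light_intensity=chunk["light"].to_numpy(),
                heavy_intensity=chunk["heavy"].to_numpy(),
                charge=int(rec["charge"]),
                n_cys=int(rec["n_cys"]),
                observed_precursor_mass=float(rec["observed_precursor_mass"]),
                theoretical_precursor_mass=float(rec["theoretical_precursor_mass"]),
                true_ratio=None if true_ratio is None else float(true_ratio),
                meta={k: v for k, v in rec.items() if k not in meta_cols},
            )
        )
    return pairs
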