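"""Run the whole pipeline end to end from a single configuration.

simulate -> roll up -> normalize -> permutation test -> classify,
writing every table plus a manifest; the same config and seed always
reproduce byte-identical outputs. The equivalent shell command is
`glycodiff run-all --seed 11 --out <dir>`.
"""

import tempfile
from pathlib import Path

import pandas as pd

import glycodiff as gd
from glycodiff.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(
        mode="end_to_end",
        design=gd.CohortDesign(effects=(gd.EffectSpec("G0001", "AAL", 1.2),)),
        out_dir=tmp,
        seed=11,
    )
    manifest = run_pipeline(cfg)
    print("row counts:", manifest["row_counts"])
    print("exclusions:", manifest["exclusions"])
    print("fraction slots per sample:",
          manifest["fraction_slots_per_sample"], "(13 RP x 3 M-LAC)")
    comp = pd.read_csv(Path(tmp) / "comparisons.tsv", sep="\t")
    hit = comp[(comp["gene"] == "G0001") & (comp["level"] == "AAL")]
    print(hit[["gene", "level", "delta", "p_value", "fdr"]].to_string(index=False))
print("-> the injected AAL effect is recovered with an exact permutation "
      "p-value; all artifacts were written alongside a reproducibility "
      "manifest.")
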