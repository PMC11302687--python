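"""Full pipeline: from synthetic cohort to nominated disease effectors.

Generates the demo study (3 proteins whose causal variants also raise
disease risk + 7 decoy proteins with QTLs but no disease link), runs
QTL scan -> thresholding -> XWAS -> colocalization -> MR -> triple-
evidence integration, and prints the evidence table.
"""

from ancestryqtl import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, out_dir="scratch/example_pipeline")
res = run_pipeline(cfg)

print(f"study-wide threshold: {res['threshold'].study_wide:.3g} "
      f"({res['n_components']} independent components)")
print(f"significant QTLs: {len(res['sig'])}  "
      f"sentinels: {len(res['sentinels'])}\n")

ev = res["evidence"].copy()
ev["intact_pp"] = ev["intact_pp"].map(lambda v: f"{v:.3f}")
print("evidence table (XWAS Bonferroni, coloc PP.H4 > 0.8, MR FDR < 0.05):")
print(ev.to_string(index=False))

nominated = res["evidence"]
nominated = nominated[nominated["nominated"]]["feature"].tolist()
planted = res["cohort"]["effector_features"]
print(f"\nnominated effectors: {nominated}")
print(f"planted effectors:   {planted}")
print("\nExactly the three proteins whose causal variants were planted on "
      "the disease liability pass all three evidence layers; the seven "
      "decoys fail XWAS, colocalization and MR despite strong QTLs.")
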