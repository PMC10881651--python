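"""Simulate a one-plate screen and score it end to end (no imaging).

Generates a 64-chip plate (8 vehicle, 4 Sunitinib-like, 4 unstimulated
controls, 24 compounds in duplicate), scores every chip's sprouting
distance D10 against the plate's vehicle controls with robust Z*, and
calls hits through the three-gate duplicate-agreement criteria.
"""

from sproutscreen import RunConfig, run_screen

cfg = RunConfig(seed=1, n_plates=1, n_compounds=24, use_imaging=False)
result = run_screen(cfg)

veh = result.chip_scores.query("role == 'vehicle'")
print(f"vehicle chips: median D10 = {veh['D10_um'].median():.1f} um "
      f"(calibration target 352.1 um)")

print("\nverdicts (partition the 24-compound library):")
print(result.screen_summary.query("category == 'verdict'").to_string(index=False))

hits = result.compound_calls.query("verdict == 'hit'")
print(f"\n{len(hits)} hit(s); per-replicate Z* of each hit:")
print(hits[["compound_id", "z_star_rep1", "z_star_rep2"]].to_string(index=False))
print("\nA hit required both replicate chips to pass QC >= 3, integrity >= 3 "
      "and Z* < -3.")
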