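"""Summarise hit compounds by their main-pathway combinations.

Runs a 4-plate, 96-compound screen, takes the hit list, and counts the
unique canonical pathway combinations among hits next to their mean Z*.
"""

from sproutscreen import RunConfig, run_screen
from sproutscreen.pathways import multi_hit_combinations

cfg = RunConfig(seed=2, n_plates=4, n_compounds=96, use_imaging=False)
result = run_screen(cfg)

print(f"hits: {(result.compound_calls['verdict'] == 'hit').sum()} "
      f"of {cfg.n_compounds} compounds")
print("\nunique pathway combinations among hits (frequency, mean Z*):")
print(result.pathway_combinations.to_string(index=False))
print("\nper-pathway membership (overlapping counts):")
print(result.pathway_membership.to_string(index=False))
print("\nCombinations shared by multiple hits point at pathways whose "
      "inhibition reproducibly blocks sprouting.")
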