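"""How the 11 features separate artifacted from clean contraction windows.

Generates a balanced set of labeled 60 s windows (contraction bursts vs
motion artifacts on a pink-noise EHG baseline), extracts the full feature
vector of each, and prints the per-class medians.  Artifacts push spectral
energy above 1 Hz (E3), sharpen amplitude excursions (RA, kappa, MD_bs,
MD_x) and break time symmetry (Tr_z); overlap is expected for the rest.
"""

from ehgkit import FEATURE_NAMES
from ehgkit.pipeline import simulate_feature_table

table = simulate_feature_table(20, 20, seed=11, n_surrogates=50)
medians = table.groupby("label")[list(FEATURE_NAMES)].median().T
medians.columns.name = None
print("per-class feature medians (20 windows each):\n")
print(medians.round(3).to_string())
print("\nDiscriminative features (higher when artifacted): "
      "E3, RA, kappa, MD_bs, MD_x, Tr_z.")
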