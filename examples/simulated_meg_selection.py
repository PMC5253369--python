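"""Interpretability-aware model selection on simulated evoked MEG.

Runs out-of-bag model selection (reduced scale: 24 channels, 60 epochs per
class, m = 20) over a lambda grid, comparing the exact interpretability
(vs the known ground-truth map) with its cERF-based approximation, and
prints the selected regularization strength under the zeta criterion.
"""

import decodemap as dm

sim = dm.simulate_meg(dm.MegSimConfig(epochs_per_class=60, n_channels=24,
                                      seed=9))
table = dm.select_model(
    sim.dataset, [1.0, 10.0, 25.0, 50.0, 100.0, 250.0], m=20, seed=10,
    true_map=sim.true_map, fit_full=False,
)

df = table.to_dataframe()
print(df[["lambda", "delta", "bias", "variance", "eta_tilde", "eta_true",
          "zeta", "degenerate_count"]].round(4).to_string(index=False))
print(f"\nzeta-chosen lambda: {table.chosen_lambda:g}")
valid = df.dropna(subset=["eta_tilde"])
print(f"eta_tilde-argmax:   {valid.loc[valid.eta_tilde.idxmax(), 'lambda']:g}")
print(f"eta_true-argmax:    {valid.loc[valid.eta_true.idxmax(), 'lambda']:g}")
print(
    "\neta_tilde (cERF reference) overestimates eta_true (ground-truth "
    "reference) but ranks the lambda values similarly, so it is a usable "
    "stand-in when the true map is unknown; degenerate_count tracks "
    "fully-shrunk replicate fits at strong regularization."
)
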