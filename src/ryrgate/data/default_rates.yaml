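# Default rate constants of the RyR2 / FK-binding-protein gating model.
# Units: association rates (k1, k3) in per-uM per-s; all other rates in per-s;
# alpha is the dimensionless spontaneous background-activity constant.
k1: 29.0          # FKBP12 association
k_m1: 6.11e-6     # FKBP12 dissociation (very slow: minutes-to-hours residence)
k2: 0.03          # RyR2_12 -> RyR2_12* conformational activation
k_m2: 0.18        # RyR2_12* -> RyR2_12 deactivation
k3: 3.3e5         # FKBP12.6 association (diffusion-limited scale)
k_m3: 4.2e-4      # FKBP12.6 dissociation
k4: 0.001         # RyR2_12.6 -> RyR2_12.6* conformational activation (near-zero efficacy)
k_m4: 0.25        # RyR2_12.6* -> RyR2_12.6 deactivation
kC: 480.0         # channel closing rate
alpha: 0.005      # spontaneous background open probability
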