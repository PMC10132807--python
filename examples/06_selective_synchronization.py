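"""Selectivity: correlated axons synchronize, independent axons do not.

One chain myelinates twenty axons: ten carry a shared (time-locked) 5 Hz
Poisson train, ten carry fully independent trains.  Both groups drive the
same global signal, yet only the correlated group's within-group arrival
spread collapses — the chain leaves independent traffic untouched, which
is the property that makes this plasticity rule safe in mixed tracts.
"""

import ompsim as om

config = om.RunConfig(
    signal=(
        om.SignalSpec(tau_s=200.0, sigma_j=1.0, group_id=0,
                      correlation=om.Correlation.time_locked, duration=1.0),
        om.SignalSpec(tau_s=200.0, sigma_j=1.0, group_id=1,
                      correlation=om.Correlation.independent, duration=1.0),
    ),
    kernel=om.ResponseParams(tau_G=30.0),
    plasticity=om.OMPParams(lambda_M=0.02, lambda_A=0.1, lambda_H=1e-6),
    chain=om.ChainConfig(n_segments=5, n_axons=20),
    experiment=om.ExperimentConfig(T_exp=6e5, n_e=40, sigma_D=5.0),
    axon_groups=[0] * 10 + [1] * 10,
)

prof = om.run_trial(config, seed=31)
for g, label in [(0, "correlated "), (1, "independent")]:
    s0 = prof.group_sigma0[g]
    s_end = prof.group_sigma[g][-1]
    print(f"{label} group: sigma_tau {s0:.2f} -> {s_end:.2f} ms "
          f"({s_end / s0:.2f}x initial)")
print("the correlated group synchronizes; the independent group's spread "
      "stays within noise of its starting value.")
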