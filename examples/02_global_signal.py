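"""The oligodendrocyte's global spike response G(t).

Shows the spike-response kernel's closed-form peak, verifies that the
event-driven state propagation reproduces the superposition of kernels
over a random spike train, and checks the mean-field prediction that the
long-run average of G equals the total spike rate N_A/tau_s (the kernel
integrates to 1, so only the rate matters).
"""

import numpy as np

import ompsim as om
from ompsim.global_signal import simulate_global

kern = om.ResponseParams(tau_G=10.0)
t_max, r_max = om.kernel_peak(kern)
print(f"kernel peak: t_max = {t_max:.3f} ms (tau_G ln2 = {10*np.log(2):.3f}), "
      f"R(t_max) = {r_max:.4f} /ms (1/(2 tau_G) = 0.0500)")

rng = np.random.default_rng(0)
spikes = np.sort(rng.uniform(0, 500, 100))
queries = np.linspace(0, 600, 200)
sim = simulate_global(spikes, kern, queries)
oracle = om.analytic_G(spikes, queries, kern)
print(f"event-driven vs superposition: max |diff| = "
      f"{np.abs(sim - oracle).max():.2e} (exact propagation)")

# mean-field: 10 Poisson axons at 10 Hz -> <G> = 10/100 = 0.1 /ms
spec = om.SignalSpec(tau_s=100.0, correlation=om.Correlation.independent,
                     duration=1e5)
sched = om.generate_bundle({0: spec}, [0] * 10,
                           om.FixedDelays(D=np.zeros(10), sigma_D=0.0), seed=3)
g = simulate_global(np.concatenate(sched.trains), kern,
                    np.arange(1e3, 1e5, 10.0))
print(f"time-averaged G: {g.mean():.4f} /ms (theory N_A/tau_s = 0.1000)")
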