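"""Predict muscle activations by static optimization and factorize them.

Solves min sum(a_i^2) under joint-moment equilibrium for every frame of
a two-joint (elevation, internal rotation) task actuated by a 15-muscle
Hill-type shoulder set, then checks that three synergies explain the
predicted activation patterns.
"""

import numpy as np

from musclesyn import (
    default_muscle_params,
    default_toy_task,
    global_vaf,
    nmf_decompose,
    reconstruct,
    simulate_model_activations,
)

params = default_muscle_params()
task = default_toy_task(n_time=101)
m = simulate_model_activations(task, params)

print(f"activation matrix: {m.values.shape}, peak activation {m.values.max():.3f}")
for t_pct in (20, 50, 80):
    top = np.argsort(m.values[:, t_pct])[-3:][::-1]
    names = ", ".join(params[i].name for i in top)
    print(f"  {t_pct}% cycle: most active {names}")

s = nmf_decompose(m, 3, n_restarts=50, seed=0)
print(f"global VAF at k=3: {global_vaf(m, reconstruct(s)):.4f}")

# Early frames recruit the trapezius group (elevation demand), mid-cycle
# the pectoralis/anterior-deltoid internal rotators, late frames the
# posterior external rotators — so the optimizer's output is itself
# low-dimensional, and three synergies reconstruct it almost exactly.
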