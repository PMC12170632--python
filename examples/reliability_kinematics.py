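"""Inter-trial reliability of kinematic variables: CV, ICC(3,1), SEM.

Generates per-trial shoulder/elbow/scapular angles for 20 subjects x 5
trials from a between/within-subject variance model and summarizes
movement consistency against the conventional thresholds (CV < 10%,
ICC > 0.80).
"""

from musclesyn import SynthConfig, reliability_report
from musclesyn.synth import generate_kinematic_trials

config = SynthConfig(seed=42)
kinematics = generate_kinematic_trials(config)
report = reliability_report(kinematics)

print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# Each variable's ICC matches its design value (0.92 / 0.89 / 0.85) up to
# sampling noise, the CVs are a few percent, and all three variables pass
# the acceptability thresholds — the regime in which synergy analysis
# across trials is trustworthy.
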