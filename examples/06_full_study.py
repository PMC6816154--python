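"""Run a small synthetic paired-protocol study end to end.

A cohort of phantoms is scanned with both arms (fully sampled reference
vs Poisson-disc R=5 + CS reconstruction), measured identically, and the
per-metric agreement table is printed — the synthetic analogue of a
scanner-vs-scanner method-comparison study.  Use cohort_size=20 for the
full experiment; 6 keeps this demo quick.
"""

from aortacs import ExperimentConfig, run_experiment

config = ExperimentConfig(cohort_size=6, master_seed=0, save_volumes=False)
report = run_experiment(config)

print(report.agreement_table().round(3).to_string(index=False))
print(f"ILT-type kappa: {report.kappa_ilt:.2f}")
print(f"failed phantoms: {len(report.failed)}")
# Diameter/area ICCs near 1 with biases well under a voxel show the
# accelerated arm reproduces the reference readout; sharpness is the most
# sensitive metric to the sparse reconstruction's smoothing.
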