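"""A miniature end-to-end adaptive fine-tuning run.

Pre-trains a plain backbone on a source phantom cohort, transfers it as
the frozen/fine-tuned pair, trains the routed network with its agent per
CV fold on a target cohort, and evaluates the fold ensemble on the
held-out common test set with the stochastic-policy protocol (mean
probability over repeated hard policies at seed 42).

Runs the canonical reduced protocol (60 patients, 32³ phantoms
preprocessed to 14³, 4-block backbone, 20 epochs, 5 folds); takes a few
minutes on one CPU.
"""

from spottune3d.experiments import (ReducedExperimentConfig,
                                    run_reduced_experiment)

result = run_reduced_experiment(seed=1, cfg=ReducedExperimentConfig())

print(f"held-out AUC: {result.auc:.3f}")
print(f"held-out AP:  {result.ap:.3f}")
print(f"SEN {result.sen:.3f} / SPE {result.spe:.3f}  "
      f"(selection score M = {result.m})")
print()
print("AUC well above 0.5 shows the routed transfer network recovers the")
print("class signal planted in the enhancing rim of the phantom tumors.")
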