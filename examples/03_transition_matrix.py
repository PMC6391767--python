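"""Estimate next-contact transition likelihoods from journeys.

Each patient's contact-type sequence is treated as a Markov chain; the
estimated row-stochastic matrix gives the likelihood of the next contact
type conditional on the previous one.  On synthetic data the estimate
can be compared against the generating matrix.
"""

from patient_journeys import (
    build_all,
    default_sim_config,
    generate_cohort,
    transition_matrices,
)

cfg = default_sim_config(seed=42)
collection, _ = generate_cohort(cfg)
mats = transition_matrices(build_all(collection))

print("Pooled (AP) next-contact likelihoods (%):")
print((mats["AP"].probs * 100).round(2), "\n")
print(f"based on {mats['AP'].n_transitions} observed transitions\n")

print("FO estimated vs configured (%):")
print((mats["FO"].probs * 100).round(2))
print((cfg.transition_frame("FO") * 100).round(2))
# Rows are previous contact type, columns next type.  After an
# emergency presentation the next contact is almost always an
# admission; estimates track the configured matrix to within sampling
# error of the per-row transition counts.
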