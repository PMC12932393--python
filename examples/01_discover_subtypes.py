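"""Discover and replicate methylation subtypes on a synthetic three-cohort study.

Generates the standard synthetic study (two planted LOAD subtypes shared by
all cohorts plus one cohort-specific cluster), runs residualization,
variable-probe filtering, dual clustering, median-profile block matching and
convex-hull latent-space replication, and prints the confirmed subtypes and
how well the calls recover the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

from methsub.pipeline import run_discovery_replication
from methsub.simulate import SimulationConfig, generate_methylation_cohorts

study = generate_methylation_cohorts(SimulationConfig(seed=1))
result = run_discovery_replication(study.beta_by_cohort, study.annotations,
                                   seed=1)

print("chosen k per cohort:",
      {c: sel.chosen_k for c, sel in result.k_selection.items()})
print("correlation blocks:", result.blocks)
print("confirmed subtypes:", result.n_confirmed)

truth = study.truth_labels
calls = result.calls_frame().set_index("sample_id")
load = calls[calls["call"] != "Control"]
ari = adjusted_rand_score(truth.loc[load.index], load["call"])
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
cs = truth.index[truth == "CohortSpecific"]
print("cohort-specific cluster called Unassigned:",
      f"{(calls.loc[cs, 'call'] == 'Unassigned').mean():.0%}")

# Two confirmed subtypes with ARI near 1 mean both planted subtypes were
# found in every cohort and validated at probe and sample level by both
# clustering methods, while the cluster unique to cohort 1 was (correctly)
# not promoted to a subtype.
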