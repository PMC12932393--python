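"""Subtype EWAS with bacon correction, meta-analysis and overlap enrichment.

For each cohort, regresses every CpG on the LOAD-S1-vs-control contrast with
covariate and surrogate-variable adjustment, corrects the per-cohort
statistics for bias and inflation, pools cohorts by inverse-variance
meta-analysis with Bonferroni DMP calling, and tests whether the DMPs
recover the planted S1 signature by a Fisher overlap test.
"""

import pandas as pd

from methsub.enrichment import fisher_overlap
from methsub.ewas import bacon_correct, estimate_svs, meta_analyze, run_ewas
from methsub.simulate import SimulationConfig, generate_methylation_cohorts

cfg = SimulationConfig(seed=3, n_cpgs=2000)
study = generate_methylation_cohorts(cfg)
ann = study.annotations.set_index("sample_id")

tables = []
for cohort, bm in study.beta_by_cohort.items():
    samples = [s for s in bm.sample_ids
               if ann.loc[s, "truth"] in ("Control", "LOAD-S1")]
    y = (ann.loc[samples, "truth"] == "LOAD-S1").astype(float).to_numpy()
    cov = ann.loc[samples, ["age", "sex", "prop_neuron", "batch"]]
    beta = bm.values[samples]
    sv = estimate_svs(beta, y, cov, seed=cfg.seed)
    res = run_ewas(beta, y, cov, sv, cohort=cohort)
    fit = bacon_correct(res.table["estimate"], res.table["se"])
    corrected = pd.DataFrame({"estimate": fit.estimates_corrected,
                              "se": fit.ses_corrected}, index=res.table.index)
    print(f"{cohort}: {res.n_surrogates} surrogate(s), "
          f"bias {fit.bias:+.3f}, inflation {fit.inflation:.3f}")
    tables.append(corrected)

meta = meta_analyze(tables)
dmps = set(meta.index[meta["dmp"]])
print(f"Bonferroni DMPs: {len(dmps)} of {len(meta)} CpGs tested")

signature = set(study.truth_registry["S1"]) | set(study.truth_registry["sharedLOAD"])
orr, p, table = fisher_overlap(dmps, signature & set(meta.index), meta.index)
print(f"overlap with planted S1/shared signature: {table.both} CpGs, "
      f"OR {orr:.1f}, p {p:.2e}")
# A large odds ratio with tiny p confirms the meta-analysis recovers the
# planted differential methylation rather than noise.
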