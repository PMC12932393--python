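"""Synthetic multi-cohort study generator.

Emulates the statistical structure of a three-cohort postmortem-brain
methylation study of late-onset Alzheimer's disease (LOAD): two planted
methylation subtypes (LOAD-S1, LOAD-S2) with disjoint CpG signatures shared
across cohorts, one cohort-specific cluster confined to the first cohort,
covariate and batch structure, an EPIC-vs-450K platform probe mask on the
last cohort, negative-binomial bulk expression with planted subtype DEGs and
CpG-linked genes, multinomial microglial-state cell counts with
state-specific marker shifts, and bounded morphology proportions.

All randomness flows from one root seed through named per-component streams,
so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ._utils import SeedStream, expit, logit
from .containers import BetaMatrix, StatePseudobulk

GROUP_CONTROL = "Control"
GROUP_S1 = "LOAD-S1"
GROUP_S2 = "LOAD-S2"
GROUP_COHORT = "CohortSpecific"

_SIGNATURES = ("S1", "S2", "sharedLOAD", "cohortSpecific", "NFT-like")


def _default_samples() -> dict[str, int]:
    return {GROUP_CONTROL: 50, GROUP_S1: 50, GROUP_S2: 50, GROUP_COHORT: 30}


def _default_signatures() -> dict[str, int]:
    return {"S1": 200, "S2": 200, "sharedLOAD": 100, "cohortSpecific": 150, "NFT-like": 150}


def _default_effects() -> dict[str, float]:
    return {"S1": 1.5, "S2": 1.5, "sharedLOAD": 0.7, "cohortSpecific": 1.0, "NFT-like": 0.7}


def _default_covariates() -> dict[str, float]:
    return {"age": 0.015, "sex": 0.15, "prop_neuron": 0.5, "batch": 0.2}


def _default_expression() -> dict[str, Any]:
    return {"n_genes": 2000, "dispersion": 0.1, "n_degs": 100, "fold_change": 2.0,
            "n_linked_pairs": 50, "link_slope": 6.0}


def _default_microglia() -> dict[str, Any]:
    return {"n_states": 6, "markers_per_state": 20, "n_genes": 600,
            "state_shift": {("MG2", GROUP_S1): 1.0},
            "cell_count_range": (500, 3000), "samples_per_group": 15,
            "rare_state_group": GROUP_S2}


def _default_morphology() -> dict[str, Any]:
    return {
        "regions": ["ITG", "MTG", "VMC", "DLC", "HIP"],
        "group_stats": {GROUP_S1: (0.35, 0.020), GROUP_S2: (0.30, 0.005),
                        "Unassigned": (0.30, 0.010), "AsymAD": (0.25, 0.010)},
        "n_donors": 12,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults define the standard run."""

    seed: int = 0
    n_cohorts: int = 3
    samples_per_group: dict[str, int] = field(default_factory=_default_samples)
    n_cpgs: int = 5000
    signature_sizes: dict[str, int] = field(default_factory=_default_signatures)
    effect_logit: dict[str, float] = field(default_factory=_default_effects)
    covariate_effects: dict[str, float] = field(default_factory=_default_covariates)
    noise_sd: float = 0.5
    nonvariant_fraction: float = 0.4  # near-constant probes, tiny noise
    nonvariant_noise_sd: float = 0.05
    # within-cluster heterogeneity: per-sample severity of the subtype effect
    # and shared low-rank latent variation (unmodeled biology)
    severity_sd: float = 0.2
    n_latent: int = 3
    latent_sd: float = 0.1
    # subclinical variation along each signature axis, present in everyone
    background_signature_sd: float = 0.25
    platform_mask_fraction: float = 0.6
    expression: dict[str, Any] = field(default_factory=_default_expression)
    microglia: dict[str, Any] = field(default_factory=_default_microglia)
    morphology: dict[str, Any] = field(default_factory=_default_morphology)

    def __post_init__(self):
        if self.n_cohorts < 1 or self.n_cpgs < 1:
            raise ValueError("counts must be positive")
        if any(c < 0 for c in self.samples_per_group.values()):
            raise ValueError("sample counts must be non-negative")
        for k in _SIGNATURES:
            self.signature_sizes.setdefault(k, 0)
            self.effect_logit.setdefault(k, 0.0)
        if sum(self.signature_sizes.values()) > self.n_cpgs:
            raise ValueError(
                f"signature sizes sum to {sum(self.signature_sizes.values())} "
                f"which exceeds n_cpgs={self.n_cpgs}")
        if not all(np.isfinite(v) for v in self.effect_logit.values()):
            raise ValueError("effect magnitudes must be finite")
        if not (0 < self.platform_mask_fraction <= 1):
            raise ValueError("platform_mask_fraction must be in (0, 1]")


@dataclass
class SyntheticStudy:
    """One realization of the synthetic multi-cohort study."""

    config: SimulationConfig
    beta_by_cohort: dict[str, BetaMatrix]
    annotations: pd.DataFrame  # sample_id, cohort, diagnosis, truth, covariates
    truth_registry: dict[str, Any]
    expression_by_cohort: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_annotation: pd.DataFrame | None = None
    microglia: list[StatePseudobulk] = field(default_factory=list)
    microglia_cell_counts: pd.DataFrame | None = None
    morphology: pd.DataFrame | None = None

    @property
    def truth_labels(self) -> pd.Series:
        """Planted subtype per LOAD sample (indexed by sample id)."""
        load = self.annotations[self.annotations["diagnosis"] == "LOAD"]
        return load.set_index("sample_id")["truth"]


def _cohort_names(n: int) -> list[str]:
    return [f"cohort{i + 1}" for i in range(n)]


def generate_methylation_cohorts(config: SimulationConfig) -> SyntheticStudy:
    """Generate per-cohort beta matrices with planted subtype structure.

    logit(beta) = per-CpG baseline + covariate terms + batch term
                + subtype effect on the planted signature CpGs + Gaussian noise,
    mapped back through the inverse logit.  Cohort 1 carries an extra
    cohort-specific cluster; the last cohort exposes only a 450K-like probe
    subset (a strict subset of the full panel with at least half of every
    signature retained).
    """
    stream = SeedStream(config.seed)
    rng = stream.child("methylation")

    n_cpgs = config.n_cpgs
    probe_ids = np.array([f"cg{i:07d}" for i in range(n_cpgs)])
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n_cpgs)])
    pos = (np.arange(n_cpgs) // 22 + 1) * 5000 + rng.integers(0, 2000, n_cpgs)
    coords = pd.DataFrame({"chrom": chroms, "pos": pos}, index=probe_ids)

    # disjoint signature CpG sets
    shuffled = rng.permutation(n_cpgs)
    registry: dict[str, Any] = {}
    start = 0
    for name in _SIGNATURES:
        size = config.signature_sizes[name]
        registry[name] = probe_ids[np.sort(shuffled[start:start + size])]
        start += size

    baseline = rng.normal(0.0, 1.2, n_cpgs)
    # near-constant probes emulate the non-variant tail removed by spread filtering
    noise_scale = np.full(n_cpgs, config.noise_sd)
    nonsig = shuffled[start:]
    n_nonvar = int(round(config.nonvariant_fraction * len(nonsig)))
    noise_scale[nonsig[:n_nonvar]] = config.nonvariant_noise_sd

    sign = {name: rng.choice([-1.0, 1.0], size=len(registry[name]))
            for name in _SIGNATURES}
    cov_coef = {name: rng.normal(0.0, scale, n_cpgs)
                for name, scale in config.covariate_effects.items()}
    # latent loadings shared across cohorts (same unmodeled biology everywhere)
    latent_loadings = rng.normal(0.0, config.latent_sd, (config.n_latent, n_cpgs))

    idx_of = {p: i for i, p in enumerate(probe_ids)}
    sig_idx = {name: np.array([idx_of[p] for p in registry[name]], dtype=int)
               for name in _SIGNATURES}

    cohorts = _cohort_names(config.n_cohorts)
    beta_by_cohort: dict[str, BetaMatrix] = {}
    ann_rows = []
    truth_rows = []

    # 450K-like mask on the last cohort
    mask_size = int(round(config.platform_mask_fraction * n_cpgs))
    mask = np.zeros(n_cpgs, dtype=bool)
    mask[rng.choice(n_cpgs, size=mask_size, replace=False)] = True
    for name in _SIGNATURES:
        idx = sig_idx[name]
        if len(idx) == 0:
            continue
        need = int(np.ceil(0.5 * len(idx)))
        have = int(mask[idx].sum())
        if have < need:
            missing = idx[~mask[idx]]
            mask[rng.choice(missing, size=need - have, replace=False)] = True
    if mask.all() and config.platform_mask_fraction < 1:
        mask[rng.integers(0, n_cpgs)] = False

    for ci, cohort in enumerate(cohorts):
        crng = stream.child(f"methylation/{cohort}")
        groups = dict(config.samples_per_group)
        if ci != 0:
            groups.pop(GROUP_COHORT, None)
        sample_ids, truths = [], []
        for g, n in groups.items():
            for j in range(n):
                sample_ids.append(f"{cohort}_{g}_{j:03d}")
                truths.append(g)
        truths = np.array(truths)
        n_samp = len(sample_ids)

        age = crng.normal(75.0, 8.0, n_samp)
        sex = crng.integers(0, 2, n_samp).astype(float)
        prop_neuron = crng.beta(10, 10, n_samp)
        batch = crng.integers(0, 2, n_samp).astype(float)

        zero = np.zeros(n_cpgs)
        L = np.tile(baseline[:, None], (1, n_samp))
        L += cov_coef.get("age", zero)[:, None] * ((age - 75.0) / 8.0)[None, :]
        L += cov_coef.get("sex", zero)[:, None] * sex[None, :]
        L += cov_coef.get("prop_neuron", zero)[:, None] * ((prop_neuron - 0.5) * 2)[None, :]
        L += cov_coef.get("batch", zero)[:, None] * batch[None, :]

        is_load = truths != GROUP_CONTROL
        severity = np.maximum(crng.normal(1.0, config.severity_sd, n_samp), 0.0)
        effects = [("S1", truths == GROUP_S1),
                   ("S2", truths == GROUP_S2),
                   ("sharedLOAD", is_load),
                   ("NFT-like", is_load)]
        if ci == 0:
            effects.append(("cohortSpecific", truths == GROUP_COHORT))
        for name, members in effects:
            idx = sig_idx[name]
            if len(idx) == 0 or not members.any():
                continue
            shift = config.effect_logit[name] * sign[name]
            L[np.ix_(idx, members)] += shift[:, None] * severity[members][None, :]

        # everyone varies along each disease axis (subclinical gradient);
        # this is what makes signature CpGs pass variance filters in every cohort
        if config.background_signature_sd > 0:
            for name in _SIGNATURES:
                idx = sig_idx[name]
                if len(idx) == 0:
                    continue
                bg = crng.normal(0.0, config.background_signature_sd, n_samp)
                L[idx, :] += sign[name][:, None] * bg[None, :]

        if config.n_latent:
            latent_scores = crng.normal(0.0, 1.0, (config.n_latent, n_samp))
            L += latent_loadings.T @ latent_scores
        L += crng.normal(0.0, 1.0, L.shape) * noise_scale[:, None]
        beta = expit(L)

        keep = mask if ci == config.n_cohorts - 1 and config.n_cohorts > 1 else np.ones(n_cpgs, bool)
        platform = "450K" if not keep.all() else "EPIC"
        values = pd.DataFrame(beta[keep], index=probe_ids[keep], columns=sample_ids)
        tags = pd.Series(platform, index=probe_ids[keep])
        beta_by_cohort[cohort] = BetaMatrix(values, coords.loc[probe_ids[keep]], tags)

        for sid, t, a, s, pn, b in zip(sample_ids, truths, age, sex, prop_neuron, batch):
            ann_rows.append({
                "sample_id": sid, "cohort": cohort,
                "diagnosis": "Control" if t == GROUP_CONTROL else "LOAD",
                "truth": t, "age": a, "sex": s, "prop_neuron": pn, "batch": b,
            })
            if t != GROUP_CONTROL:
                truth_rows.append((sid, t))

    annotations = pd.DataFrame(ann_rows)
    registry["seed_log"] = list(stream.log)
    return SyntheticStudy(config=config, beta_by_cohort=beta_by_cohort,
                          annotations=annotations, truth_registry=registry)


def generate_expression(study: SyntheticStudy,
                        config: SimulationConfig | None = None) -> SyntheticStudy:
    """Add negative-binomial gene counts per cohort to a generated study.

    Planted DEGs shift the mean by the configured fold change in one subtype;
    linked CpG-gene pairs couple a gene's log-mean to the sample's beta at a
    planted S2 CpG, giving a monotone methylation-expression relation in
    LOAD-S2 samples.
    """
    config = config or study.config
    ex = config.expression
    n_genes = ex["n_genes"]
    s2_cpgs = study.truth_registry["S2"]
    if ex["n_linked_pairs"] > min(n_genes, len(s2_cpgs)):
        raise ValueError("n_linked_pairs exceeds min(n_genes, planted S2 CpGs)")

    stream = SeedStream(config.seed)
    stream.child("methylation")  # keep stream positions aligned with generation order
    rng = stream.child("expression")

    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    base = rng.normal(np.log(200.0), 1.0, n_genes)
    disp = ex["dispersion"]

    n_degs = ex["n_degs"]
    order = rng.permutation(n_genes)
    deg_s1 = gene_ids[np.sort(order[:n_degs])]
    deg_s2 = gene_ids[np.sort(order[n_degs:2 * n_degs])]
    linked_genes = gene_ids[np.sort(order[2 * n_degs:2 * n_degs + ex["n_linked_pairs"]])]
    linked_cpgs = rng.choice(s2_cpgs, size=ex["n_linked_pairs"], replace=False)
    deg_sign = {g: s for g, s in zip(
        np.concatenate([deg_s1, deg_s2]),
        rng.choice([-1.0, 1.0], size=2 * n_degs))}

    # gene annotation: linked genes get a TSS within 10 kb of their CpG
    first_beta = next(iter(study.beta_by_cohort.values()))
    coords = first_beta.probe_coords
    all_coords = None
    for bm in study.beta_by_cohort.values():
        if all_coords is None or len(bm.probe_coords) > len(all_coords):
            all_coords = bm.probe_coords
    tss = rng.integers(10 ** 6, 10 ** 8, n_genes)
    chrom = rng.choice([f"chr{c}" for c in range(1, 23)], size=n_genes)
    gene_ann = pd.DataFrame({"chrom": chrom, "tss": tss}, index=gene_ids)
    for g, c in zip(linked_genes, linked_cpgs):
        row = all_coords.loc[c]
        gene_ann.loc[g, "chrom"] = row["chrom"]
        gene_ann.loc[g, "tss"] = row["pos"] + int(rng.integers(-8000, 8000))

    idx_of = {g: i for i, g in enumerate(gene_ids)}
    log_fc = np.log(ex["fold_change"])
    slope = ex.get("link_slope", 6.0)

    for cohort, bm in study.beta_by_cohort.items():
        crng = stream.child(f"expression/{cohort}")
        ann = study.annotations[study.annotations["cohort"] == cohort]
        sample_ids = list(ann["sample_id"])
        truths = ann.set_index("sample_id")["truth"]
        n_samp = len(sample_ids)
        libfac = crng.lognormal(0.0, 0.3, n_samp)

        logmu = np.tile(base[:, None], (1, n_samp)) + np.log(libfac)[None, :]
        for genes, grp in ((deg_s1, GROUP_S1), (deg_s2, GROUP_S2)):
            members = (truths.loc[sample_ids] == grp).to_numpy()
            gi = np.array([idx_of[g] for g in genes])
            signs = np.array([deg_sign[g] for g in genes])
            logmu[np.ix_(gi, members)] += (log_fc * signs)[:, None]
        s2_members = (truths.loc[sample_ids] == GROUP_S2).to_numpy()
        if s2_members.any():
            for g, c in zip(linked_genes, linked_cpgs):
                if c not in bm.values.index:
                    continue
                bvals = bm.values.loc[c, np.array(sample_ids)[s2_members]].to_numpy()
                logmu[idx_of[g], s2_members] += slope * (bvals - bvals.mean())

        mu = np.exp(logmu)
        if disp > 0:
            counts = crng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))
        else:
            counts = crng.poisson(mu)
        study.expression_by_cohort[cohort] = pd.DataFrame(
            counts, index=gene_ids, columns=sample_ids)

    study.gene_annotation = gene_ann
    study.truth_registry.update({
        "deg_S1": deg_s1, "deg_S2": deg_s2,
        "linked_pairs": list(zip(linked_cpgs, linked_genes)),
    })
    return study


def generate_microglia(config: SimulationConfig) -> tuple[list[StatePseudobulk], pd.DataFrame]:
    """Generate per-state pseudobulk expression and a cell-count table.

    Per-sample state cell counts are multinomial; pseudobulk counts are
    log-normal with a +2 log2 marker elevation in each state's own markers;
    configured (state, group) shifts raise that state's marker expression in
    the given subtype.  One state is made rare in one group (< 100 cells in
    total) to exercise the downstream exclusion rule.
    """
    mg = config.microglia
    n_states, mpstate = mg["n_states"], mg["markers_per_state"]
    if n_states < 2:
        raise ValueError("need at least 2 microglial states")
    n_genes = mg["n_genes"]
    if n_states * mpstate > n_genes:
        raise ValueError("marker sets exceed gene count (would overlap)")

    stream = SeedStream(config.seed)
    rng = stream.child("microglia")
    states = [f"MG{i + 1}" for i in range(n_states)]
    gene_ids = [f"mg_g{i:04d}" for i in range(n_genes)]
    markers = {s: gene_ids[i * mpstate:(i + 1) * mpstate] for i, s in enumerate(states)}

    groups = [GROUP_CONTROL, GROUP_S1, GROUP_S2]
    nper = mg["samples_per_group"]
    sample_ids = [f"sn_{g}_{j:02d}" for g in groups for j in range(nper)]
    group_of = pd.Series([g for g in groups for _ in range(nper)], index=sample_ids)

    base_prob = rng.dirichlet(np.full(n_states, 8.0))
    lo, hi = mg["cell_count_range"]
    rare_state, rare_group = states[-1], mg["rare_state_group"]

    count_rows = {}
    for sid in sample_ids:
        total = int(rng.integers(lo, hi + 1))
        p = base_prob.copy()
        if group_of[sid] == rare_group:
            p[-1] = 0.002
        p = p / p.sum()
        count_rows[sid] = rng.multinomial(total, p)
    cell_counts = pd.DataFrame(count_rows, index=states).T  # samples x states

    base = rng.normal(5.0, 1.0, n_genes)
    shift_map = {(s, g): v for (s, g), v in mg["state_shift"].items()}

    pseudobulks = []
    for si, state in enumerate(states):
        srng = stream.child(f"microglia/{state}")
        logmean = base.copy()
        mi = np.array([gene_ids.index(g) for g in markers[state]])
        logmean[mi] += 2.0
        mat = np.empty((n_genes, len(sample_ids)))
        for j, sid in enumerate(sample_ids):
            lm = logmean.copy()
            delta = shift_map.get((state, group_of[sid]), 0.0)
            if delta:
                lm[mi] += delta
            size_term = np.log2(max(cell_counts.loc[sid, state], 1))
            mat[:, j] = np.rint(2.0 ** (lm + size_term - np.log2(1000)
                                        + srng.normal(0, 0.3, n_genes)) * 50)
        counts = pd.DataFrame(np.maximum(mat, 0), index=gene_ids, columns=sample_ids)
        pseudobulks.append(StatePseudobulk(
            state=state, counts=counts,
            cell_counts=cell_counts[state].copy(),
            groups=group_of.copy(), marker_genes=list(markers[state])))
    return pseudobulks, cell_counts


def generate_morphology(config: SimulationConfig) -> pd.DataFrame:
    """Per-donor per-region proportions of activated microglia (PAM).

    PAM is drawn from a Beta distribution matched to each group's configured
    mean and variance, so draws are bounded in [0, 1] and group-specific
    spread (e.g. a wider LOAD-S1 distribution) is honored.
    """
    mo = config.morphology
    regions = mo["regions"]
    if not regions:
        raise ValueError("regions must be non-empty")
    stream = SeedStream(config.seed)
    rng = stream.child("morphology")
    rows = []
    for group, (mean, var) in mo["group_stats"].items():
        var = min(var, 0.95 * mean * (1 - mean))
        nu = mean * (1 - mean) / var - 1.0
        a, b = mean * nu, (1 - mean) * nu
        for d in range(mo["n_donors"]):
            donor = f"{group}_d{d:02d}"
            for region in regions:
                pam = float(rng.beta(a, b))
                stage3 = float(rng.lognormal(np.log(20 * mean), 0.4))
                rows.append({"donor": donor, "group": group, "region": region,
                             "pam": pam, "stage3_density": stage3})
    return pd.DataFrame(rows)


def generate_study(config: SimulationConfig | None = None,
                   with_expression: bool = True,
                   with_microglia: bool = True,
                   with_morphology: bool = True) -> SyntheticStudy:
    """Full synthetic study: methylation plus requested downstream layers."""
    config = config or SimulationConfig()
    study = generate_methylation_cohorts(config)
    if with_expression:
        generate_expression(study, config)
    if with_microglia:
        study.microglia, study.microglia_cell_counts = generate_microglia(config)
    if with_morphology:
        study.morphology = generate_morphology(config)
    return study
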