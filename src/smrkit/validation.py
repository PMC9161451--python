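"""Replicate-based validation experiments: calibration, power, recovery.

These functions drive the synthetic-data generator through the SMR and
HEIDI statistics many times and summarize the operating characteristics
— the type-I error of SMR under the null architecture, HEIDI's false-
and true-positive rates under pleiotropy and linkage, the bias of the
ratio estimate, and the agreement of the summary-level estimate with
individual-level two-stage least squares.  They are the package's own
evidence that the statistics behave as advertised; the test suite and
the acceptance script both run them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .harmonize import HarmonizedSnp
from .heidi import heidi_test, select_heidi_snps
from .refpanel import ReferencePanel
from .simulate import (
    SimulatedStudy, SyntheticScenario, simulate_genotypes, simulate_panel,
    simulate_phenotypes, simulate_study, scenario_mafs, summarize_cohort,
)
from .smr import select_top_snp, smr_statistic_from_z2


def _harmonized_from_study(study: SimulatedStudy) -> list[HarmonizedSnp]:
    """Build the per-probe harmonized set directly from a simulated study.

    The generator emits all three sources on a common orientation, so
    harmonization reduces to bookkeeping; SNPs whose regression failed
    (monomorphic) are skipped.
    """
    out = []
    e, g = study.eqtl_summary, study.gwas_summary
    freq_ref = study.panel.genotypes.mean(axis=0) / 2.0
    for i, sid in enumerate(study.snp_ids):
        if e.monomorphic[i] or g.monomorphic[i]:
            continue
        a1, a2 = study.alleles[i]
        out.append(HarmonizedSnp(
            snp_id=sid, pos=int(study.positions[i]), a1=a1, a2=a2,
            b_gwas=float(g.beta[i]), se_gwas=float(g.se[i]), p_gwas=float(g.p[i]),
            b_eqtl=float(e.beta[i]), se_eqtl=float(e.se[i]), p_eqtl=float(e.p[i]),
            freq_gwas=float(g.freq[i]), freq_eqtl=float(e.freq[i]),
            freq_ref=float(freq_ref[i]),
        ))
    return out


@dataclass
class RejectionSummary:
    n_reps: int
    n_eligible: int       # replicates where the probe was testable
    n_rejected: int

    @property
    def rate(self) -> float:
        return self.n_rejected / self.n_eligible if self.n_eligible else float("nan")


def smr_rejection_rate(
    scenario: SyntheticScenario,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
) -> RejectionSummary:
    """Empirical SMR rejection rate at ``alpha`` over seeded replicates.

    Under the null architecture this is the type-I error of the SMR test
    (no multiplicity correction: a single probe per replicate).  Only the
    summary statistics are needed, so no panel is simulated.
    """
    rng = np.random.default_rng(seed)
    mafs = scenario_mafs(scenario)
    n_eligible = n_rejected = 0
    for _ in range(n_reps):
        g_e = simulate_genotypes(scenario.n_eqtl_cohort, scenario.n_snps,
                                 mafs, scenario.ld_rho, rng)
        g_g = simulate_genotypes(scenario.n_gwas_cohort, scenario.n_snps,
                                 mafs, scenario.ld_rho, rng)
        x, y = simulate_phenotypes(g_e, g_g, scenario, rng)
        e = summarize_cohort(g_e, x)
        g = summarize_cohort(g_g, y)
        top = int(np.nanargmin(e.p))
        if e.p[top] > 5e-8:
            continue
        n_eligible += 1
        z2_e = (e.beta[top] / e.se[top]) ** 2
        z2_g = (g.beta[top] / g.se[top]) ** 2
        _, p_smr = smr_statistic_from_z2(z2_e, z2_g)
        if p_smr < alpha:
            n_rejected += 1
    return RejectionSummary(n_reps=n_reps, n_eligible=n_eligible,
                            n_rejected=n_rejected)


def heidi_rejection_rate(
    scenario: SyntheticScenario,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    panel: Optional[ReferencePanel] = None,
) -> RejectionSummary:
    """Empirical HEIDI rejection rate at ``alpha`` over seeded replicates.

    Under pleiotropy (single shared causal variant) rejections are false
    positives and the rate estimates HEIDI's size; under linkage they are
    true positives and the rate estimates its power.  One reference panel
    is drawn up front and reused for all replicates, as a real analysis
    reuses a single panel.  Replicates where the probe is ineligible or
    the instrument set is below the minimum count are excluded from the
    denominator.
    """
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = simulate_panel(scenario, rng)
    n_eligible = n_rejected = 0
    for _ in range(n_reps):
        study = simulate_study(scenario, rng=rng, panel=panel)
        snps = _harmonized_from_study(study)
        top = select_top_snp(snps)
        if top is None:
            continue
        heidi_in = select_heidi_snps(snps, top, panel)
        res = heidi_test(heidi_in)
        if res.p_heidi is None:
            continue
        n_eligible += 1
        if res.p_heidi < alpha:
            n_rejected += 1
    return RejectionSummary(n_reps=n_reps, n_eligible=n_eligible,
                            n_rejected=n_rejected)


@dataclass
class RecoverySummary:
    n_reps: int
    n_eligible: int
    mean_b_smr: float
    sd_b_smr: float
    true_b_xy: float

    @property
    def relative_bias(self) -> float:
        return (self.mean_b_smr - self.true_b_xy) / self.true_b_xy


def parameter_recovery(
    scenario: SyntheticScenario,
    n_reps: int,
    seed: int,
) -> RecoverySummary:
    """Mean SMR ratio estimate across replicates vs the generative b_xy."""
    rng = np.random.default_rng(seed)
    mafs = scenario_mafs(scenario)
    estimates = []
    for _ in range(n_reps):
        g_e = simulate_genotypes(scenario.n_eqtl_cohort, scenario.n_snps,
                                 mafs, scenario.ld_rho, rng)
        g_g = simulate_genotypes(scenario.n_gwas_cohort, scenario.n_snps,
                                 mafs, scenario.ld_rho, rng)
        x, y = simulate_phenotypes(g_e, g_g, scenario, rng)
        e = summarize_cohort(g_e, x)
        g = summarize_cohort(g_g, y)
        top = int(np.nanargmin(e.p))
        if e.p[top] > 5e-8:
            continue
        estimates.append(g.beta[top] / e.beta[top])
    arr = np.asarray(estimates)
    return RecoverySummary(
        n_reps=n_reps, n_eligible=len(arr),
        mean_b_smr=float(arr.mean()), sd_b_smr=float(arr.std(ddof=1)),
        true_b_xy=scenario.b_xy,
    )


@dataclass
class TwoStageComparison:
    b_smr: float
    b_2sls: float

    @property
    def relative_difference(self) -> float:
        return abs(self.b_smr - self.b_2sls) / abs(self.b_2sls)


def two_stage_equivalence(
    seed: int,
    n_individuals: int = 4000,
    scenario: Optional[SyntheticScenario] = None,
) -> TwoStageComparison:
    """Summary-level b_SMR vs individual-level 2SLS on the SAME cohort.

    One cohort is measured for both expression and trait; the per-SNP
    summary statistics computed from it feed the ratio b_GWAS / b_eQTL,
    which is compared with the two-stage least-squares estimate
    cov(g, y) / cov(g, x) computed from the raw data.  With a single
    instrument the two are algebraically identical, so agreement is to
    numerical precision — a check that the summary pathway loses nothing.
    """
    scenario = scenario or SyntheticScenario(architecture="pleiotropy", seed=seed)
    rng = np.random.default_rng(seed)
    mafs = scenario_mafs(scenario)
    g = simulate_genotypes(n_individuals, scenario.n_snps, mafs,
                           scenario.ld_rho, rng)
    c1 = scenario.causal_index
    x = scenario.b_zx * g[:, c1] + rng.normal(0.0, scenario.sd_x, n_individuals)
    y = scenario.b_xy * x + rng.normal(0.0, scenario.sd_y, n_individuals)

    e = summarize_cohort(g, x)
    t = summarize_cohort(g, y)
    top = int(np.nanargmin(e.p))
    b_smr = float(t.beta[top] / e.beta[top])

    z = g[:, top] - g[:, top].mean()
    b_2sls = float((z @ (y - y.mean())) / (z @ (x - x.mean())))
    return TwoStageComparison(b_smr=b_smr, b_2sls=b_2sls)


def null_scenario(**overrides) -> SyntheticScenario:
    """The study's null-architecture conditions (b_xy = 0)."""
    return replace(SyntheticScenario(architecture="null", b_xy=0.0), **overrides)


def pleiotropy_scenario(**overrides) -> SyntheticScenario:
    return replace(SyntheticScenario(architecture="pleiotropy"), **overrides)


def linkage_scenario(**overrides) -> SyntheticScenario:
    return replace(SyntheticScenario(architecture="linkage"), **overrides)
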