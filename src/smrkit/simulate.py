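"""Synthetic cohorts, summary statistics and reference panels.

The generator realizes the causal diagram the analysis assumes: genotype
-> expression (eQTL arrow), genotype -> trait (GWAS arrow), and the
expression -> trait arrow whose presence the SMR test adjudicates.  Three
architectures are supported for a single cis locus:

``pleiotropy``
    one causal variant drives expression (effect ``b_zx``) and, through
    expression, the trait (mediated per-allele effect ``b_xy * b_zx``);
``linkage``
    one variant drives expression while a second variant in LD with it
    carries a direct trait effect ``b_zy2`` (no mediation);
``null``
    the expression arrow exists but ``b_xy = 0``: no trait signal.

Genotypes are drawn from a Gaussian-copula AR(1) LD model: a latent
normal vector with correlation rho^|i-j| is thresholded at the MAF
quantile once per haplotype, and two independent haplotypes are summed to
a dosage in {0, 1, 2}.  Thresholding attenuates the dosage-level LD below
the latent rho; the attenuation is measured empirically by the tests, not
assumed.  Expression and trait cohorts and the reference panel are three
independent draws from the same LD model, mirroring the three independent
data sources the analysis integrates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .refpanel import ReferencePanel, write_panel
from .sumstats_io import (
    EqtlProbe, EqtlSnpRecord, GwasRecord, write_eqtl, write_gwas,
)

ARCHITECTURES = ("null", "pleiotropy", "linkage")

#: unambiguous allele pairs assigned to simulated variants (no A/T, C/G)
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass
class SyntheticScenario:
    """Generative parameters for one cis locus.

    Defaults describe a well-powered quantitative-trait study: cohorts of
    5,000, a 2,000-individual reference panel, a 20-SNP locus with AR(1)
    latent LD decay 0.9, a causal eQTL effect of 0.3 phenotypic SD per
    allele, and an expression-on-trait effect of 0.3 under pleiotropy.
    Under linkage the second causal variant sits 2 SNPs away — at the
    default LD decay the thresholded dosages there correlate at r ~ 0.6
    — with a direct trait effect of 0.15.
    """

    architecture: str = "pleiotropy"
    n_eqtl_cohort: int = 5000
    n_gwas_cohort: int = 5000
    n_ref_panel: int = 2000
    n_snps: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.9
    b_zx: float = 0.3
    b_xy: float = 0.3
    b_zy2: float = 0.15
    causal_index: Optional[int] = None
    causal_index2: Optional[int] = None
    sd_x: float = 1.0
    sd_y: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if min(self.n_eqtl_cohort, self.n_gwas_cohort, self.n_ref_panel) < 2:
            raise ValueError("cohort sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.causal_index is None:
            self.causal_index = self.n_snps // 2
        if self.causal_index2 is None:
            self.causal_index2 = min(self.causal_index + 2, self.n_snps - 1)
        if self.architecture == "linkage" and self.causal_index == self.causal_index2:
            raise ValueError("linkage requires two distinct causal indices")


@dataclass
class CohortSummary:
    """Per-SNP simple-regression summary statistics for one cohort."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    freq: np.ndarray
    n: int
    monomorphic: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@lru_cache(maxsize=32)
def _ar1_cholesky(n_snps: int, rho: float) -> np.ndarray:
    idx = np.arange(n_snps)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def scenario_mafs(scenario: SyntheticScenario) -> np.ndarray:
    """Deterministic per-SNP MAFs, evenly spread over ``maf_range``."""
    lo, hi = scenario.maf_range
    return np.linspace(lo, hi, scenario.n_snps)


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    mafs: np.ndarray,
    ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an n x m dosage matrix under the Gaussian-copula AR(1) model."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (n_snps,):
        raise ValueError("mafs must have one entry per SNP")
    chol = _ar1_cholesky(n_snps, float(ld_rho))
    thresholds = stats.norm.ppf(mafs)
    dosage = np.zeros((n_individuals, n_snps))
    for _ in range(2):  # two independent haplotypes
        latent = rng.standard_normal((n_individuals, n_snps)) @ chol.T
        dosage += latent < thresholds
    return dosage


def simulate_phenotypes(
    g_eqtl: np.ndarray,
    g_gwas: np.ndarray,
    scenario: SyntheticScenario,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Expression for the eQTL cohort and trait for the GWAS cohort.

    Expression: x = b_zx * g[causal] + N(0, sd_x^2) in the eQTL cohort.
    Trait, by architecture (GWAS cohort):
      pleiotropy  y = b_xy * (b_zx * g[causal]) + N(0, sd_y^2)
      linkage     y = b_zy2 * g[causal2] + N(0, sd_y^2)
      null        y = N(0, sd_y^2)
    """
    if g_eqtl.shape[1] != g_gwas.shape[1]:
        raise ValueError("cohorts must cover the same variants")
    c1, c2 = scenario.causal_index, scenario.causal_index2
    x = scenario.b_zx * g_eqtl[:, c1] + rng.normal(0.0, scenario.sd_x, g_eqtl.shape[0])
    noise_y = rng.normal(0.0, scenario.sd_y, g_gwas.shape[0])
    if scenario.architecture == "pleiotropy":
        y = scenario.b_xy * (scenario.b_zx * g_gwas[:, c1]) + noise_y
    elif scenario.architecture == "linkage":
        y = scenario.b_zy2 * g_gwas[:, c2] + noise_y
    else:
        y = noise_y
    return x, y


def summarize_cohort(genotypes: np.ndarray, outcome: np.ndarray) -> CohortSummary:
    """Per-SNP simple least-squares of the outcome on dosage.

    Returns beta, its standard error, the two-sided p-value from the t
    statistic with n-2 df, and the allele-1 frequency.  Monomorphic SNPs
    are flagged and reported with NaN beta/se/p.
    """
    n, m = genotypes.shape
    if n < 3:
        raise ValueError("need at least 3 individuals for regression SEs")
    if outcome.shape != (n,):
        raise ValueError("outcome length must match the cohort size")
    gc = genotypes - genotypes.mean(axis=0)
    yc = outcome - outcome.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    mono = sxx == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan
    return CohortSummary(beta=beta, se=se, p=p,
                         freq=genotypes.mean(axis=0) / 2.0, n=n,
                         monomorphic=mono)


@dataclass
class SimulatedStudy:
    """In-memory realization of a scenario: all three data sources."""

    scenario: SyntheticScenario
    snp_ids: list[str]
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    eqtl_summary: CohortSummary
    gwas_summary: CohortSummary
    panel: ReferencePanel
    probe_id: str = "probe1"
    gene: str = "GENE1"
    chrom: str = "1"
    probe_pos: int = 1_000_000

    def gwas_records(self) -> list[GwasRecord]:
        out = []
        for i, sid in enumerate(self.snp_ids):
            a1, a2 = self.alleles[i]
            out.append(GwasRecord(
                snp_id=sid, a1=a1, a2=a2,
                freq_a1=float(self.gwas_summary.freq[i]),
                beta=float(self.gwas_summary.beta[i]),
                se=float(self.gwas_summary.se[i]),
                p=float(self.gwas_summary.p[i]),
                n=float(self.gwas_summary.n),
                chrom=self.chrom, pos=int(self.positions[i]),
            ))
        return out

    def eqtl_probe(self) -> EqtlProbe:
        snps = []
        for i, sid in enumerate(self.snp_ids):
            a1, a2 = self.alleles[i]
            snps.append(EqtlSnpRecord(
                snp_id=sid, chrom=self.chrom, pos=int(self.positions[i]),
                a1=a1, a2=a2, freq_a1=float(self.eqtl_summary.freq[i]),
                beta=float(self.eqtl_summary.beta[i]),
                se=float(self.eqtl_summary.se[i]),
                p=float(self.eqtl_summary.p[i]),
            ))
        return EqtlProbe(probe_id=self.probe_id, gene=self.gene,
                         chrom=self.chrom, probe_pos=self.probe_pos, snps=snps)


def simulate_study(
    scenario: SyntheticScenario,
    rng: Optional[np.random.Generator] = None,
    panel: Optional[ReferencePanel] = None,
) -> SimulatedStudy:
    """Realize a scenario: two cohorts' summary statistics plus a panel.

    The expression cohort, trait cohort and reference panel are mutually
    independent draws.  Pass a pre-built ``panel`` to reuse one panel
    across replicates (LD estimation error then stays fixed, as it does
    in a real analysis where a single panel serves every locus).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m = scenario.n_snps
    mafs = scenario_mafs(scenario)
    snp_ids = [f"snp{i + 1:04d}" for i in range(m)]
    positions = 1_000_000 - 50_000 + 5_000 * np.arange(m)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]

    g_e = simulate_genotypes(scenario.n_eqtl_cohort, m, mafs, scenario.ld_rho, rng)
    g_g = simulate_genotypes(scenario.n_gwas_cohort, m, mafs, scenario.ld_rho, rng)
    x, y = simulate_phenotypes(g_e, g_g, scenario, rng)

    if panel is None:
        panel = simulate_panel(scenario, rng)
    return SimulatedStudy(
        scenario=scenario, snp_ids=snp_ids, positions=positions, alleles=alleles,
        eqtl_summary=summarize_cohort(g_e, x),
        gwas_summary=summarize_cohort(g_g, y),
        panel=panel,
    )


def simulate_panel(
    scenario: SyntheticScenario, rng: np.random.Generator,
) -> ReferencePanel:
    """Independent reference-panel draw under the scenario's LD model."""
    m = scenario.n_snps
    g_p = simulate_genotypes(scenario.n_ref_panel, m, scenario_mafs(scenario),
                             scenario.ld_rho, rng)
    snp_ids = [f"snp{i + 1:04d}" for i in range(m)]
    positions = 1_000_000 - 50_000 + 5_000 * np.arange(m)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    variants = pd.DataFrame({
        "snp_id": snp_ids, "chrom": "1", "pos": positions,
        "a1": [a for a, _ in alleles], "a2": [b for _, b in alleles],
    })
    iids = [f"ind{i + 1:05d}" for i in range(scenario.n_ref_panel)]
    return ReferencePanel(variants=variants, genotypes=g_p, individual_ids=iids)


def write_scenario(
    scenario: SyntheticScenario,
    out_dir: str | Path,
    flip_gwas_fraction: float = 0.0,
) -> dict[str, str]:
    """Write a scenario to disk in the pipeline's input formats.

    Emits ``gwas.txt`` (whitespace text), ``eqtl.tsv``, a PLINK triplet
    ``panel.bed/.bim/.fam`` and ``manifest.json`` recording every
    generative parameter and the seed.  ``flip_gwas_fraction`` flips the
    reported allele orientation (swap a1/a2, negate beta, reflect freq)
    for that fraction of GWAS rows: the information is unchanged, so the
    pipeline must produce identical results — a harmonization probe.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(scenario)
    records = study.gwas_records()
    if flip_gwas_fraction > 0.0:
        rng = np.random.default_rng(scenario.seed + 1)
        flip = rng.random(len(records)) < flip_gwas_fraction
        for rec, do_flip in zip(records, flip):
            if do_flip:
                rec.a1, rec.a2 = rec.a2, rec.a1
                rec.beta = -rec.beta
                rec.freq_a1 = 1.0 - rec.freq_a1

    gwas_path = out_dir / "gwas.txt"
    eqtl_path = out_dir / "eqtl.tsv"
    write_gwas(records, gwas_path)
    write_eqtl([study.eqtl_probe()], eqtl_path)
    bed, bim, fam = write_panel(study.panel, out_dir / "panel")

    manifest = {
        "scenario": asdict(study.scenario),
        "flip_gwas_fraction": flip_gwas_fraction,
        "files": {"gwas": gwas_path.name, "eqtl": eqtl_path.name,
                  "bed": bed.name, "bim": bim.name, "fam": fam.name},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return {"gwas": str(gwas_path), "eqtl": str(eqtl_path),
            "bed": str(bed), "bim": str(bim), "fam": str(fam),
            "manifest": str(manifest_path)}
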