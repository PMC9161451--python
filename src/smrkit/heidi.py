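"""HEIDI: heterogeneity in dependent instruments.

A significant SMR association can arise in two ways: a single variant
affects both expression and trait (pleiotropy, the interesting case), or
two distinct variants in LD affect one each (linkage).  Under the
single-causal-variant null, the ratio estimate b_xy(i) = b_GWAS(i) /
b_eQTL(i) is the same at every SNP in the cis region, so heterogeneity
among the per-SNP ratios is evidence for linkage.

HEIDI tests the null by forming, for each non-top instrument i,

    d_i = b_xy(i) - b_xy(top),

standardizing by the delta-method variance, and summing the squares:
T_HEIDI = sum_i z_d(i)^2.  Because the instruments are in mutual LD the
z_d are correlated, and T_HEIDI follows a weighted sum of 1-df chi-square
variables with weights equal to the eigenvalues of the correlation matrix
of d.  The tail probability of that quadratic form is evaluated by
numerical inversion of its characteristic function (Imhof's method), with
a Satterthwaite moment-matching approximation as a logged fallback.

Covariance model: within a study, cov(b_i, b_j) = r_ij * se_i * se_j
where r_ij is the signed dosage LD correlation from the reference panel;
the GWAS and eQTL studies are independent, so cross-covariances are zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, stats

from .harmonize import HarmonizedSnp
from .refpanel import ReferencePanel, ld_matrix

logger = logging.getLogger(__name__)

R2_MIN = 0.05
R2_MAX = 0.90
P_EQTL_INSTRUMENT_MAX = 1.57e-3   # ~ |z_eQTL| > 3.16
MAX_SNPS = 20
MIN_SNPS = 3
RIDGE = 1e-8


@dataclass
class HeidiInput:
    """Instruments for one HEIDI test, with their LD structure.

    ``others`` excludes the top SNP; ``ld_r_matrix`` is the signed LD
    correlation over [top] + others in that order (unit diagonal), and
    ``ld_r_vector`` its first row minus the diagonal element.
    """

    top: HarmonizedSnp
    others: list[HarmonizedSnp]
    ld_r_vector: np.ndarray
    ld_r_matrix: np.ndarray


@dataclass(frozen=True)
class HeidiResult:
    t_heidi: Optional[float]
    df_effective: Optional[float]
    p_heidi: Optional[float]
    n_snps_used: int
    used_fallback: bool = False


def quadform_tail(x: float, lambdas: Sequence[float]) -> float:
    """P(Q > x) for Q = sum_k lambda_k * chi2_1 (independent, central).

    Imhof's exact characteristic-function inversion,

        P(Q > x) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du,
        theta(u) = (1/2) sum_k atan(lambda_k u) - x u / 2,
        rho(u)   = prod_k (1 + lambda_k^2 u^2)^(1/4),

    evaluated with adaptive quadrature.  Falls back to the Satterthwaite
    two-moment chi-square approximation when the quadrature does not
    converge; the fallback is logged.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 1.0 if x <= 0 else 0.0
    if x <= 0:
        return 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return float(np.sin(theta) / (u * rho))

    try:
        with np.errstate(over="ignore"), warnings.catch_warnings():
            # the integrand oscillates forever; the subdivision-limit warning
            # is expected and the abserr check below guards accuracy
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            value, abserr = integrate.quad(integrand, 0.0, np.inf, limit=500)
        p = 0.5 + value / np.pi
        if abserr > 1e-5 or not np.isfinite(p):
            raise RuntimeError(f"Imhof quadrature unreliable (abserr={abserr:.2e})")
    except Exception as exc:  # integration failure -> moment matching
        logger.warning("Imhof inversion failed (%s); using Satterthwaite fallback", exc)
        return _satterthwaite_tail(x, lam)
    return float(min(max(p, 1e-15), 1.0))


def _satterthwaite_tail(x: float, lam: np.ndarray) -> float:
    """Two-moment scaled-chi-square approximation to the quadratic form."""
    s1, s2 = float(np.sum(lam)), float(np.sum(lam ** 2))
    if s1 <= 0 or s2 <= 0:
        return 1.0
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(stats.chi2.sf(x / scale, df=df))


def select_heidi_snps(
    snps: Sequence[HarmonizedSnp],
    top: HarmonizedSnp,
    panel: ReferencePanel,
    r2_min: float = R2_MIN,
    r2_max: float = R2_MAX,
    p_eqtl_instrument_max: float = P_EQTL_INSTRUMENT_MAX,
    max_snps: int = MAX_SNPS,
) -> HeidiInput:
    """Choose the HEIDI instrument set around the top SNP.

    Keeps SNPs with r2_min <= r^2(snp, top) <= r2_max and an eQTL
    p-value below ``p_eqtl_instrument_max``; then prunes pairs of
    retained SNPs whose mutual r^2 leaves the same window (dropping the
    weaker-eQTL member of each offending pair); finally caps the set at
    the ``max_snps`` strongest eQTL instruments.  The retained SNPs keep
    a deterministic position/snp_id order.
    """
    candidates = []
    for s in snps:
        if s.snp_id == top.snp_id:
            continue
        if s.p_eqtl >= p_eqtl_instrument_max:
            continue
        if s.snp_id not in panel:
            continue
        candidates.append(s)

    if candidates:
        ids = [top.snp_id] + [s.snp_id for s in candidates]
        full_r = ld_matrix(panel, ids)
        r2_top = full_r[0, 1:] ** 2
        keep = [s for s, r2 in zip(candidates, r2_top) if r2_min <= r2 <= r2_max]
    else:
        keep = []

    # pairwise prune among the survivors: greedy in eQTL strength order,
    # so the weaker member of every out-of-window pair is the one dropped
    if keep:
        ids = [top.snp_id] + [s.snp_id for s in keep]
        r = ld_matrix(panel, ids)
        order = sorted(range(len(keep)),
                       key=lambda i: (keep[i].p_eqtl, keep[i].snp_id))
        accepted: list[int] = []
        for i in order:
            ok = True
            for j in accepted:
                r2 = r[1 + i, 1 + j] ** 2
                if r2 > r2_max or r2 < r2_min:
                    ok = False
                    break
            if ok:
                accepted.append(i)
        accepted = sorted(
            accepted, key=lambda i: (keep[i].p_eqtl, keep[i].snp_id))[:max_snps]
        chosen = sorted((keep[i] for i in accepted),
                        key=lambda s: (s.pos, s.snp_id))
    else:
        chosen = []

    ids = [top.snp_id] + [s.snp_id for s in chosen]
    r = ld_matrix(panel, ids) if len(ids) >= 2 else np.ones((1, 1))
    return HeidiInput(top=top, others=chosen,
                      ld_r_vector=r[0, 1:].copy(), ld_r_matrix=r)


def heidi_test(inp: HeidiInput, min_snps: int = MIN_SNPS) -> HeidiResult:
    """Run the HEIDI heterogeneity test on a selected instrument set.

    Requires at least ``min_snps`` non-top instruments; otherwise the
    p-value is reported absent (the probe cannot be adjudicated).  A
    numerically singular d-correlation matrix is ridge-regularized on the
    diagonal (1e-8) and the event logged.
    """
    m = len(inp.others)
    if m < min_snps:
        return HeidiResult(t_heidi=None, df_effective=None, p_heidi=None,
                           n_snps_used=m)

    all_snps = [inp.top] + inp.others
    b_g = np.array([s.b_gwas for s in all_snps])
    se_g = np.array([s.se_gwas for s in all_snps])
    b_e = np.array([s.b_eqtl for s in all_snps])
    se_e = np.array([s.se_eqtl for s in all_snps])
    r = inp.ld_r_matrix

    if np.any(b_e == 0.0):
        raise ValueError("b_eqtl = 0 in HEIDI instrument set")

    # delta-method covariance of the ratio estimates f_i = b_g_i / b_e_i:
    #   cov(f_i, f_j) = r_ij se_g_i se_g_j / (b_e_i b_e_j)
    #                 + (b_g_i b_g_j / (b_e_i^2 b_e_j^2)) r_ij se_e_i se_e_j
    f = b_g / b_e
    g_term = np.outer(se_g / b_e, se_g / b_e)
    e_term = np.outer(b_g * se_e / b_e ** 2, b_g * se_e / b_e ** 2)
    cov_f = r * (g_term + e_term)

    # d_i = f_i - f_0 for i = 1..m
    d = f[1:] - f[0]
    cov_d = (cov_f[1:, 1:]
             - cov_f[1:, :1]
             - cov_f[:1, 1:]
             + cov_f[0, 0])

    var_d = np.diag(cov_d).copy()
    if np.any(var_d <= 0):
        raise ValueError("non-positive variance in HEIDI d vector")
    z_d = d / np.sqrt(var_d)
    t_heidi = float(np.sum(z_d ** 2))

    corr_d = cov_d / np.sqrt(np.outer(var_d, var_d))
    corr_d = (corr_d + corr_d.T) / 2.0
    eigvals = np.linalg.eigvalsh(corr_d)
    if np.min(eigvals) < 1e-10:
        logger.warning("HEIDI d-correlation near-singular (min eig %.2e); "
                       "ridge-regularizing", float(np.min(eigvals)))
        corr_d = corr_d + RIDGE * np.eye(m)
        eigvals = np.linalg.eigvalsh(corr_d)
    eigvals = np.clip(eigvals, 0.0, None)

    p = quadform_tail(t_heidi, eigvals)
    df_eff = float(np.sum(eigvals) ** 2 / np.sum(eigvals ** 2))
    return HeidiResult(t_heidi=t_heidi, df_effective=df_eff,
                       p_heidi=p, n_snps_used=m)
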