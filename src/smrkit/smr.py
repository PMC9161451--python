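"""The SMR instrumental-variable statistic.

Using the top cis-eQTL SNP as an instrument, the effect of gene
expression on the trait is estimated as the ratio of summary effects,

    b_SMR = b_GWAS / b_eQTL,

and tested with the chi-square(1) statistic

    T_SMR = z_GWAS^2 * z_eQTL^2 / (z_GWAS^2 + z_eQTL^2),

the harmonic combination of the two squared z-scores.  T_SMR is bounded
above by the weaker of the two association signals, so a gene can only be
significant when both the eQTL and the GWAS associations are strong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSnp

#: genome-wide eligibility threshold for the top cis-eQTL (inclusive)
P_EQTL_MAX = 5e-8


@dataclass(frozen=True)
class SmrStatistic:
    top_snp: str
    z2_gwas: float
    z2_eqtl: float
    b_smr: float
    se_smr: Optional[float]
    t_smr: float
    p_smr: float


def z_from_p(p: float) -> float:
    """|z| corresponding to a two-sided p-value.

    Upper-tail standard-normal quantile at p/2; exact tail arithmetic in
    scipy keeps this accurate down to p = 1e-300.  z_from_p(1) = 0.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p={p!r} outside (0, 1]")
    return float(stats.norm.isf(p / 2.0))


def _z2(beta: Optional[float], se: Optional[float], p: float) -> float:
    """Squared z from beta/se when both present, else from the p-value."""
    if beta is not None and se is not None and se > 0:
        return (beta / se) ** 2
    return z_from_p(p) ** 2


def smr_statistic_from_z2(z2_eqtl: float, z2_gwas: float) -> tuple[float, float]:
    """(T_SMR, p_SMR) from the two squared z-scores."""
    if z2_eqtl < 0 or z2_gwas < 0:
        raise ValueError("squared z-scores must be non-negative")
    total = z2_eqtl + z2_gwas
    if total == 0.0:
        return 0.0, 1.0
    t = z2_eqtl * z2_gwas / total
    return t, float(stats.chi2.sf(t, df=1))


def smr_p_from_pvalues(p_eqtl: float, p_gwas: float) -> float:
    """SMR p-value computed from the two association p-values alone.

    Supports reanalysis of published results tables that print p-values
    but not effect sizes.
    """
    _, p = smr_statistic_from_z2(z_from_p(p_eqtl) ** 2, z_from_p(p_gwas) ** 2)
    return p


def select_top_snp(
    snps: Sequence[HarmonizedSnp],
    p_eqtl_max: float = P_EQTL_MAX,
) -> Optional[HarmonizedSnp]:
    """Pick the instrument: the SNP with the smallest eQTL p-value.

    Returns None (probe not testable) when no SNP reaches ``p_eqtl_max``
    (inclusive).  Ties on p are broken by larger |z_eQTL| computed from
    beta/se, then by lexicographically smaller snp_id.
    """
    if not snps:
        return None
    best = min(snps, key=lambda s: (s.p_eqtl, -abs(s.b_eqtl / s.se_eqtl), s.snp_id))
    if best.p_eqtl > p_eqtl_max:
        return None
    return best


def smr_test(top: HarmonizedSnp) -> SmrStatistic:
    """SMR ratio estimate and chi-square test at the instrument SNP.

    The squared z-scores are taken from beta/se (the p-value path is used
    only when a beta is unavailable).  The standard error of b_SMR is the
    first-order delta-method expression

        se = |b_SMR| * sqrt(se_G^2/b_G^2 + se_E^2/b_E^2),

    reported as None when b_GWAS = 0 (the expansion point is degenerate).
    """
    if top.b_eqtl == 0.0:
        raise ValueError(f"{top.snp_id}: b_eqtl = 0, instrument invalid")
    z2_g = _z2(top.b_gwas, top.se_gwas, top.p_gwas)
    z2_e = _z2(top.b_eqtl, top.se_eqtl, top.p_eqtl)
    t, p = smr_statistic_from_z2(z2_e, z2_g)
    b_smr = top.b_gwas / top.b_eqtl
    if top.b_gwas == 0.0:
        se_smr = None
    else:
        se_smr = abs(b_smr) * float(np.sqrt(
            (top.se_gwas / top.b_gwas) ** 2 + (top.se_eqtl / top.b_eqtl) ** 2
        ))
    return SmrStatistic(
        top_snp=top.snp_id, z2_gwas=z2_g, z2_eqtl=z2_e,
        b_smr=b_smr, se_smr=se_smr, t_smr=t, p_smr=p,
    )
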