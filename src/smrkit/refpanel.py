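"""Individual-level genotype reference panel: PLINK I/O, QC, frequencies, LD.

The panel plays a supporting role only: it supplies effect-allele
frequencies (for harmonization checks and for GWAS files that ship
without frequency columns) and dosage-level LD (r, r²) for HEIDI
instrument selection and covariance modelling.  No association testing
is ever run on it.

Genotypes are stored as an ``n_individuals x n_variants`` float matrix of
allele-1 dosages in {0, 1, 2} with NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PLINK_MAGIC = bytes((0x6C, 0x1B))
SNP_MAJOR = 0x01

# 2-bit PLINK .bed codes -> allele-1 dosage: 00 hom A1 = 2, 01 missing,
# 10 het = 1, 11 hom A2 = 0.  First sample occupies the lowest two bits.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_BYTE_LUT = np.empty((256, 4))
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 0b11]


class PanelFormatError(ValueError):
    """Malformed PLINK triplet (bad magic bytes, inconsistent dimensions)."""


class PanelLookupError(KeyError):
    """A requested SNP is absent from the panel or has no usable genotypes."""


@dataclass
class ReferencePanel:
    """Genotype matrix plus variant/individual metadata.

    ``variants`` has columns ``snp_id, chrom, pos, a1, a2``; ``genotypes``
    is individuals x variants with allele-1 dosages (NaN = missing).
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        n_ind, n_var = self.genotypes.shape
        if n_var != len(self.variants) or n_ind != len(self.individual_ids):
            raise PanelFormatError(
                f"genotype matrix {self.genotypes.shape} inconsistent with "
                f"{len(self.variants)} variants / {len(self.individual_ids)} individuals"
            )
        self._index = {s: i for i, s in enumerate(self.variants["snp_id"])}

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.genotypes[:, self._index[snp_id]]
        except KeyError:
            raise PanelLookupError(snp_id) from None

    def variant(self, snp_id: str) -> pd.Series:
        try:
            return self.variants.iloc[self._index[snp_id]]
        except KeyError:
            raise PanelLookupError(snp_id) from None


@dataclass(frozen=True)
class PanelQcReport:
    n_variants_in: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_individuals_removed: int
    n_variants_out: int


def load_panel(bed_path: str | Path, bim_path: str | Path, fam_path: str | Path) -> ReferencePanel:
    """Load a PLINK binary triplet (.bed v1.00, SNP-major) into memory.

    Raises :class:`PanelFormatError` on bad magic bytes or when the .bed
    payload size disagrees with the .bim/.fam dimensions.
    """
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    bim["pos"] = bim["pos"].astype(int)
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    n_var, n_ind = len(bim), len(fam)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != PLINK_MAGIC:
        raise PanelFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != SNP_MAJOR:
        raise PanelFormatError(f"{bed_path}: not in SNP-major mode")
    bytes_per_variant = (n_ind + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * n_var:
        raise PanelFormatError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{n_var} variants x {bytes_per_variant} bytes"
        )
    # decode all variants at once via a per-byte lookup table
    decoded = _BYTE_LUT[payload.reshape(n_var, bytes_per_variant)]
    genotypes = decoded.reshape(n_var, bytes_per_variant * 4)[:, :n_ind].T.copy()

    variants = bim[["snp_id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    return ReferencePanel(variants=variants, genotypes=genotypes,
                          individual_ids=list(fam["iid"]))


def write_panel(panel: ReferencePanel, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write a panel as PLINK .bed/.bim/.fam (SNP-major v1.00)."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    n_ind, n_var = panel.genotypes.shape
    bytes_per_variant = (n_ind + 3) // 4
    # dosage -> 2-bit code: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
    g = panel.genotypes
    codes = np.where(np.isnan(g), 1, np.where(g == 2, 0, np.where(g == 1, 2, 3)))
    codes = codes.astype(np.uint8).T  # variants x individuals
    padded = np.zeros((n_var, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n_ind] = codes
    packed = np.zeros((n_var, bytes_per_variant), dtype=np.uint8)
    for i in range(4):
        packed |= padded[:, i::4] << (2 * i)
    with open(bed_path, "wb") as fh:
        fh.write(PLINK_MAGIC + bytes((SNP_MAJOR,)))
        fh.write(packed.tobytes())

    with open(bim_path, "w") as fh:
        for row in panel.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    with open(fam_path, "w") as fh:
        for iid in panel.individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    return bed_path, bim_path, fam_path


def hwe_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Observed genotype counts are compared with the expectation from the
    sample allele frequency.  Monomorphic variants return p = 1 by
    convention (the test is undefined without both alleles present).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped individuals")
    p1 = (2 * n_hom1 + n_het) / (2 * n)
    q1 = 1.0 - p1
    if p1 == 0.0 or q1 == 0.0:
        return 1.0
    expected = np.array([n * p1 * p1, 2 * n * p1 * q1, n * q1 * q1])
    observed = np.array([n_hom1, n_het, n_hom2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Vectorised HWE chi-square p per variant column."""
    n_hom1 = np.nansum(genotypes == 2, axis=0)
    n_het = np.nansum(genotypes == 1, axis=0)
    n_hom2 = np.nansum(genotypes == 0, axis=0)
    n = n_hom1 + n_het + n_hom2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * n_hom1 + n_het) / (2 * np.maximum(n, 1))
        q1 = 1.0 - p1
        e_hom1, e_het, e_hom2 = n * p1 ** 2, 2 * n * p1 * q1, n * q1 ** 2
        chi2 = ((n_hom1 - e_hom1) ** 2 / e_hom1
                + (n_het - e_het) ** 2 / e_het
                + (n_hom2 - e_hom2) ** 2 / e_hom2)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[(p1 == 0) | (q1 == 0) | (n == 0)] = 1.0  # monomorphic / empty
    return pvals


def qc_panel(
    panel: ReferencePanel,
    marker_call_rate: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_max: float = 1e-6,
    indiv_call_rate: float = 0.95,
) -> tuple[ReferencePanel, PanelQcReport]:
    """Apply standard panel QC with a fixed removal order.

    Variants are removed for (1) marker call rate < ``marker_call_rate``,
    then (2) MAF < ``maf_min``, then (3) HWE departure p < ``hwe_p_max``;
    finally individuals with call rate < ``indiv_call_rate`` over the
    surviving variants are removed.  Each variant is counted against the
    first criterion it fails, so the report's removal counts are disjoint.
    """
    g = panel.genotypes
    n_ind, n_var = g.shape
    missing = np.isnan(g)
    n_called = n_ind - missing.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        call_rate = n_called / n_ind
        freq = np.nansum(g, axis=0) / (2 * np.maximum(n_called, 1))
        maf = np.minimum(freq, 1 - freq)
    fail_cr = call_rate < marker_call_rate
    fail_maf = ~fail_cr & ((maf < maf_min) | (n_called == 0))
    hwe_p = _hwe_pvalues(g)
    fail_hwe = ~fail_cr & ~fail_maf & (hwe_p < hwe_p_max)

    keep_var = ~(fail_cr | fail_maf | fail_hwe)
    g2 = g[:, keep_var]
    if g2.shape[1] > 0:
        ind_call = 1.0 - np.isnan(g2).sum(axis=1) / g2.shape[1]
    else:
        ind_call = np.ones(n_ind)
    keep_ind = ind_call >= indiv_call_rate

    qced = ReferencePanel(
        variants=panel.variants.loc[keep_var].reset_index(drop=True),
        genotypes=g2[keep_ind],
        individual_ids=[iid for iid, k in zip(panel.individual_ids, keep_ind) if k],
    )
    report = PanelQcReport(
        n_variants_in=n_var,
        n_removed_call_rate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_individuals_removed=int((~keep_ind).sum()),
        n_variants_out=int(keep_var.sum()),
    )
    return qced, report


def allele_freq(panel: ReferencePanel, snp_id: str) -> float:
    """Allele-1 frequency: mean dosage / 2 over non-missing individuals."""
    col = panel.column(snp_id)
    n = np.sum(~np.isnan(col))
    if n == 0:
        raise PanelLookupError(f"{snp_id}: all genotypes missing")
    return float(np.nansum(col) / (2 * n))


def ld_r(panel: ReferencePanel, snp_a: str, snp_b: str) -> float:
    """Signed LD correlation r between two variants' dosage columns.

    Pearson correlation over pairwise-complete individuals; the sign is
    with respect to each variant's allele 1.  Raises on zero variance.
    """
    a, b = panel.column(snp_a), panel.column(snp_b)
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 2:
        raise PanelLookupError(f"fewer than 2 complete pairs for {snp_a}/{snp_b}")
    ax, bx = a[mask], b[mask]
    sa, sb = ax.std(), bx.std()
    if sa == 0.0 or sb == 0.0:
        raise PanelLookupError(f"zero variance for {snp_a} or {snp_b}")
    return float(np.corrcoef(ax, bx)[0, 1])


def ld_matrix(panel: ReferencePanel, snp_ids: Sequence[str]) -> np.ndarray:
    """Signed LD correlation matrix for a list of variants.

    Complete-case across the listed variants (adequate for the simulated
    and QC'd panels this package targets, where missingness is sparse).
    """
    cols = np.column_stack([panel.column(s) for s in snp_ids])
    mask = ~np.isnan(cols).any(axis=1)
    if mask.sum() < 2:
        raise PanelLookupError("fewer than 2 complete individuals for LD matrix")
    sub = cols[mask]
    if np.any(sub.std(axis=0) == 0.0):
        raise PanelLookupError("zero-variance variant in LD matrix request")
    return np.corrcoef(sub, rowvar=False)
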