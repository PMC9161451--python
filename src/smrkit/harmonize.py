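"""Allele/frequency harmonization across GWAS, eQTL and reference panel.

All effect sizes and frequencies are re-expressed on the orientation of
the reference panel's allele 1 before any statistic is computed, so a SNP
reported on opposite strands or with swapped effect/other alleles in the
two summary datasets yields identical downstream results.  SNP-level
filters (allele reconcilability, effect-allele-frequency agreement,
minor-allele frequency) are applied in a fixed order and every removal is
written to an exhaustive drop log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .refpanel import ReferencePanel, allele_freq
from .sumstats_io import EqtlProbe, GwasRecord

CIS_WINDOW_BP = 1_000_000

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs whose strand flip is indistinguishable from an orientation swap
AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


class AlleleMismatchError(ValueError):
    """Allele sets cannot be reconciled even after a strand flip."""


@dataclass
class HarmonizedSnp:
    """One SNP with GWAS and eQTL effects on a common effect allele.

    ``a1`` is the shared effect allele after alignment (the panel's
    allele 1); all betas and frequencies refer to it.
    """

    snp_id: str
    pos: int
    a1: str
    a2: str
    b_gwas: float
    se_gwas: float
    p_gwas: float
    b_eqtl: float
    se_eqtl: float
    p_eqtl: float
    freq_gwas: float
    freq_eqtl: float
    freq_ref: float


@dataclass(frozen=True)
class DropLogEntry:
    snp_id: str
    probe_id: str
    reason: str


def align_alleles(
    record_alleles: tuple[str, str, float, Optional[float]],
    target_alleles: tuple[str, str],
) -> tuple[float, Optional[float]]:
    """Re-express (beta, freq) on the target (a1, a2) orientation.

    The record's allele pair must equal the target pair as an unordered
    set, directly or after complementing both alleles (strand flip).  A
    reversed orientation negates beta and reflects freq about 0.5.

    Strand-ambiguous pairs (A/T, C/G) are aligned here by label only;
    resolving their true strand needs frequency evidence and is handled by
    :func:`build_probe_dataset`.
    """
    a1, a2, beta, freq = record_alleles
    t1, t2 = target_alleles
    if (a1, a2) == (t1, t2):
        return beta, freq
    if (a1, a2) == (t2, t1):
        return -beta, None if freq is None else 1.0 - freq
    c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (c1, c2) == (t1, t2):
        return beta, freq
    if (c1, c2) == (t2, t1):
        return -beta, None if freq is None else 1.0 - freq
    raise AlleleMismatchError(f"alleles {a1}/{a2} irreconcilable with target {t1}/{t2}")


def frequency_check(freq_a: float, freq_b: float, max_diff: float = 0.2) -> bool:
    """Effect-allele-frequency agreement: pass iff |freq_a - freq_b| <= max_diff."""
    if not (0.0 <= freq_a <= 1.0 and 0.0 <= freq_b <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return abs(freq_a - freq_b) <= max_diff


def apply_snp_filters(
    snps: Sequence[HarmonizedSnp],
    maf_min: float = 0.01,
    probe_id: str = "",
) -> tuple[list[HarmonizedSnp], list[DropLogEntry]]:
    """Drop SNPs rare in ANY source: min(freq, 1-freq) < maf_min (strict)."""
    kept, dropped = [], []
    for s in snps:
        mafs = [min(f, 1.0 - f) for f in (s.freq_gwas, s.freq_eqtl, s.freq_ref)]
        if min(mafs) < maf_min:
            dropped.append(DropLogEntry(s.snp_id, probe_id, "maf_below_min"))
        else:
            kept.append(s)
    return kept, dropped


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset({a1, a2}) in AMBIGUOUS_PAIRS


def _flip_if(freq: Optional[float], flipped: bool) -> Optional[float]:
    if freq is None:
        return None
    return 1.0 - freq if flipped else freq


def _orient_ambiguous(
    beta: float, freq: Optional[float], freq_ref: float, ambiguous_maf_max: float,
) -> tuple[float, float] | None:
    """Resolve an A/T or C/G SNP by frequency matching against the panel.

    Returns the (beta, freq) orientation whose frequency agrees better
    with the panel, or None when the frequency is too close to 0.5 to
    decide (min(freq, 1-freq) > ambiguous_maf_max).
    """
    if freq is None:
        return None
    if min(freq, 1.0 - freq) > ambiguous_maf_max or \
            min(freq_ref, 1.0 - freq_ref) > ambiguous_maf_max:
        return None
    if abs(freq - freq_ref) <= abs((1.0 - freq) - freq_ref):
        return beta, freq
    return -beta, 1.0 - freq


def build_probe_dataset(
    probe: EqtlProbe,
    gwas: Mapping[str, GwasRecord],
    panel: ReferencePanel,
    cis_window: int = CIS_WINDOW_BP,
    maf_min: float = 0.01,
    freq_diff_max: float = 0.2,
    ambiguous_maf_max: float = 0.4,
) -> tuple[list[HarmonizedSnp], list[DropLogEntry]]:
    """Assemble the analysis-ready SNP set for one probe.

    Takes the intersection of the probe's cis-SNPs (|snp_pos - probe_pos|
    strictly below ``cis_window``), the GWAS index and the panel,
    harmonizes everything to the panel's allele-1 orientation, and applies
    the SNP filters in fixed order: allele match -> frequency check
    (all three pairs) -> MAF.  A GWAS record without a frequency column
    inherits the panel frequency.  Output is sorted by position then
    snp_id; the drop log is exhaustive and disjoint.
    """
    droplog: list[DropLogEntry] = []
    candidates = []
    for es in probe.snps:
        if abs(es.pos - probe.probe_pos) >= cis_window:
            droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "outside_cis_window"))
            continue
        if es.snp_id not in gwas:
            droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "absent_from_gwas"))
            continue
        if es.snp_id not in panel:
            droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "absent_from_panel"))
            continue
        gw = gwas[es.snp_id]
        if not gw.usable:
            droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "gwas_missing_beta_se"))
            continue
        candidates.append((es, gw))

    harmonized: list[HarmonizedSnp] = []
    for es, gw in candidates:
        var = panel.variant(es.snp_id)
        target = (var["a1"], var["a2"])
        freq_ref = allele_freq(panel, es.snp_id)
        if _is_ambiguous(target[0], target[1]):
            # A/T or C/G: label alignment is strand-undecidable; orient each
            # summary source by matching its frequency against the panel,
            # dropping SNPs whose frequency is too close to 0.5 to decide.
            if frozenset({es.a1, es.a2}) != frozenset(target) or \
                    frozenset({gw.a1, gw.a2}) != frozenset(target):
                droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "allele_mismatch"))
                continue
            oe = _orient_ambiguous(es.beta if es.a1 == target[0] else -es.beta,
                                   _flip_if(es.freq_a1, es.a1 != target[0]),
                                   freq_ref, ambiguous_maf_max)
            og = _orient_ambiguous(gw.beta if gw.a1 == target[0] else -gw.beta,
                                   _flip_if(gw.freq_a1, gw.a1 != target[0]),
                                   freq_ref, ambiguous_maf_max)
            if oe is None or og is None:
                droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "ambiguous_freq"))
                continue
            (b_e, f_e), (b_g, f_g) = oe, og
        else:
            try:
                if _is_ambiguous(es.a1, es.a2) or _is_ambiguous(gw.a1, gw.a2):
                    # ambiguous in a summary source but not in the panel
                    raise AlleleMismatchError("ambiguous vs unambiguous allele pair")
                b_e, f_e = align_alleles((es.a1, es.a2, es.beta, es.freq_a1), target)
                b_g, f_g = align_alleles((gw.a1, gw.a2, gw.beta, gw.freq_a1), target)
            except AlleleMismatchError:
                droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "allele_mismatch"))
                continue
        if f_g is None:  # GWAS shipped no frequencies; mirror the panel
            f_g = freq_ref
        if f_e is None:
            f_e = freq_ref
        ok = (frequency_check(f_g, freq_ref, freq_diff_max)
              and frequency_check(f_e, freq_ref, freq_diff_max)
              and frequency_check(f_g, f_e, freq_diff_max))
        if not ok:
            droplog.append(DropLogEntry(es.snp_id, probe.probe_id, "freq_mismatch"))
            continue
        harmonized.append(HarmonizedSnp(
            snp_id=es.snp_id, pos=es.pos, a1=target[0], a2=target[1],
            b_gwas=b_g, se_gwas=gw.se, p_gwas=gw.p,
            b_eqtl=b_e, se_eqtl=es.se, p_eqtl=es.p,
            freq_gwas=f_g, freq_eqtl=f_e, freq_ref=freq_ref,
        ))

    harmonized, maf_drops = apply_snp_filters(harmonized, maf_min, probe.probe_id)
    droplog.extend(maf_drops)
    harmonized.sort(key=lambda s: (s.pos, s.snp_id))
    return harmonized, droplog


def write_drop_log(entries: Sequence[DropLogEntry], path) -> None:
    """Write the drop log as a TSV (snp_id, probe_id, reason)."""
    with open(path, "w") as fh:
        fh.write("snp_id\tprobe_id\treason\n")
        for e in entries:
            fh.write(f"{e.snp_id}\t{e.probe_id}\t{e.reason}\n")
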