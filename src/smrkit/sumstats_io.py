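"""Domain types and text I/O for GWAS and cis-eQTL summary statistics.

GWAS summary statistics are read from whitespace-delimited text with the
widely used header convention ``SNP A1 A2 freq b se p n``; eQTL summary
statistics use a tab-separated per-probe layout (one row per probe/SNP
pair).  Readers never silently drop a line: every rejected row is returned
as a :class:`ParseIssue` carrying the 1-based line number and a reason, so
that ``len(records) + len(issues)`` always equals the number of data lines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: default column names for the GWAS summary text format
GWAS_COLUMNS = ("SNP", "A1", "A2", "freq", "b", "se", "p", "n")

EQTL_COLUMNS = (
    "probe_id", "gene", "probe_chrom", "probe_pos",
    "snp_id", "snp_chrom", "snp_pos", "a1", "a2", "freq_a1", "beta", "se", "p",
)

RESULT_COLUMNS = (
    "probe_id", "gene", "top_snp", "b_smr", "se_smr", "p_smr",
    "p_heidi", "n_heidi_snps", "passed_bonferroni", "passed_heidi", "status",
)


class SumstatsFormatError(ValueError):
    """A structural problem with an input file (missing column, conflicting metadata)."""


@dataclass(frozen=True)
class ParseIssue:
    """One rejected input row."""

    line: int           # 1-based line number in the source file
    snp_id: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line} ({self.snp_id}): {self.reason}"


@dataclass
class GwasRecord:
    """One SNP's association with the trait.

    ``beta`` is the per-allele effect of ``a1`` (the effect allele) on the
    trait; ``freq_a1`` is the effect-allele frequency.  ``n`` is optional and
    unused by the core statistics.
    """

    snp_id: str
    a1: str
    a2: str
    freq_a1: Optional[float]
    beta: Optional[float]
    se: Optional[float]
    p: float
    n: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    p_censored: bool = False

    @property
    def usable(self) -> bool:
        """Whether the record carries the beta/se pair needed for estimation."""
        return self.beta is not None and self.se is not None


@dataclass
class EqtlSnpRecord:
    """One SNP's association with the expression of a probe (b_eQTL, SE, p)."""

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    freq_a1: Optional[float]
    beta: float
    se: float
    p: float
    p_censored: bool = False


@dataclass
class EqtlProbe:
    """A gene-expression probe and its cis-SNP association records."""

    probe_id: str
    gene: str
    chrom: str
    probe_pos: int
    snps: list[EqtlSnpRecord] = field(default_factory=list)


@dataclass
class SmrResult:
    """Per-probe output row of the analysis."""

    probe_id: str
    gene: str
    top_snp: Optional[str]
    b_smr: Optional[float]
    se_smr: Optional[float]
    p_smr: Optional[float]
    p_heidi: Optional[float]
    n_heidi_snps: int
    passed_bonferroni: bool
    passed_heidi: bool
    status: str = "ok"  # "ok" | "not_testable"


def _parse_p(raw: str) -> tuple[float, bool]:
    """Parse a p-value cell, honouring censored values like ``<1.00E-300``.

    Returns ``(p, censored)``; censored entries are clamped to the printed
    bound so extreme associations survive the (0, 1] domain check.
    """
    raw = raw.strip()
    censored = raw.startswith("<")
    p = float(raw[1:] if censored else raw)
    return p, censored


def _norm_allele(raw: str) -> str:
    return raw.strip().upper()


def _opt_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    if raw in ("", "NA", "NaN", "nan", "."):
        return None
    value = float(raw)
    return None if math.isnan(value) else value


def read_gwas(
    path: str | Path,
    column_map: Optional[dict[str, str]] = None,
) -> tuple[list[GwasRecord], list[ParseIssue]]:
    """Read GWAS summary statistics from whitespace-delimited text.

    Parameters
    ----------
    path
        File with a mandatory header line.  Default column names are
        ``SNP A1 A2 freq b se p n``; ``column_map`` maps those canonical
        names to the names actually present (e.g. ``{"SNP": "rsid"}``).

    Returns
    -------
    records, issues
        Parsed records and the per-line rejects.  Records with missing
        beta or se are kept but flagged unusable (``record.usable``).

    Raises
    ------
    SumstatsFormatError
        If a mandatory column cannot be resolved in the header.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    colmap = {name: name for name in GWAS_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canonical in ("SNP", "A1", "A2", "p"):
        if colmap[canonical] not in table.columns:
            raise SumstatsFormatError(
                f"{path}: mandatory column {colmap[canonical]!r} not found "
                f"(header: {list(table.columns)})"
            )
    has = {c: colmap[c] in table.columns for c in GWAS_COLUMNS}
    columns = {c: table[colmap[c]].tolist() for c in GWAS_COLUMNS if has[c]}

    records: list[GwasRecord] = []
    issues: list[ParseIssue] = []
    for idx in range(len(table)):
        line = idx + 2  # 1-based, after header
        get = lambda c: columns[c][idx] if has[c] else ""
        snp_id = str(get("SNP")).strip()
        try:
            a1, a2 = _norm_allele(get("A1")), _norm_allele(get("A2"))
            if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
                raise ValueError(f"non-SNP alleles {a1!r}/{a2!r}")
            if a1 == a2:
                raise ValueError(f"identical alleles {a1!r}")
            p, censored = _parse_p(get("p"))
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p={p!r} outside (0, 1]")
            freq = _opt_float(get("freq")) if has["freq"] else None
            if freq is not None and not (0.0 <= freq <= 1.0):
                raise ValueError(f"freq={freq!r} outside [0, 1]")
            beta = _opt_float(get("b")) if has["b"] else None
            se = _opt_float(get("se")) if has["se"] else None
            if se is not None and se <= 0:
                raise ValueError(f"se={se!r} not positive")
            n = _opt_float(get("n")) if has["n"] else None
        except ValueError as exc:
            issues.append(ParseIssue(line=line, snp_id=snp_id or "?", reason=str(exc)))
            continue
        records.append(GwasRecord(
            snp_id=snp_id, a1=a1, a2=a2, freq_a1=freq,
            beta=beta, se=se, p=p, n=n, p_censored=censored,
        ))
    if issues:
        logger.warning("%s: rejected %d of %d data lines", path, len(issues), len(table))
    return records, issues


def read_eqtl(path: str | Path) -> tuple[list[EqtlProbe], list[ParseIssue]]:
    """Read cis-eQTL summary statistics (TSV, one row per probe/SNP pair).

    Rows are grouped by ``probe_id`` preserving first-appearance order;
    duplicate ``snp_id`` within a probe keeps the first occurrence and logs
    the rest.  Conflicting probe metadata for the same ``probe_id`` is a
    hard error.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EQTL_COLUMNS if c not in table.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing columns {missing}")

    probes: dict[str, EqtlProbe] = {}
    seen: dict[str, set[str]] = {}
    issues: list[ParseIssue] = []
    for idx, row in enumerate(table.itertuples(index=False)):
        line = idx + 2
        probe_id = str(row.probe_id).strip()
        snp_id = str(row.snp_id).strip()
        try:
            probe_pos = int(row.probe_pos)
            probe_chrom = str(row.probe_chrom).strip()
            if probe_id in probes:
                probe = probes[probe_id]
                if probe.probe_pos != probe_pos or probe.chrom != probe_chrom:
                    raise SumstatsFormatError(
                        f"{path} line {line}: probe {probe_id} re-declared at "
                        f"{probe_chrom}:{probe_pos} (was {probe.chrom}:{probe.probe_pos})"
                    )
            else:
                probe = EqtlProbe(
                    probe_id=probe_id, gene=str(row.gene).strip(),
                    chrom=probe_chrom, probe_pos=probe_pos,
                )
                probes[probe_id] = probe
                seen[probe_id] = set()
            if snp_id in seen[probe_id]:
                logger.warning("%s line %d: duplicate SNP %s in probe %s (first kept)",
                               path, line, snp_id, probe_id)
                issues.append(ParseIssue(line=line, snp_id=snp_id, reason="duplicate_snp"))
                continue
            a1, a2 = _norm_allele(row.a1), _norm_allele(row.a2)
            if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES or a1 == a2:
                raise ValueError(f"invalid allele pair {a1!r}/{a2!r}")
            p, censored = _parse_p(row.p)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p={p!r} outside (0, 1]")
            se = float(row.se)
            if se <= 0:
                raise ValueError(f"se={se!r} not positive")
            record = EqtlSnpRecord(
                snp_id=snp_id, chrom=str(row.snp_chrom).strip(), pos=int(row.snp_pos),
                a1=a1, a2=a2, freq_a1=_opt_float(row.freq_a1),
                beta=float(row.beta), se=se, p=p, p_censored=censored,
            )
        except SumstatsFormatError:
            raise
        except ValueError as exc:
            issues.append(ParseIssue(line=line, snp_id=snp_id or "?", reason=str(exc)))
            continue
        seen[probe_id].add(snp_id)
        probe.snps.append(record)
    return list(probes.values()), issues


def _fmt(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.6e}"


def write_gwas(records: Sequence[GwasRecord], path: str | Path) -> None:
    """Write GWAS records in the ``SNP A1 A2 freq b se p n`` text format."""
    with open(path, "w") as fh:
        fh.write("\t".join(GWAS_COLUMNS) + "\n")
        for r in records:
            n_cell = "NA" if r.n is None else f"{r.n:g}"
            fh.write("\t".join((
                r.snp_id, r.a1, r.a2, _fmt(r.freq_a1), _fmt(r.beta),
                _fmt(r.se), _fmt(r.p), n_cell,
            )) + "\n")


def write_eqtl(probes: Sequence[EqtlProbe], path: str | Path) -> None:
    """Write probes in the eQTL TSV dialect consumed by :func:`read_eqtl`."""
    with open(path, "w") as fh:
        fh.write("\t".join(EQTL_COLUMNS) + "\n")
        for probe in probes:
            for s in probe.snps:
                fh.write("\t".join((
                    probe.probe_id, probe.gene, probe.chrom, str(probe.probe_pos),
                    s.snp_id, s.chrom, str(s.pos), s.a1, s.a2,
                    _fmt(s.freq_a1), _fmt(s.beta), _fmt(s.se), _fmt(s.p),
                )) + "\n")


def write_results(results: Sequence[SmrResult], path: str | Path) -> None:
    """Write the per-probe results table (TSV, stable column order).

    Floats use scientific notation with 6 significant digits; an absent
    HEIDI p-value (too few instruments, or HEIDI not run) is written "NA".
    """
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join((
                r.probe_id, r.gene, r.top_snp or "NA",
                _fmt(r.b_smr), _fmt(r.se_smr), _fmt(r.p_smr), _fmt(r.p_heidi),
                str(r.n_heidi_snps),
                "1" if r.passed_bonferroni else "0",
                "1" if r.passed_heidi else "0",
                r.status,
            )) + "\n")


def read_results(path: str | Path) -> list[SmrResult]:
    """Read back a results table written by :func:`write_results`."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in table.itertuples(index=False):
        out.append(SmrResult(
            probe_id=row.probe_id, gene=row.gene,
            top_snp=None if row.top_snp == "NA" else row.top_snp,
            b_smr=_opt_float(row.b_smr), se_smr=_opt_float(row.se_smr),
            p_smr=_opt_float(row.p_smr), p_heidi=_opt_float(row.p_heidi),
            n_heidi_snps=int(row.n_heidi_snps),
            passed_bonferroni=row.passed_bonferroni == "1",
            passed_heidi=row.passed_heidi == "1",
            status=row.status,
        ))
    return out
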