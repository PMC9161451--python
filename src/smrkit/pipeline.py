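"""End-to-end analysis: harmonize -> SMR per probe -> Bonferroni -> HEIDI.

The multiple-testing correction divides alpha by the number of probes
that actually produced an SMR test (probes whose top eQTL misses the
eligibility threshold are "not testable" and consume no Bonferroni
budget).  HEIDI runs only for Bonferroni survivors, mirroring the
sequential use of the two tests: SMR finds candidate genes, HEIDI then
removes those whose association looks like linkage.  A probe "passes"
HEIDI when p_HEIDI >= heidi_alpha — rejection means heterogeneity, i.e.
linkage, so survivors are the NON-rejections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .harmonize import (
    DropLogEntry, HarmonizedSnp, build_probe_dataset, write_drop_log,
)
from .heidi import HeidiInput, heidi_test, select_heidi_snps
from .refpanel import ReferencePanel, load_panel
from .smr import select_top_snp, smr_test
from .sumstats_io import (
    EqtlProbe, GwasRecord, SmrResult, read_eqtl, read_gwas, write_results,
)


class PipelineError(RuntimeError):
    """Structured analysis failure (e.g. zero testable probes)."""


@dataclass
class AnalysisConfig:
    """Paths and thresholds for one analysis run."""

    gwas_path: Optional[str] = None
    eqtl_path: Optional[str] = None
    bfile_prefix: Optional[str] = None
    out_dir: Optional[str] = None
    p_eqtl_max: float = 5e-8
    maf_min: float = 0.01
    freq_diff_max: float = 0.2
    r2_min: float = 0.05
    r2_max: float = 0.90
    alpha: float = 0.05
    heidi_alpha: float = 0.05
    heidi_min_snps: int = 3
    heidi_max_snps: int = 20
    heidi_instrument_p: float = 1.57e-3
    cis_window: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_eqtl_max", "maf_min", "freq_diff_max", "r2_min",
                     "r2_max", "alpha", "heidi_alpha", "heidi_instrument_p"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name}={value} outside (0, 1)")


@dataclass
class RunReport:
    """Per-stage counts for auditability and gating reconstruction."""

    n_probes_in: int = 0
    n_probes_harmonized: int = 0
    n_probes_tested: int = 0
    n_not_testable: int = 0
    n_passed_bonferroni: int = 0
    n_heidi_run: int = 0
    n_heidi_evaluable: int = 0
    n_survivors: int = 0
    bonferroni_threshold: Optional[float] = None
    alpha: float = 0.05
    heidi_alpha: float = 0.05
    n_snps_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)


def bonferroni_threshold(n_probes_tested: int, alpha: float = 0.05) -> float:
    """Per-analysis significance threshold: alpha / number of probes tested."""
    if n_probes_tested < 1:
        raise PipelineError("no probes tested; Bonferroni threshold undefined")
    return alpha / n_probes_tested


@dataclass
class ProbeAnalysis:
    """Intermediate per-probe state kept for exports and reporting."""

    probe: EqtlProbe
    harmonized: list[HarmonizedSnp]
    result: SmrResult
    heidi_input: Optional[HeidiInput] = None


def analyze(
    gwas: Mapping[str, GwasRecord] | Sequence[GwasRecord],
    probes: Sequence[EqtlProbe],
    panel: ReferencePanel,
    config: Optional[AnalysisConfig] = None,
) -> tuple[list[ProbeAnalysis], list[DropLogEntry], RunReport]:
    """Run the full in-memory analysis over a set of probes.

    Stage 1 computes an SMR test for every probe with an eligible top
    cis-eQTL; stage 2 applies the Bonferroni gate at alpha divided by the
    number tested; stage 3 runs HEIDI for the survivors only.
    """
    config = config or AnalysisConfig()
    if not isinstance(gwas, Mapping):
        gwas = {r.snp_id: r for r in gwas}

    report = RunReport(n_probes_in=len(probes), alpha=config.alpha,
                       heidi_alpha=config.heidi_alpha)
    droplog: list[DropLogEntry] = []
    analyses: list[ProbeAnalysis] = []

    for probe in probes:
        harmonized, drops = build_probe_dataset(
            probe, gwas, panel,
            cis_window=config.cis_window, maf_min=config.maf_min,
            freq_diff_max=config.freq_diff_max,
        )
        droplog.extend(drops)
        if harmonized:
            report.n_probes_harmonized += 1
        top = select_top_snp(harmonized, config.p_eqtl_max)
        if top is None:
            report.n_not_testable += 1
            analyses.append(ProbeAnalysis(
                probe=probe, harmonized=harmonized,
                result=SmrResult(
                    probe_id=probe.probe_id, gene=probe.gene, top_snp=None,
                    b_smr=None, se_smr=None, p_smr=None, p_heidi=None,
                    n_heidi_snps=0, passed_bonferroni=False,
                    passed_heidi=False, status="not_testable",
                ),
            ))
            continue
        stat = smr_test(top)
        report.n_probes_tested += 1
        analyses.append(ProbeAnalysis(
            probe=probe, harmonized=harmonized,
            result=SmrResult(
                probe_id=probe.probe_id, gene=probe.gene, top_snp=stat.top_snp,
                b_smr=stat.b_smr, se_smr=stat.se_smr, p_smr=stat.p_smr,
                p_heidi=None, n_heidi_snps=0, passed_bonferroni=False,
                passed_heidi=False, status="ok",
            ),
        ))

    if report.n_probes_tested == 0:
        raise PipelineError("zero testable probes; see drop log")
    threshold = bonferroni_threshold(report.n_probes_tested, config.alpha)
    report.bonferroni_threshold = threshold

    for pa in analyses:
        res = pa.result
        if res.p_smr is None:
            continue
        res.passed_bonferroni = res.p_smr < threshold
        if not res.passed_bonferroni:
            continue
        report.n_passed_bonferroni += 1
        top = next(s for s in pa.harmonized if s.snp_id == res.top_snp)
        heidi_in = select_heidi_snps(
            pa.harmonized, top, panel,
            r2_min=config.r2_min, r2_max=config.r2_max,
            p_eqtl_instrument_max=config.heidi_instrument_p,
            max_snps=config.heidi_max_snps,
        )
        pa.heidi_input = heidi_in
        heidi_res = heidi_test(heidi_in, min_snps=config.heidi_min_snps)
        report.n_heidi_run += 1
        res.p_heidi = heidi_res.p_heidi
        res.n_heidi_snps = heidi_res.n_snps_used
        if heidi_res.p_heidi is not None:
            report.n_heidi_evaluable += 1
            res.passed_heidi = heidi_res.p_heidi >= config.heidi_alpha
            if res.passed_heidi:
                report.n_survivors += 1

    report.n_snps_dropped = len(droplog)
    reasons: dict[str, int] = {}
    for e in droplog:
        reasons[e.reason] = reasons.get(e.reason, 0) + 1
    report.drop_reasons = reasons
    return analyses, droplog, report


def export_effect_pairs(
    analyses: Sequence[ProbeAnalysis], probe_id: str, path: str | Path,
) -> None:
    """Write per-SNP (b_eQTL, b_GWAS) pairs for one probe's effect plot.

    One row per SNP in the probe's harmonized set that entered SMR or
    HEIDI (the top SNP plus the HEIDI instrument set), flagged by role.
    """
    for pa in analyses:
        if pa.probe.probe_id == probe_id:
            break
    else:
        raise KeyError(f"probe {probe_id!r} not in this analysis")
    top_snp = pa.result.top_snp
    heidi_ids = set()
    if pa.heidi_input is not None:
        heidi_ids = {s.snp_id for s in pa.heidi_input.others}
    with open(path, "w") as fh:
        fh.write("snp_id\tb_eqtl\tse_eqtl\tb_gwas\tse_gwas\tis_top\tin_heidi_set\n")
        for s in pa.harmonized:
            if s.snp_id != top_snp and s.snp_id not in heidi_ids:
                continue
            fh.write("\t".join((
                s.snp_id,
                f"{s.b_eqtl:.6e}", f"{s.se_eqtl:.6e}",
                f"{s.b_gwas:.6e}", f"{s.se_gwas:.6e}",
                "1" if s.snp_id == top_snp else "0",
                "1" if s.snp_id in heidi_ids else "0",
            )) + "\n")


def run_analysis(config: AnalysisConfig) -> tuple[list[SmrResult], RunReport]:
    """File-to-file analysis: load inputs, analyze, write all outputs.

    Writes ``smr_results.tsv``, ``drop_log.tsv``, ``run_report.json`` and
    one ``effect_pairs_<probe>.tsv`` per Bonferroni survivor into
    ``config.out_dir``.
    """
    if not (config.gwas_path and config.eqtl_path and config.bfile_prefix
            and config.out_dir):
        raise PipelineError("config must carry gwas/eqtl/bfile/out_dir paths")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gwas_records, gwas_issues = read_gwas(config.gwas_path)
    probes, eqtl_issues = read_eqtl(config.eqtl_path)
    prefix = Path(config.bfile_prefix)
    panel = load_panel(prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
                       prefix.with_suffix(".fam"))

    analyses, droplog, report = analyze(gwas_records, probes, panel, config)
    results = [pa.result for pa in analyses]

    write_results(results, out_dir / "smr_results.tsv")
    write_drop_log(droplog, out_dir / "drop_log.tsv")
    for pa in analyses:
        if pa.result.passed_bonferroni:
            export_effect_pairs(analyses, pa.probe.probe_id,
                                out_dir / f"effect_pairs_{pa.probe.probe_id}.tsv")
    payload = asdict(report)
    payload["n_gwas_rejected_lines"] = len(gwas_issues)
    payload["n_eqtl_rejected_lines"] = len(eqtl_issues)
    (out_dir / "run_report.json").write_text(json.dumps(payload, indent=2) + "\n")
    return results, report
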