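"""Recompute published SMR p-values for three AD-associated genes.

A published scan integrating brain/blood meta-analytic cis-eQTLs with an
AD-by-proxy GWAS printed, for each novel gene, the top SNP's cis-eQTL
and GWAS p-values and the SMR p-value they imply.  Because the SMR
chi-square statistic depends only on the two squared z-scores, those
printed inputs are enough to recompute the result exactly.
"""

from smrkit.worked_examples import comparison_table

print(f"{'gene':<14}{'top SNP':<12}{'p_eQTL':>10}{'p_GWAS':>10}"
      f"{'p_SMR (ours)':>14}{'published':>12}{'rel.err':>9}")
for row in comparison_table():
    print(f"{row['gene']:<14}{row['top_snp']:<12}"
          f"{row['p_eqtl']:>10.2e}{row['p_gwas']:>10.2e}"
          f"{row['p_smr_computed']:>14.3e}{row['p_smr_published']:>12.3e}"
          f"{row['rel_error']:>9.4f}")

print()
print("Each p_SMR tests whether the gene's expression mediates AD risk at")
print("its top cis-eQTL SNP; agreement within ~1% of the published values")
print("(inputs are printed to 3 significant figures) confirms the statistic.")
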