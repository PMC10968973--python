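"""Recompute the published cohort tables from their raw printed counts.

Replicates the cohort-characteristics table (visualizable percentages and
univariable Wald odds ratios) and the subsite-by-age grid from count data
alone.  The headline result: 58.2% of colorectal adenocarcinomas arise in
subsites a sigmoidoscope can reach, rising to ~73% under age 50.
"""

from sigreach.report import replicate_tables

tables = replicate_tables()

print(tables["headline_proportions"].to_string(index=False))
print()
t1 = tables["table1"]
ors = t1.dropna(subset=["uni_or"])
for _, row in ors.iterrows():
    print(
        f"{row['factor']:>15} {row['level']:<12} "
        f"OR {row['uni_or']:.2f} (95% CI {row['uni_ci_low']:.2f}-{row['uni_ci_high']:.2f})"
    )
print("\nORs > 1 mean higher odds of a sigmoidoscopy-visualizable tumor "
      "than the factor's reference level (e.g. ~2.2 for ages 45-49 vs 50+).")
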