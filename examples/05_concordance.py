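"""Cross-contrast sign concordance on the packaged gene tables.

Genes selected in two tissue contrasts are classed by strict sign
agreement of their log2 ratios: concordant (same direction in both),
discordant (opposite directions), or unclassified (any exact zero).
"""

from mahex import concordance_counts
from mahex.fixtures import fixture_tables

t11, t12, t13 = fixture_tables()

r11 = concordance_counts(t11)
print(f"same-trend set: {r11.total} genes -> "
      f"{r11.counts['concordant-up']} up in both contrasts, "
      f"{r11.counts['concordant-down']} down in both")

r13 = concordance_counts(t13)
print(f"opposite-trend set: {r13.total} genes -> "
      f"{r13.counts['discordant']} discordant")

r12 = concordance_counts(t12)
for _, row in r12.table.iterrows():
    print(f"  {row.gene_symbol}: {row.concordance_class} across three contrasts")
# The pairwise sets separate a shared LPS response (concordant genes)
# from region-specific responses (discordant genes).
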