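"""Mid- and high-parent heterosis of the packaged flag-leaf trait table.

Recomputes MPH% and HPH% for every trait of the rice trio (P1 = WFB,
P2 = CHT025, F1 = WFYT025) from the published genotype means and compares
them with the originally printed percentages.
"""

from triohet import hph, mph, table1_phenotypes

table = table1_phenotypes()
print(f"{'trait':<18} {'env':<7} {'tp':<4} {'MPH%':>8} {'printed':>8} {'HPH%':>8} {'printed':>8}")
for _, row in table.iterrows():
    m = mph(row.p1_mean, row.p2_mean, row.f1_mean)
    h = hph(row.p1_mean, row.p2_mean, row.f1_mean)
    flag = f"  <- {row.note}" if row.note else ""
    print(f"{row.trait:<18} {row.environment:<7} {row.timepoint:<4} "
          f"{m:8.1f} {row.mph_printed:8.1f} {h:8.1f} {row.hph_printed:8.1f}{flag}")

# MPH is the hybrid's percent advantage over the parental average, HPH over
# the better parent; positive values mean the hybrid outperforms.  The two
# flagged rows are entries whose printed percentage cannot be reproduced
# from the printed means (suspected misprints in the source table).
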