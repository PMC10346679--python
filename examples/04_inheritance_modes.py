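"""Decompose trio expression into additive and dominance effects.

For each gene, [a] = (P1 - P2)/2 and [d] = F1 - midparent on the
log2(FPKM+1) scale; the potency ratio Hp = [d]/[a] classifies inheritance
as additive, partial dominance, dominance, or over-dominance.
"""

from triohet import TrioSimConfig, breakdown, compute_fpkm, effects_table, generate_trio_counts

config = TrioSimConfig(n_genes=5000, seed=0, dispersion=0.1)
counts, design, truth = generate_trio_counts(config)

effects = effects_table(compute_fpkm(counts), design)  # pools all 12 reps/genotype
print(effects[["a_hat", "d_hat", "hp", "mode"]].head(8).round(3).to_string())

recovered = breakdown(effects)
planted = breakdown(truth.rename(columns={"class": "mode"}))
print("\nmode breakdown (% of genes):")
for mode in recovered.columns:
    print(f"  {mode:<18} recovered {recovered[mode].iloc[0]:5.1f}   planted {planted[mode].iloc[0]:5.1f}")
# The recovered percentages track the planted architecture to within a few
# points; disagreement concentrates near the Hp class boundaries where
# replicate noise can flip a gene into the adjacent class.
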