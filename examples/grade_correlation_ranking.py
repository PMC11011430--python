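"""Rank genes by Pearson correlation of expression with Gleason grade group.

Grade group is treated as an integer score 1-5 over tumor samples; genes are
ranked by |r| with BH-adjusted p-values, mirroring the ranked gene list an
appendix of a cohort study would print.
"""

from gleason_sig import SyntheticConfig, correlate_with_grade, generate_cohort, top_k

config = SyntheticConfig(n_genes=1000, n_planted=30, effect_size=0.5, seed=3)
expr, annotations, truth = generate_cohort(config)

records = correlate_with_grade(expr, annotations)
print("ten genes most correlated with grade group:")
print(records.head(10)[["gene_id", "pearson_r", "q", "rank"]].to_string(index=False))

top20 = top_k(records, 20)
planted = set(truth.planted_gene_ids)
print(f"\nplanted genes in the top 20: {len(planted & set(top20))}/20")
print("positive and negative correlates rank together (|r| ordering), as a")
print("grade signature needs genes moving in both directions")
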