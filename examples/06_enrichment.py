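"""Gene-set over-representation of the DEx genes.

Tests user-supplied gene sets (GMT-style) for enrichment in the DEx
query against the expressed background with the upper-tail
hypergeometric distribution and Benjamini-Hochberg correction.
"""

from pubernet import (
    SimulationConfig,
    generate_expression,
    generate_gene_sets,
    hypergeometric_enrichment,
)

cfg = SimulationConfig(seed=1)
_, _, truth = generate_expression(cfg)
sets = generate_gene_sets(truth, n_sets=10, set_size=15,
                          enriched_overlap=10, seed=2)

res = hypergeometric_enrichment(
    set(truth.de_gene_ids), set(truth.gene_ids), sets
)
print(res.head(3).round(6)[["k", "n", "K", "N", "fold_enrichment",
                            "p_value", "adjusted_p"]])
# SET_ENRICHED carries 10 of the 20 planted DE genes and tops the table
# with a fold enrichment of ~6.7; the uniform background sets sit near
# p = 1.  Adjusted p-values are BH step-up over the 10 tested sets.
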