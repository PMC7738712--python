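"""RPKM noise filtering and PCA sample QC.

Converts a log2 matrix back to RPKM, drops genes whose mean RPKM never
reaches 0.2 in any group (the 'expressed' criterion), and runs PCA-based
outlier detection on a study with one deliberately corrupted sample —
the reproducible analogue of spotting a faulty library in a PCA plot.
"""

from pubernet import (
    ExpressionMatrix,
    SimulationConfig,
    filter_expressed,
    generate_expression,
    pca_outliers,
)

cfg = SimulationConfig(seed=3, corrupt_sample=True)
expr, meta, truth = generate_expression(cfg)

report = pca_outliers(expr, n_components=2, sd_multiplier=3.0)
print(f"variance explained by PC1/PC2: "
      f"{report.variance_explained[0]:.2f} / {report.variance_explained[1]:.2f}")
print(f"flagged outlier samples: {report.outliers}")
# The corrupted sample (PRE1) sits far from the centroid of the first two
# principal-component scores and is the only sample beyond 3 SD.

good = [s for s in expr.sample_ids if s not in set(report.outliers)]
clean = ExpressionMatrix(expr.data[good], scale="log2")
rpkm = ExpressionMatrix(2.0 ** clean.data, scale="rpkm")
groups = meta.loc[good, "group"].to_dict()
kept = filter_expressed(rpkm, groups, threshold=0.2)
print(f"expressed genes after dropping the faulty sample: "
      f"{kept.n_genes} of {expr.n_genes} "
      f"({len(truth.silent_ids)} planted silent genes removed)")
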