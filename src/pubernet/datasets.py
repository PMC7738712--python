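"""Published summary tables from the bovine puberty muscle study.

These are printed, public summary statistics — not raw data — shipped
so the package's arithmetic conventions can be checked against the
source study and so the worked examples run offline:

* :func:`top_de_transcripts` — the study's top differentially expressed
  transcripts: normalized mean expression after (POST) and before (PRE)
  puberty, plus the printed average difference and fold change
  (FC = POST / PRE on the normalized scale).
* :func:`key_tf_roster` — the 48 transcription factors the study
  flagged as key regulators, with their TF family and published
  RIF1/RIF2 z-scores (note the negative entries: the 1.96 cutoff is on
  |z|).

Note: one printed difference (bta-mir-450b: 8.59 - 3.88 printed as
4.70) reflects rounding of the study's unrounded means; recomputation
from the printed means gives 4.71.
"""

from __future__ import annotations

import pandas as pd

_TOP_DE = [
    # gene_id, symbol, post, pre, printed_diff, printed_fc
    ("ENSBTAG00000043574", "ENS43574", 7.19, 1.91, 5.28, 3.76),
    ("ENSBTAG00000025485", "ENS25485", 1.95, 7.12, -5.17, 0.27),
    ("ENSBTAG00000042678", "SNORA71", 2.01, 6.94, -4.93, 0.29),
    ("ENSBTAG00000045039", "SCARNA17", 7.40, 2.55, 4.85, 2.90),
    ("ENSBTAG00000044778", "U6", 2.14, 6.91, -4.77, 0.31),
    ("ENSBTAG00000043695", "bta-mir-450b", 8.59, 3.88, 4.70, 2.21),
    ("ENSBTAG00000031600", "ENS31600", 2.51, 7.06, -4.55, 0.36),
    ("ENSBTAG00000048516", "ENS48156", 8.61, 4.26, 4.35, 2.02),
]

_KEY_TFS = [
    # gene_id, symbol, family, rif1_z, rif2_z
    ("ENSBTAG00000017613", "ZNF419", "zf-C2H2", 4.10, 1.50),
    ("ENSBTAG00000018645", "DLX5", "Homeobox", 4.05, 1.00),
    ("ENSBTAG00000003027", "EMX2", "Homeobox", 3.42, 1.40),
    ("ENSBTAG00000038926", "ENSBTAG00000038926", "zf-C2H2", 3.35, 1.38),
    ("ENSBTAG00000018131", "ATF1", "TF_bZIP", 2.01, 2.68),
    ("ENSBTAG00000002291", "ZBTB41", "ZBTB", 2.51, 1.59),
    ("ENSBTAG00000002690", "BLZF1", "Others", 2.29, 1.76),
    ("ENSBTAG00000017651", "ENSBTAG00000017651", "zf-C2H2", 2.33, 1.70),
    ("ENSBTAG00000024115", "FOXO6", "Fork_head", 2.49, 1.38),
    ("ENSBTAG00000005572", "ZNF205", "zf-C2H2", 2.19, -1.68),
    ("ENSBTAG00000030939", "ZNF575", "zf-C2H2", 2.54, 1.33),
    ("ENSBTAG00000014749", "ZIC4", "zf-C2H2", 2.24, 1.61),
    ("ENSBTAG00000037440", "ENSBTAG00000037440", "zf-C2H2", 2.20, 1.43),
    ("ENSBTAG00000026307", "ZNF629", "zf-C2H2", 2.49, 1.09),
    ("ENSBTAG00000019885", "ZNF280C", "zf-C2H2", 2.62, 0.89),
    ("ENSBTAG00000002201", "NFXL1", "zf-NF-X1", 2.75, 0.67),
    ("ENSBTAG00000012385", "NFX1", "zf-NF-X1", 2.43, -0.99),
    ("ENSBTAG00000026408", "ZNF213", "zf-C2H2", 2.06, 1.36),
    ("ENSBTAG00000012074", "MYB", "MYB", 2.20, 1.13),
    ("ENSBTAG00000040585", "NR6A1", "GCNF-like", 2.20, -1.10),
    ("ENSBTAG00000000054", "SNAPC4", "MYB", 2.27, -0.98),
    ("ENSBTAG00000047405", "ENSBTAG00000047405", "zf-C2H2", -2.08, -1.14),
    ("ENSBTAG00000023938", "CENPA", "Others", 2.51, 0.70),
    ("ENSBTAG00000047499", "IRX2", "Homeobox", 2.07, 1.14),
    ("ENSBTAG00000005734", "GATA6", "zf-GATA", 2.50, 0.53),
    ("ENSBTAG00000005029", "TAL1", "bHLH", 2.27, -0.75),
    ("ENSBTAG00000019707", "GATA2", "zf-GATA", 2.45, -0.56),
    ("ENSBTAG00000014705", "HES4", "bHLH", 2.16, 0.83),
    ("ENSBTAG00000002336", "RCOR1", "MYB", 2.42, -0.56),
    ("ENSBTAG00000033563", "ZNF529", "zf-C2H2", 2.67, -0.30),
    ("ENSBTAG00000037906", "ENSBTAG00000037906", "zf-C2H2", 2.07, -0.88),
    ("ENSBTAG00000015879", "TULP3", "Tub", 2.64, 0.28),
    ("ENSBTAG00000008132", "SOX13", "HMG", 2.81, 0.09),
    ("ENSBTAG00000000195", "ENSBTAG00000000195", "zf-C2H2", 2.62, -0.26),
    ("ENSBTAG00000014265", "SREBF2", "bHLH", 2.25, -0.63),
    ("ENSBTAG00000018270", "NFATC2", "RHD", 2.32, 0.55),
    ("ENSBTAG00000027442", "NFIB", "CTF/NFI", 2.86, 0.00),
    ("ENSBTAG00000011957", "CREBL2", "Others", 2.45, 0.36),
    ("ENSBTAG00000024341", "HOXA6", "Homeobox", 2.14, -0.60),
    ("ENSBTAG00000000625", "SMAD6", "MH1", 2.69, -0.03),
    ("ENSBTAG00000015209", "MXD4", "bHLH", 2.33, 0.28),
    ("ENSBTAG00000010568", "ZBED5", "zf-BED", 2.51, 0.02),
    ("ENSBTAG00000003687", "FOXK2", "Fork_head", -2.00, 0.43),
    ("ENSBTAG00000010130", "ZNF335", "zf-C2H2", 1.99, -0.42),
    ("ENSBTAG00000007983", "ZNF775", "zf-C2H2", 2.28, 0.08),
    ("ENSBTAG00000038034", "ZNF628", "zf-C2H2", 2.05, 0.30),
    ("ENSBTAG00000008695", "TCF3", "bHLH", -2.07, -0.26),
    ("ENSBTAG00000003457", "ATF5", "TF_bZIP", 2.16, 0.16),
]


def top_de_transcripts() -> pd.DataFrame:
    """Top DEx transcripts: published POST/PRE means, difference, FC."""
    return pd.DataFrame(
        _TOP_DE,
        columns=["gene_id", "symbol", "post_mean", "pre_mean",
                 "printed_diff", "printed_fc"],
    ).set_index("gene_id")


def key_tf_roster() -> pd.DataFrame:
    """The study's 48 key TFs with family and published RIF z-scores."""
    return pd.DataFrame(
        _KEY_TFS, columns=["gene_id", "symbol", "family", "rif1_z", "rif2_z"]
    ).set_index("gene_id")


def is_zinc_finger(family: str) -> bool:
    """Zinc-finger TF families carry a ``zf-`` domain prefix."""
    return family.startswith("zf-")
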