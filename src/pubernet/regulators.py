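"""Hub-gene detection and regulatory impact factor (RIF) scoring.

**Hubs.**  A hub is a node whose degree exceeds the network's mean
degree by more than ``sd_multiplier`` population standard deviations.
The dual-network criterion requires this simultaneously in the
co-expression network and in a protein-protein interaction network; a
gene absent from either network cannot be a hub.

**RIF.**  The regulatory impact factor ranks transcription factors by
how strongly their wiring to the differentially expressed (DEx) target
genes changes between the two conditions.  For TF i and DEx gene j,
with POST/PRE group means e1_j, e2_j and within-group Pearson
correlations r1_ij, r2_ij:

    a_j  = (e1_j + e2_j) / 2          (average abundance)
    d_j  = e1_j - e2_j                (differential expression)
    dw_ij = r1_ij - r2_ij             (differential wiring)

    RIF1_i = mean_j [ a_j * d_j * dw_ij**2 ]
    RIF2_i = mean_j [ (e1_j * r1_ij)**2 - (e2_j * r2_ij)**2 ]

RIF1 rewards TFs consistently re-wired to abundant, strongly DEx
targets (the squared dw accumulates opposite-sign rewiring instead of
cancelling; the unsquared variant is available via ``square_dw=False``).
RIF2 rewards TFs whose ability to predict target abundance changes most
between conditions.  Raw scores are z-standardized across TFs (sample
SD, ddof=1); a TF is a key regulator when either |z| exceeds the
threshold (default 1.96).  The absolute value matters: strongly
negative scores are as extreme as strongly positive ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DegreeSummary:
    degrees: pd.Series
    mean: float
    sd: float  # population SD
    threshold: float  # mean + sd_multiplier * sd


def degree_summary(net: nx.Graph, sd_multiplier: float = 2.0) -> DegreeSummary:
    """Degree distribution summary with the hub threshold mean + k*SD."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = pd.Series(dict(net.degree()), dtype=int).sort_index()
    mean = float(deg.mean())
    sd = float(deg.to_numpy().std())  # population SD
    return DegreeSummary(degrees=deg, mean=mean, sd=sd, threshold=mean + sd_multiplier * sd)


def find_hubs(coexp: nx.Graph, ppi: nx.Graph, sd_multiplier: float = 2.0) -> set[str]:
    """Genes exceeding mean + k*SD degree in *both* networks.

    Each network contributes its own mean/SD; only genes present in both
    node sets are eligible.
    """
    out: set[str] | None = None
    for net in (coexp, ppi):
        summ = degree_summary(net, sd_multiplier)
        hubs = set(summ.degrees.index[summ.degrees > summ.threshold])
        out = hubs if out is None else out & hubs
    return out or set()


def _group_stats(
    expr: ExpressionMatrix,
    groups: pd.Series,
    tf_ids: list[str],
    de_ids: list[str],
    label: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-group means (TF, DE) and the TF x DE correlation matrix.

    Zero-variance rows within the group get correlation 0 (logged)."""
    cols = groups.index[groups == label]
    if len(cols) < 3:
        raise ValueError(f"group {label!r} needs >= 3 samples for correlations")
    sub = expr.data[list(cols)]
    tf = sub.loc[tf_ids].to_numpy()
    de = sub.loc[de_ids].to_numpy()
    tf_mean, de_mean = tf.mean(axis=1), de.mean(axis=1)
    tf_c = tf - tf_mean[:, None]
    de_c = de - de_mean[:, None]
    tf_sd = tf_c.std(axis=1, ddof=1)
    de_sd = de_c.std(axis=1, ddof=1)
    for name, sds, ids in (("TF", tf_sd, tf_ids), ("target", de_sd, de_ids)):
        flat = [i for i, s in zip(ids, sds) if s == 0]
        if flat:
            logger.warning(
                "zero-variance %s gene(s) in group %s, correlations set to 0: %s",
                name, label, flat[:5],
            )
    m = len(cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tf_c @ de_c.T) / (m - 1) / np.outer(tf_sd, de_sd)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    r = np.clip(r, -1.0, 1.0)
    return tf_mean, de_mean, r, de_sd


def rif(
    expr: ExpressionMatrix,
    groups: pd.Series | dict,
    tf_ids: Iterable[str],
    de_ids: Iterable[str],
    threshold: float = 1.96,
    square_dw: bool = True,
) -> pd.DataFrame:
    """RIF1/RIF2 scores for every TF against the DEx target genes.

    Returns a DataFrame indexed by TF with columns ``rif1_raw``,
    ``rif2_raw``, ``rif1_z``, ``rif2_z``, ``key_flag``.  A TF that is
    itself DEx is scored as a TF and kept as a target for the other
    TFs, but never used as its own target.
    """
    tf_ids = [t for t in tf_ids if t in set(expr.gene_ids)]
    de_ids = [d for d in de_ids if d in set(expr.gene_ids)]
    if not de_ids:
        raise ValueError("no DEx target genes")
    if not tf_ids:
        raise ValueError("no TFs to score")
    g = pd.Series(groups).reindex(expr.sample_ids)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")

    e1_tf, e1, r1, _ = _group_stats(expr, g, tf_ids, de_ids, "POST")
    e2_tf, e2, r2, _ = _group_stats(expr, g, tf_ids, de_ids, "PRE")

    a = (e1 + e2) / 2.0
    d = e1 - e2
    dw = r1 - r2
    dw_term = dw**2 if square_dw else dw
    # mask self-targeting (TF also in the DEx list)
    self_mask = np.zeros((len(tf_ids), len(de_ids)), dtype=bool)
    de_pos = {gid: j for j, gid in enumerate(de_ids)}
    for i, t in enumerate(tf_ids):
        if t in de_pos:
            self_mask[i, de_pos[t]] = True
    n_targets = len(de_ids) - self_mask.sum(axis=1)

    rif1_terms = a[None, :] * d[None, :] * dw_term
    rif2_terms = (e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2
    rif1_terms = np.where(self_mask, 0.0, rif1_terms)
    rif2_terms = np.where(self_mask, 0.0, rif2_terms)
    rif1 = rif1_terms.sum(axis=1) / n_targets
    rif2 = rif2_terms.sum(axis=1) / n_targets

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z1, z2 = zscore(rif1), zscore(rif2)
    out = pd.DataFrame(
        {
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": z1,
            "rif2_z": z2,
            "key_flag": np.maximum(np.abs(z1), np.abs(z2)) > threshold,
        },
        index=pd.Index(tf_ids, name="tf_id"),
    )
    return out


def key_regulators(scores: pd.DataFrame, threshold: float = 1.96) -> set[str]:
    """TFs whose RIF1 or RIF2 z-score exceeds ``threshold`` in absolute
    value (a z of -2.07 is as extreme as +2.07)."""
    z = scores[["rif1_z", "rif2_z"]].abs().max(axis=1)
    return set(scores.index[z > threshold])


def classify_tf_family(
    tf_ids: Iterable[str], family_table: Mapping[str, str]
) -> pd.DataFrame:
    """Count TFs per family; unknown TFs fall under ``unannotated``.

    Returns a DataFrame with columns ``count`` and ``fraction`` indexed
    by family name, sorted by descending count.
    """
    tf_ids = list(tf_ids)
    if not tf_ids:
        return pd.DataFrame(columns=["count", "fraction"]).rename_axis("family")
    fams = pd.Series([family_table.get(t, "unannotated") for t in tf_ids])
    counts = fams.value_counts()
    out = pd.DataFrame({"count": counts, "fraction": counts / len(tf_ids)})
    out.index.name = "family"
    return out
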