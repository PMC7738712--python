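"""Query-versus-background over-representation testing.

Given a query gene list (e.g. the DEx genes), a background list (all
expressed genes) and a GMT collection of gene sets, each set is tested
with the one-sided (upper-tail) hypergeometric distribution:

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

with N the background size, K the background members of the set, n the
query size and k the query members of the set.  Raw p-values are
corrected with the Benjamini-Hochberg step-up procedure.  An optional
EASE-style conservative variant scores k - 1 hits instead of k.
Depletion is deliberately not tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def hypergeometric_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of each gene set in the query list.

    Set members are intersected with the background before testing.
    Returns a DataFrame sorted by raw p-value with columns ``k`` (query
    hits), ``n`` (query size), ``K`` (background hits), ``N``
    (background size), ``fold_enrichment`` = (k/n)/(K/N), ``p_value``
    and ``adjusted_p``.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    stray = query - background
    if stray:
        raise ValueError(f"query gene(s) not in background: {sorted(stray)[:5]}")
    n, N = len(query), len(background)
    rows = []
    for name, members in sets.items():
        inset = set(members) & background
        K = len(inset)
        k = len(inset & query)
        shift = 2 if ease and k >= 1 else 1
        p = float(stats.hypergeom.sf(k - shift, N, K, n)) if K else 1.0
        fe = (k / n) / (K / N) if K else float("nan")
        rows.append(
            {"set": name, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fe, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["adjusted_p"] = bh_adjust(out["p_value"].tolist())
    return out.sort_values("p_value", kind="stable")
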