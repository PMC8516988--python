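"""Gene-set over-representation analysis (Fisher exact / hypergeometric).

Given a hit list (e.g. significantly hypo-methylated genes), a background
universe (all genes measurable on the array after QC filtering) and named
gene sets from a GMT file, each set is scored with the one-sided
hypergeometric upper-tail probability — identical to the one-sided Fisher
exact test on the 2x2 membership table — and the enrichment score
``-log10(p)``. Only over-representation is tested; depletion is not scored.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

ENRICHMENT_COLUMNS = [
    "term_id", "category", "n_hits_in_set", "set_size",
    "n_hits", "background_size", "p", "score",
]

CATEGORIES = ("BP", "CC", "MF", "pathway", "custom")


def _infer_category(term_id: str) -> str:
    head = term_id.split(":", 1)[0].split("_", 1)[0]
    return head if head in CATEGORIES else "custom"


def fisher_enrichment(
    hits: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One record per gene set with the one-sided enrichment p and score.

    Gene sets are intersected with the background before testing, so genes
    the array cannot measure never count. With overlap k, set size K, hit
    count m and background size M the p-value is
    ``P[X >= k]`` for ``X ~ Hypergeometric(M, K, m)``. Records are ordered by
    (p, term_id). Hits outside the background raise an error listing them.
    """
    hits = set(hits)
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    stray = sorted(hits - background)
    if stray:
        raise ValueError(f"hit(s) not in background: {stray[:10]}")

    m, big_m = len(hits), len(background)
    records = []
    for term_id in gene_sets:
        members = set(gene_sets[term_id]) & background
        k = len(members & hits)
        big_k = len(members)
        p = float(sps.hypergeom.sf(k - 1, big_m, big_k, m)) if big_k else 1.0
        p = min(p, 1.0)
        if categories is not None:
            category = categories.get(term_id, "custom")
        else:
            category = _infer_category(term_id)
        records.append(
            {
                "term_id": term_id,
                "category": category,
                "n_hits_in_set": k,
                "set_size": big_k,
                "n_hits": m,
                "background_size": big_m,
                "p": p,
                "score": float(-np.log10(p)) if p > 0 else np.inf,
            }
        )
    table = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS)
    return table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def top_terms(records: pd.DataFrame, n: int = 10, per_category: bool = False) -> pd.DataFrame:
    """Lowest-p ``n`` terms, overall or per category, ties broken by term id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = records.sort_values(["p", "term_id"], kind="mergesort")
    if per_category:
        return ordered.groupby("category", group_keys=False, sort=False).head(n).reset_index(drop=True)
    return ordered.head(n).reset_index(drop=True)
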