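"""Gene-set over-representation analysis (hypergeometric ORA).

Standing in for GO/KEGG enrichment of a differential gene list: for each set
in a GMT collection, the upper-tail hypergeometric probability of observing
at least the seen overlap between the query and the set, given the universe
of expressed genes. Benjamini-Hochberg q-values are reported alongside, but
the significance flag follows the raw-p criterion common in this literature
(p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentRecord:
    """One set's overlap test: k of n query genes hit a set of K in universe N."""

    set_id: str
    set_size: int        # K (after intersection with the universe)
    universe_size: int   # N
    query_size: int      # n
    overlap: int         # k
    pvalue: float        # P(X >= k), hypergeometric
    qvalue: float        # BH-adjusted
    significant: bool    # raw p < p_cut


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts marked items (from K marked of N total) in a draw of n without
    replacement. Computed via the survival function in log-stable form;
    k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent arguments k={k}, K={K}, n={n}, N={N}: need "
            "0 <= k <= min(K, n) and K, n <= N")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    pvals = list(pvalues)
    if not pvals:
        return []
    if any((p < 0 or p > 1) for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(q) for q in qvals]


def ora(query: set[str], universe: set[str], collection: dict[str, set[str]],
        p_cut: float = 0.05) -> list[EnrichmentRecord]:
    """Test every gene set for over-representation of the query.

    Query genes outside the universe are clipped (with a warning); each set
    is intersected with the universe before testing. Records are sorted by
    p-value (ties by set id).
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were clipped",
            stacklevel=2)
        query = query & universe

    N = len(universe)
    n = len(query)
    ids = sorted(collection)
    rows = []
    for sid in ids:
        members = collection[sid] & universe
        K = len(members)
        k = len(members & query)
        rows.append((sid, K, k, hypergeom_upper(k, K, n, N)))
    qvals = bh_adjust([r[3] for r in rows])
    records = [
        EnrichmentRecord(set_id=sid, set_size=K, universe_size=N, query_size=n,
                         overlap=k, pvalue=p, qvalue=q, significant=p < p_cut)
        for (sid, K, k, p), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (r.pvalue, r.set_id))
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in records],
        columns=["set_id", "set_size", "universe_size", "query_size",
                 "overlap", "pvalue", "qvalue", "significant"],
    )
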