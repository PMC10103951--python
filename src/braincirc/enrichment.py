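"""Over-representation analysis of circRNA host genes.

One-sided Fisher's exact test per gene set or disease: with a universe of N
genes, a set of K, a query of n and an intersection of k, the p-value is the
hypergeometric upper tail P(X >= k); the odds ratio comes from the 2x2 table
[[k, K-k], [n-k, N-K-n+k]].  Multiple testing is controlled with
Benjamini-Hochberg, and near-duplicate significant terms are slimmed by
greedy Jaccard filtering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

BRAIN_MESH_CLASSES = frozenset({"C10", "F03"})


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return a * d / (b * c)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    query_genes, sets: dict[str, tuple[str, tuple[str, ...]]], universe_genes
) -> pd.DataFrame:
    """Over-representation of the query in each gene set, rows sorted by p.

    Sets are intersected with the universe before testing; the returned table
    carries the intersected member tuple for downstream slimming.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    offenders = sorted(query - universe)
    if offenders:
        raise ValidationError(f"query genes outside universe: {offenders}")
    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(sets):
        desc, members = sets[set_id]
        in_universe = sorted(universe.intersection(members))
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query.intersection(in_universe))
        rows.append(
            {
                "set_id": set_id,
                "description": desc,
                "k": k, "K": K, "n": n, "N": N,
                "odds_ratio": _odds_ratio(k, K, n, N),
                "p": hypergeom_upper_tail(k, N, K, n),
                "members": tuple(in_universe),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = bh_fdr(table["p"])
    table = table.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return table


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def slim_terms(rows: pd.DataFrame, jaccard_threshold: float = 0.7) -> pd.DataFrame:
    """Greedy redundancy filter over p-sorted enrichment rows.

    Keeps the most significant row, then drops any later row whose member-gene
    Jaccard similarity with an already-kept row exceeds the threshold.
    Deterministic: ties in p are broken by set_id.
    """
    if rows.empty:
        return rows
    ordered = rows.sort_values(["p", "set_id"], kind="mergesort")
    kept_members: list[tuple[str, ...]] = []
    kept_idx = []
    for idx, row in ordered.iterrows():
        if all(jaccard(row["members"], m) <= jaccard_threshold for m in kept_members):
            kept_idx.append(idx)
            kept_members.append(row["members"])
    return ordered.loc[kept_idx].reset_index(drop=True)


def disease_enrich(
    host_genes_by_group: dict[str, set],
    gda: pd.DataFrame,
    universe_genes,
    brain_only: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of each disease's gene set in each group's host genes.

    ``gda`` must already be filtered at the association-score threshold.  With
    ``brain_only`` the disease universe is restricted to nervous-system (MeSH
    C10) and mental-disorder (F03) classes.  BH correction is applied across
    diseases within each cell group.  Diseases with no genes left in the
    universe are skipped.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValidationError("empty gene universe")
    table = gda
    if brain_only:
        table = table[
            table["mesh_classes"].map(lambda s: bool(BRAIN_MESH_CLASSES & set(s)))
        ]
    disease_genes: dict[tuple[str, str], set] = {}
    for _, row in table.iterrows():
        key = (row["disease_id"], row["disease_name"])
        disease_genes.setdefault(key, set()).add(row["gene_id"])

    frames = []
    N = len(universe)
    for group in sorted(host_genes_by_group):
        query = set(host_genes_by_group[group])
        offenders = sorted(query - universe)
        if offenders:
            raise ValidationError(
                f"group {group!r} host genes outside universe: {offenders}"
            )
        n = len(query)
        rows = []
        for (did, dname) in sorted(disease_genes):
            members = disease_genes[(did, dname)] & universe
            K = len(members)
            if K == 0:
                continue
            k = len(query & members)
            rows.append(
                {
                    "group": group,
                    "disease_id": did,
                    "disease_name": dname,
                    "k": k, "K": K, "n": n, "N": N,
                    "odds_ratio": _odds_ratio(k, K, n, N),
                    "p": hypergeom_upper_tail(k, N, K, n),
                }
            )
        sub = pd.DataFrame(rows)
        if not sub.empty:
            sub["q"] = bh_fdr(sub["p"])
        frames.append(sub)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "p", "disease_id"], kind="mergesort").reset_index(
        drop=True
    )
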