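"""Over-representation analysis of hit lists against a detected-feature
reference, in the style of the PANTHER tool: for each gene set, the number
of hits expected under uniform sampling from the reference is n*K/N, the
fold enrichment is observed/expected, and the p-value is a one-sided
binomial tail (upper tail for over-represented sets, lower tail for
fold-enrichment below 1). Redundant overlapping terms can be merged by
single-linkage clustering on Jaccard similarity of their member sets.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .datamodel import GeneSetCollection
from .diffexp import bh_adjust

log = logging.getLogger(__name__)


def binomial_ora(hit_list, reference, sets: GeneSetCollection,
                 correct_fdr: bool = True, test: str = "binomial",
                 tail: str = "auto") -> pd.DataFrame:
    """Over/under-representation of each gene set in ``hit_list``.

    Parameters
    ----------
    hit_list, reference
        Feature ids; the hit list must be a subset of the reference (the
        reference is every feature detected in the experiment).
    correct_fdr
        Add a Benjamini-Hochberg ``fdr`` column (both corrected and raw
        modes are legitimate reporting choices).
    test
        ``"binomial"`` (default) or ``"hypergeometric"`` for the exact
        urn-model alternative.
    tail
        ``"auto"`` (default) reports the upper tail P(X >= k) for sets at or
        above expectation and the lower tail P(X <= k) for sets below it
        (under-representation rows carry fold_enrichment < 1). ``"over"`` /
        ``"under"`` force one fixed one-sided tail for every set, which is
        the calibrated choice when only one direction is of interest.

    Returns a DataFrame with one row per testable set: term, category, n, N,
    K, k, expected, fold_enrichment, p_value[, fdr], members (the set
    restricted to the reference, for downstream merging).
    """
    if test not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown test {test!r}")
    if tail not in ("auto", "over", "under"):
        raise ValueError(f"unknown tail {tail!r}")
    hits = set(map(str, hit_list))
    ref = set(map(str, reference))
    stray = hits - ref
    if stray:
        raise ValueError(f"hit list contains ids absent from the reference: "
                         f"{sorted(stray)[:5]}")
    n, N = len(hits), len(ref)
    rows = []
    for s in sets:
        members = frozenset(s.members) & ref
        K = len(members)
        if K == 0:
            log.info("skipping set %r: no members in the reference", s.name)
            continue
        k = len(members & hits)
        expected = n * K / N
        fe = k / expected if expected > 0 else np.nan
        upper = fe >= 1 if tail == "auto" else tail == "over"
        if test == "binomial":
            p = float(binom.sf(k - 1, n, K / N)) if upper \
                else float(binom.cdf(k, n, K / N))
        else:
            p = float(hypergeom.sf(k - 1, N, K, n)) if upper \
                else float(hypergeom.cdf(k, N, K, n))
        rows.append({"term": s.name, "category": s.category, "n": n, "N": N,
                     "K": K, "k": k, "expected": expected,
                     "fold_enrichment": fe, "p_value": min(p, 1.0),
                     "members": members})
    df = pd.DataFrame(rows, columns=["term", "category", "n", "N", "K", "k",
                                     "expected", "fold_enrichment", "p_value",
                                     "members"])
    if correct_fdr and len(df):
        df.insert(df.columns.get_loc("p_value") + 1, "fdr",
                  bh_adjust(df["p_value"].to_numpy()))
    return df


def merge_redundant_terms(rows: pd.DataFrame,
                          jaccard_min: float = 0.5) -> pd.DataFrame:
    """Merge overlapping terms by single-linkage on Jaccard similarity.

    Terms whose reference-restricted member sets have Jaccard similarity
    >= ``jaccard_min`` join the same cluster (transitively). Each merged row
    is named after its most significant member and reports the mean, min and
    max fold enrichment and the mean significance over members.
    """
    if rows.empty:
        return pd.DataFrame(columns=["merged_name", "member_terms", "n_members",
                                     "mean_fold_enrichment", "min_fold_enrichment",
                                     "max_fold_enrichment", "mean_significance",
                                     "members"])
    members = [frozenset(m) for m in rows["members"]]
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            inter = len(members[i] & members[j])
            if inter == 0:
                continue
            union = len(members[i] | members[j])
            if inter / union >= jaccard_min:
                parent[find(i)] = find(j)

    sig_col = "fdr" if "fdr" in rows.columns else "p_value"
    clusters: dict[int, list[int]] = {}
    for i in range(len(rows)):
        clusters.setdefault(find(i), []).append(i)
    merged = []
    for idx in clusters.values():
        sub = rows.iloc[idx]
        best = sub.loc[sub["p_value"].idxmin()]
        merged.append({
            "merged_name": best["term"],
            "member_terms": tuple(sub["term"]),
            "n_members": len(sub),
            "mean_fold_enrichment": float(sub["fold_enrichment"].mean()),
            "min_fold_enrichment": float(sub["fold_enrichment"].min()),
            "max_fold_enrichment": float(sub["fold_enrichment"].max()),
            "mean_significance": float(sub[sig_col].mean()),
            "members": frozenset().union(*[members[i] for i in idx]),
        })
    out = pd.DataFrame(merged).sort_values("mean_significance",
                                           kind="stable", ignore_index=True)
    return out


def filter_relevance(rows: pd.DataFrame, blocklist) -> pd.DataFrame:
    """Drop rows whose term matches any blocklist pattern (case-insensitive
    regex search); removals are logged. Used to strip terms irrelevant to
    the assayed cell type."""
    if rows.empty or not blocklist:
        return rows.copy()
    name_col = "merged_name" if "merged_name" in rows.columns else "term"
    patterns = [re.compile(p, re.IGNORECASE) for p in blocklist]
    drop = rows[name_col].map(
        lambda t: any(p.search(t) for p in patterns)).to_numpy(bool)
    for t in rows.loc[drop, name_col]:
        log.info("removed term %r (blocklist)", t)
    return rows.loc[~drop].reset_index(drop=True)
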