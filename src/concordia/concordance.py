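"""Transcript-protein concordance statistics over functional gene sets.

This is the analytical core: after a per-cohort detection filter, each
feature is classified by its fold-change; per set and per ome, a two-sample
proportion test (pooled z with continuity correction, the classic R
``prop.test`` convention) asks whether up- and downregulated members are
balanced, and a one-sample t-test against 1 asks whether the magnitude of
the fold-changes departs from no change. Comparing the per-ome calls
classifies each set's transcript-protein coupling as concordant or
discordant.

Two denominator conventions are used on purpose: set-level tests compare
n_up vs n_down each out of n_up + n_down, while the global (whole-ome) test
compares the up- and down-counts each out of the total number of detected
features.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm, ttest_1samp

from .datamodel import GeneSetCollection

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
MIXED = "mixed"
NONE = "none"

CONCORDANT_UP = "concordant_up"
CONCORDANT_DOWN = "concordant_down"
DISCORDANT_T_DOWN_P_UP = "discordant_t_down_p_up"
DISCORDANT_T_UP_P_DOWN = "discordant_t_up_p_down"
UNDETERMINED = "undetermined"

_COUPLING_LOOKUP = {
    (DOWN, UP): DISCORDANT_T_DOWN_P_UP,
    (UP, DOWN): DISCORDANT_T_UP_P_DOWN,
    (UP, UP): CONCORDANT_UP,
    (DOWN, DOWN): CONCORDANT_DOWN,
}


def min_detection_filter(detection: pd.DataFrame,
                         min_per_group: int = 5) -> pd.Index:
    """Feature ids detected in at least ``min_per_group`` samples of each
    cohort. ``detection`` carries n_detected_case / n_detected_control."""
    keep = ((detection["n_detected_case"] >= min_per_group)
            & (detection["n_detected_control"] >= min_per_group))
    return detection.index[keep]


def classify_direction(fold_change: float, up_cut: float = 1.1,
                       down_cut: float = 0.9) -> str:
    """Three-way abundance call: up above ``up_cut``, down below
    ``down_cut``, otherwise unchanged. Inequalities are strict, so a
    fold-change exactly at a cut is unchanged."""
    if not fold_change > 0:
        raise ValueError("fold_change must be positive")
    if fold_change > up_cut:
        return UP
    if fold_change < down_cut:
        return DOWN
    return UNCHANGED


def classify_directions(fold_changes, up_cut: float = 1.1,
                        down_cut: float = 0.9) -> pd.Series:
    fc = pd.Series(fold_changes, dtype=float)
    if (fc <= 0).any():
        raise ValueError("fold_change must be positive")
    out = pd.Series(UNCHANGED, index=fc.index, dtype=object)
    out[fc > up_cut] = UP
    out[fc < down_cut] = DOWN
    return out


def two_sample_prop_test(x1: int, x2: int, n1: int, n2: int,
                         continuity: bool = True) -> float:
    """Two-sided pooled two-proportion z-test, optionally with the Yates
    continuity correction (equivalent to the corrected chi-square test on
    the 2x2 table).

    With pooled proportion p = (x1+x2)/(n1+n2), the statistic is
    z = (|x1/n1 - x2/n2| - c) / sqrt(p(1-p)(1/n1 + 1/n2)) where the
    continuity term c = (1/n1 + 1/n2)/2; the numerator is floored at 0. A
    degenerate pooled proportion (0 or 1) yields p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n with n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    c = (1 / n1 + 1 / n2) / 2 if continuity else 0.0
    num = max(abs(x1 / n1 - x2 / n2) - c, 0.0)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(min(2 * norm.sf(num / se), 1.0))


def set_direction_test(fold_changes) -> tuple[int, int, float]:
    """(n_up, n_down, proportion-test p) for one set's member fold-changes.

    Members with fold-change above 1 count as up, below 1 as down (exactly
    1 counts in neither). The two arms are compared each out of
    n_up + n_down. No members either side gives p = NaN.
    """
    fc = np.asarray(list(fold_changes), dtype=float)
    n_up = int((fc > 1).sum())
    n_down = int((fc < 1).sum())
    total = n_up + n_down
    if total == 0:
        return n_up, n_down, float("nan")
    return n_up, n_down, two_sample_prop_test(n_up, n_down, total, total)


def set_magnitude_test(fold_changes) -> tuple[float, float, float]:
    """(mean_fc_up, mean_fc_down, magnitude p) for one set.

    The magnitude test is a two-sided one-sample t-test of all member
    fold-changes against 1; fewer than two members or zero variance gives
    NaN. Means are reported separately for the up (FC > 1) and down
    (FC < 1) members.
    """
    fc = np.asarray(list(fold_changes), dtype=float)
    up, down = fc[fc > 1], fc[fc < 1]
    mean_up = float(up.mean()) if up.size else float("nan")
    mean_down = float(down.mean()) if down.size else float("nan")
    if fc.size < 2 or np.ptp(fc) == 0:
        return mean_up, mean_down, float("nan")
    p = float(ttest_1samp(fc, 1.0).pvalue)
    return mean_up, mean_down, p


def global_direction_test(n_up: int, n_down: int, n_total: int) -> float:
    """Whole-ome balance test: up- and down-counts each measured against
    the full detected population of ``n_total`` features."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_up + n_down > n_total:
        raise ValueError("n_up + n_down exceeds n_total")
    return two_sample_prop_test(n_up, n_down, n_total, n_total)


def concordance_table(de: pd.DataFrame, sets: GeneSetCollection, ome: str,
                      min_detect: int = 5) -> pd.DataFrame:
    """Per-set direction and magnitude statistics for one ome.

    ``de`` is a differential-expression table (fold_change plus detection
    counts, indexed by feature id). Members failing the per-cohort detection
    filter are excluded before counting.
    """
    retained = set(min_detection_filter(de, min_per_group=min_detect))
    rows = []
    for s in sets:
        ids = [m for m in sorted(s.members) if m in retained]
        fc = de.loc[ids, "fold_change"].to_numpy(float) if ids else np.array([])
        n_up, n_down, prop_p = set_direction_test(fc) if ids else (0, 0, float("nan"))
        mean_up, mean_down, mag_p = (set_magnitude_test(fc) if ids
                                     else (float("nan"),) * 3)
        rows.append({"set_name": s.name, "ome": ome, "n_detected": len(ids),
                     "n_up": n_up, "n_down": n_down,
                     "mean_fc_up": mean_up, "mean_fc_down": mean_down,
                     "prop_p": prop_p, "magnitude_p": mag_p})
    return pd.DataFrame(rows)


def _ome_call(row: pd.Series | None, alpha: float) -> str:
    if row is None:
        return NONE
    prop_p, n_up, n_down = row["prop_p"], row["n_up"], row["n_down"]
    if n_up + n_down == 0 or not np.isfinite(prop_p):
        return NONE
    if prop_p <= alpha and n_up > n_down:
        return UP
    if prop_p <= alpha and n_down > n_up:
        return DOWN
    return MIXED


def classify_coupling(transcript_row: pd.Series | None,
                      protein_row: pd.Series | None,
                      alpha: float = 0.05) -> dict:
    """Coupling call for one set from its two per-ome concordance rows.

    Each ome is called up/down when its proportion test is significant at
    ``alpha`` and the majority points that way, otherwise mixed (or none if
    the row is missing/untestable); the pair maps to
    concordant_up/concordant_down/discordant_* or undetermined.
    """
    t_call = _ome_call(transcript_row, alpha)
    p_call = _ome_call(protein_row, alpha)
    name = None
    for row in (transcript_row, protein_row):
        if row is not None:
            name = row["set_name"]
    return {"set_name": name, "transcript_call": t_call,
            "protein_call": p_call,
            "coupling": _COUPLING_LOOKUP.get((t_call, p_call), UNDETERMINED)}


def coupling_table(transcript_conc: pd.DataFrame, protein_conc: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    t_by = {r["set_name"]: r for _, r in transcript_conc.iterrows()}
    p_by = {r["set_name"]: r for _, r in protein_conc.iterrows()}
    names = list(dict.fromkeys(list(t_by) + list(p_by)))
    return pd.DataFrame([
        classify_coupling(t_by.get(n), p_by.get(n), alpha=alpha) for n in names
    ])


def _ome_summary(de: pd.DataFrame) -> dict:
    n_total = len(de)
    n_up = int(((de["direction"] == UP)).sum())
    n_down = int(((de["direction"] == DOWN)).sum())
    return {
        "n_detected": n_total,
        "n_significant_up": n_up,
        "n_significant_down": n_down,
        "pct_up": round(100 * n_up / n_total) if n_total else 0,
        "pct_down": round(100 * n_down / n_total) if n_total else 0,
        "global_prop_p": global_direction_test(n_up, n_down, n_total)
        if n_total else float("nan"),
    }


def build_summary(de_transcript: pd.DataFrame, de_protein: pd.DataFrame,
                  sets: GeneSetCollection, alpha: float = 0.05,
                  min_detect: int = 5, up_cut: float = 1.1,
                  down_cut: float = 0.9) -> dict:
    """Assemble the full concordance report bundle.

    Returns a dict with per-ome global counts/percentages and proportion
    tests, the per-set concordance tables for both omes, the coupling table,
    and the thresholds used.
    """
    groups = GeneSetCollection(sets.by_category("functional_group")) \
        if sets.by_category("functional_group") else sets
    conc_t = concordance_table(de_transcript, groups, "transcript",
                               min_detect=min_detect)
    conc_p = concordance_table(de_protein, groups, "protein",
                               min_detect=min_detect)
    coupling = coupling_table(conc_t, conc_p, alpha=alpha)
    union = frozenset().union(*[s.members for s in groups]) if len(groups) else frozenset()
    return {
        "thresholds": {"alpha": alpha, "min_detect": min_detect,
                       "up_cut": up_cut, "down_cut": down_cut},
        "transcript": _ome_summary(de_transcript),
        "protein": _ome_summary(de_protein),
        "set_union_transcript": set_union_direction_summary(
            de_transcript, union, up_cut, down_cut, min_detect),
        "set_union_protein": set_union_direction_summary(
            de_protein, union, up_cut, down_cut, min_detect),
        "concordance_transcript": conc_t,
        "concordance_protein": conc_p,
        "coupling": coupling,
    }


def set_union_direction_summary(de: pd.DataFrame, members, up_cut: float = 1.1,
                                down_cut: float = 0.9,
                                min_detect: int = 5) -> dict:
    """Venn-style counts for the union of a set collection (e.g. all
    mitochondrial features): detected members after the per-cohort filter,
    how many are up (> up_cut) or down (< down_cut), and the proportion
    test of those counts against the detected-member total."""
    retained = min_detection_filter(de, min_per_group=min_detect)
    ids = [m for m in sorted(members) if m in set(retained)]
    if not ids:
        return {"n_detected": 0, "n_up": 0, "n_down": 0,
                "prop_p": float("nan")}
    cls = classify_directions(de.loc[ids, "fold_change"], up_cut, down_cut)
    n_up, n_down = int((cls == UP).sum()), int((cls == DOWN).sum())
    return {"n_detected": len(ids), "n_up": n_up, "n_down": n_down,
            "prop_p": global_direction_test(n_up, n_down, len(ids))}
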