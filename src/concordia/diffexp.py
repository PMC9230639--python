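"""Per-feature differential expression for each ome.

Proteins: Welch t-tests on log intensities of detected values, linear
fold-changes from raw group means, Benjamini-Hochberg q-values, significance
at q <= alpha. Features not detected at all in either cohort are excluded
before testing.

Transcripts: TMM scaling-factor normalization (trimmed mean of M-values
against a reference sample), a common negative-binomial dispersion estimated
by method of moments, and a conditional exact test on the two group totals.
A gene is called significant when q <= alpha AND the linear fold-change is
at least ``fc_min`` in either direction (default 2).

FDR families are per ome: transcripts and proteins are corrected separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata, ttest_ind

from .datamodel import PROTEIN, TRANSCRIPT, CohortDesign, ExpressionMatrix

UP = "up"
DOWN = "down"
NONE = "none"

#: pseudocount used for transcript fold-changes only, never for testing
FC_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorts ascending, takes q_(i) = min_{j>=i} p_(j) * m / j capped at 1, and
    returns q in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# detection

def detection_counts(matrix: ExpressionMatrix, design: CohortDesign) -> pd.DataFrame:
    """Per-feature detection counts (n_detected_case, n_detected_control).

    A protein is detected in a sample when its intensity is non-missing; a
    transcript when its read count is > 0.
    """
    design.validate_against(matrix)
    out = {}
    for label, samples in (("n_detected_case", design.case_samples),
                           ("n_detected_control", design.control_samples)):
        sub = matrix.values[[s for s in samples if s in matrix.values.columns]]
        if matrix.ome == PROTEIN:
            out[label] = sub.notna().sum(axis=1)
        else:
            out[label] = (sub > 0).sum(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# proteins

def protein_de(matrix: ExpressionMatrix, design: CohortDesign,
               alpha: float = 0.05, log_transform: bool = True,
               equal_var: bool = False) -> pd.DataFrame:
    """Differential expression of protein intensities.

    Fold-change is the ratio of the detected-sample means (case/control).
    The t-test (Welch by default; ``equal_var=True`` for the pooled variant)
    runs on log intensities unless ``log_transform=False``. Features with
    zero detections in either cohort are dropped; features with fewer than
    two detected values in a group are reported with p = q = 1 and are not
    part of the FDR family.
    """
    if matrix.ome != PROTEIN:
        raise ValueError("protein_de expects a protein matrix")
    design.validate_against(matrix)
    det = detection_counts(matrix, design)
    keep = (det["n_detected_case"] > 0) & (det["n_detected_control"] > 0)
    values = matrix.values.loc[keep]
    det = det.loc[keep]

    case = values[design.case_samples].to_numpy(float)
    ctrl = values[design.control_samples].to_numpy(float)
    mean_case = np.nanmean(case, axis=1)
    mean_ctrl = np.nanmean(ctrl, axis=1)
    fold_change = mean_case / mean_ctrl

    a, b = (np.log(case), np.log(ctrl)) if log_transform else (case, ctrl)
    testable = ((det["n_detected_case"] >= 2)
                & (det["n_detected_control"] >= 2)).to_numpy()
    p = np.ones(len(values))
    if testable.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = ttest_ind(a[testable], b[testable], axis=1,
                            equal_var=equal_var, nan_policy="omit")
        pt = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: p=1 when the means agree, else 0
        nan_mask = np.isnan(pt)
        if nan_mask.any():
            same = np.isclose(np.nanmean(a[testable], axis=1),
                              np.nanmean(b[testable], axis=1))
            pt[nan_mask] = np.where(same[nan_mask], 1.0, 0.0)
        p[testable] = pt
    q = np.ones(len(values))
    if testable.any():
        q[testable] = bh_adjust(p[testable])

    significant = q <= alpha
    direction = np.where(~significant, NONE, np.where(fold_change > 1, UP, DOWN))
    return pd.DataFrame({
        "mean_case": mean_case,
        "mean_control": mean_ctrl,
        "fold_change": fold_change,
        "p_value": p,
        "q_value": q,
        "significant": significant,
        "n_detected_case": det["n_detected_case"].to_numpy(),
        "n_detected_control": det["n_detected_control"].to_numpy(),
        "direction": direction,
    }, index=values.index.rename("feature_id"))


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(matrix: ExpressionMatrix | pd.DataFrame,
                log_ratio_trim: float = 0.30,
                abs_expr_trim: float = 0.05,
                weighted: bool = True) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions. For each sample, genes with zero
    counts in either the sample or the reference are dropped pairwise, the
    most extreme 30% of log2 ratios (M) and 5% of average log2 abundances (A)
    are trimmed, and the factor is 2 to the (inverse-variance weighted) mean
    of the remaining M values. Factors are rescaled to have product 1, so the
    effective library size is raw library size x factor.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = values.to_numpy(float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        bad = [values.columns[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"samples with all-zero counts: {bad}")
    f75 = np.quantile(X, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair(X[:, s], X[:, ref], lib[s], lib[ref],
                  log_ratio_trim, abs_expr_trim, weighted)
        for s in range(X.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, log_ratio_trim, abs_expr_trim, weighted):
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    if o.size == 0:
        return 1.0
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        # asymptotic variance of M under binomial sampling
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    else:
        f = np.mean(m[keep])
    return float(2.0 ** f)


def effective_library_sizes(matrix: ExpressionMatrix | pd.DataFrame,
                            **tmm_kwargs) -> pd.Series:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    lib = values.sum(axis=0)
    return (lib * tmm_factors(matrix, **tmm_kwargs)).rename("effective_library_size")


def fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million, on TMM-effective
    library sizes: count / ((length/1e3) * (effective_library_size/1e6))."""
    if matrix.ome != TRANSCRIPT:
        raise ValueError("fpkm expects a transcript matrix")
    if matrix.feature_length_bp is None:
        raise ValueError("fpkm requires feature_length_bp")
    eff = effective_library_sizes(matrix)
    kb = matrix.feature_length_bp.to_numpy(float)[:, None] / 1e3
    per_million = eff.to_numpy(float)[None, :] / 1e6
    return pd.DataFrame(matrix.values.to_numpy(float) / (kb * per_million),
                        index=matrix.values.index, columns=matrix.values.columns)


# ---------------------------------------------------------------------------
# transcripts

def estimate_common_dispersion(scaled: np.ndarray, n_case: int,
                               min_mean: float = 1.0) -> float:
    """Method-of-moments common NB dispersion on TMM-scaled counts.

    Uses the pooled within-group variance so planted group differences do not
    inflate the estimate, averages the per-gene moment estimates
    (var - mean) / mean^2 over genes with adequate counts, and floors the
    result at 0 (the Poisson limit).
    """
    case, ctrl = scaled[:, :n_case], scaled[:, n_case:]
    n1, n2 = case.shape[1], ctrl.shape[1]
    v = ((n1 - 1) * case.var(axis=1, ddof=1)
         + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    m = (case.sum(axis=1) + ctrl.sum(axis=1)) / (n1 + n2)
    ok = m >= min_mean
    if not ok.any():
        return 0.0
    phi = np.mean((v[ok] - m[ok]) / m[ok] ** 2)
    return float(max(phi, 0.0))


def nb_exact_pvalues(y_case, y_control, n_case: int, n_control: int,
                     dispersion: float, chunk_elems: int = 4_000_000) -> np.ndarray:
    """Conditional exact p-values for two group totals of NB counts.

    Given library-equalized group totals y1, y2 with per-sample dispersion
    ``phi``, the conditional law of y1 given t = y1 + y2 depends only on the
    group shapes r_j = n_j / phi (a negative hypergeometric); at phi = 0 it
    is Binomial(t, n1/(n1+n2)). The two-sided p-value is the total
    probability of outcomes no more likely than the one observed.
    """
    y1 = np.asarray(y_case, dtype=np.int64)
    y2 = np.asarray(y_control, dtype=np.int64)
    t = y1 + y2
    p = np.ones(t.size)
    todo = np.flatnonzero(t > 0)
    start = 0
    while start < todo.size:
        # grow the chunk until the enumeration budget is reached
        stop, total = start, 0
        while stop < todo.size and total + t[todo[stop]] + 1 <= chunk_elems:
            total += t[todo[stop]] + 1
            stop += 1
        stop = max(stop, start + 1)
        idx = todo[start:stop]
        p[idx] = _exact_chunk(y1[idx], t[idx], n_case, n_control, dispersion)
        start = stop
    return p


def _exact_chunk(y1, t, n1, n2, phi):
    sizes = t + 1
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    gene = np.repeat(np.arange(t.size), sizes)
    y = np.arange(offsets[-1]) - np.repeat(offsets[:-1], sizes)
    tt = np.repeat(t, sizes)
    if phi > 0:
        r1, r2 = n1 / phi, n2 / phi
        lw = (gammaln(y + r1) - gammaln(y + 1)
              + gammaln(tt - y + r2) - gammaln(tt - y + 1))
    else:
        pi1 = n1 / (n1 + n2)
        lw = (gammaln(tt + 1) - gammaln(y + 1) - gammaln(tt - y + 1)
              + y * np.log(pi1) + (tt - y) * np.log1p(-pi1))
    seg_max = np.maximum.reduceat(lw, offsets[:-1])
    lse = seg_max + np.log(np.add.reduceat(np.exp(lw - seg_max[gene]),
                                           offsets[:-1]))
    lp = lw - lse[gene]
    lp_obs = lp[offsets[:-1] + y1]
    le = lp <= lp_obs[gene] + 1e-9
    pv = np.zeros(t.size)
    np.add.at(pv, gene[le], np.exp(lp[le]))
    return np.minimum(pv, 1.0)


def transcript_de(matrix: ExpressionMatrix, design: CohortDesign,
                  alpha: float = 0.05, fc_min: float = 2.0,
                  dispersion: float | None = None) -> pd.DataFrame:
    """Differential expression of transcript counts.

    Counts are TMM-normalized and scaled to a common (geometric-mean)
    effective library size; genes with no reads in either cohort are
    excluded; the common dispersion (estimated unless given) parameterizes a
    conditional exact test on the two group totals. Fold-change uses the
    normalized group means with a 0.5 pseudocount. Significance requires
    q <= alpha and fold-change >= fc_min or <= 1/fc_min.
    """
    if matrix.ome != TRANSCRIPT:
        raise ValueError("transcript_de expects a transcript count matrix")
    design.validate_against(matrix)
    case_s, ctrl_s = design.case_samples, design.control_samples
    values = matrix.values[case_s + ctrl_s]
    eff = effective_library_sizes(values)
    if np.any(eff.to_numpy() <= 0):
        raise ValueError("group with zero total library size")

    det = detection_counts(matrix, design)
    keep = (det["n_detected_case"] > 0) & (det["n_detected_control"] > 0)
    values = values.loc[keep]
    det = det.loc[keep]

    geo = float(np.exp(np.mean(np.log(eff.to_numpy()))))
    scaled = values.to_numpy(float) * (geo / eff.to_numpy(float))[None, :]
    n1, n2 = len(case_s), len(ctrl_s)
    if dispersion is None:
        dispersion = estimate_common_dispersion(scaled, n1)

    y1 = np.rint(scaled[:, :n1].sum(axis=1)).astype(np.int64)
    y2 = np.rint(scaled[:, n1:].sum(axis=1)).astype(np.int64)
    p = nb_exact_pvalues(y1, y2, n1, n2, dispersion)
    q = bh_adjust(p)

    mean_case = scaled[:, :n1].mean(axis=1)
    mean_ctrl = scaled[:, n1:].mean(axis=1)
    fold_change = (mean_case + FC_PSEUDOCOUNT) / (mean_ctrl + FC_PSEUDOCOUNT)
    significant = (q <= alpha) & ((fold_change >= fc_min)
                                  | (fold_change <= 1.0 / fc_min))
    direction = np.where(~significant, NONE, np.where(fold_change > 1, UP, DOWN))
    return pd.DataFrame({
        "mean_case": mean_case,
        "mean_control": mean_ctrl,
        "fold_change": fold_change,
        "p_value": p,
        "q_value": q,
        "significant": significant,
        "n_detected_case": det["n_detected_case"].to_numpy(),
        "n_detected_control": det["n_detected_control"].to_numpy(),
        "direction": direction,
    }, index=values.index.rename("feature_id")).assign(dispersion=dispersion)
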