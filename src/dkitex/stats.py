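"""Inference layer: group comparisons, ROC/Youden, DeLong, ICC, combinations.

Implements the statistics used to grade diagnostic markers of bladder-cancer
muscle invasiveness and histologic grade:

* Mann-Whitney U comparison of a marker between two groups (exact permutation
  p for small samples, tie-corrected normal approximation otherwise);
* empirical ROC AUC with DeLong 95% CI and the Youden-index optimal cutoff;
* DeLong's test for correlated (same-subject) AUC differences;
* two-way random, absolute-agreement, single-measure ICC(2,1) for
  inter-reader agreement, banded on the conventional qualitative scale;
* an in-sample logistic "combination" score over several markers;
* threshold classification of ordinal VI-RADS scores;
* the closed-form binormal AUC used as a simulation oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ROCResult",
    "ICCResult",
    "CombinationModel",
    "mann_whitney",
    "roc_auc",
    "youden_cutoff",
    "delong_compare",
    "icc_agreement",
    "fit_combination",
    "virads_classifier",
    "binormal_auc",
    "mean_binormal_empirical_auc",
]

EXACT_MW_MAX_N = 16  # combined-sample bound for exact permutation enumeration


@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(x, y) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    For combined n <= 16 the p-value is computed by exhaustive enumeration of
    all group assignments of the pooled sample (valid under ties); beyond
    that, the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        total = 0
        extreme = 0
        obs_dev = abs(u - mu)
        for comb in itertools.combinations(range(n1 + n2), n1):
            r1 = ranks[list(comb)].sum()
            u_perm = r1 - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return ComparisonResult(
        u_statistic=u, p_value=p,
        mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)) if n1 > 1 else 0.0,
        mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)) if n2 > 1 else 0.0,
        n_a=n1, n_b=n2, method=method,
    )


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    direction: str      # 'higher' or 'lower': which sign indicates the positive class


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return scores, labels, pos, neg


def _orient(scores, labels, direction):
    """Return scores flipped so that higher always indicates positive."""
    scores, labels, pos, neg = _split(scores, labels)
    if direction == "auto":
        auc_higher = _u_statistic(pos, neg) / (pos.size * neg.size)
        direction = "higher" if auc_higher >= 0.5 else "lower"
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher', 'lower' or 'auto'")
    oriented = scores if direction == "higher" else -scores
    return oriented, labels, direction


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def _delong_var(pos: np.ndarray, neg: np.ndarray) -> float:
    v10, v01, _ = _delong_components(pos, neg)
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return s10 / pos.size + s01 / neg.size


_Z975 = 1.959963984540054


def _auc_ci(auc: float, se: float) -> tuple[float, float]:
    """DeLong 95% CI, computed on the logit scale to respect the [0, 1]
    bounds (plain Wald at degenerate AUC or zero variance)."""
    if se == 0.0 or auc <= 0.0 or auc >= 1.0:
        return (max(0.0, auc - _Z975 * se), min(1.0, auc + _Z975 * se))
    se_logit = se / (auc * (1.0 - auc))
    lo = sps.logistic.cdf(sps.logistic.ppf(auc) - _Z975 * se_logit)
    hi = sps.logistic.cdf(sps.logistic.ppf(auc) + _Z975 * se_logit)
    return (float(lo), float(hi))


def roc_auc(scores, labels, direction: str = "auto") -> ROCResult:
    """Empirical ROC AUC (ties count 1/2) with DeLong 95% CI and Youden cutoff.

    ``labels`` are booleans marking the positive class.  ``direction='lower'``
    means lower scores indicate the positive class (e.g. diffusivity markers
    of invasive tumors); ``'auto'`` picks the orientation giving AUC >= 0.5.
    """
    oriented, lab, direction = _orient(scores, labels, direction)
    pos, neg = oriented[lab], oriented[~lab]
    auc = _u_statistic(pos, neg) / (pos.size * neg.size)
    se = float(np.sqrt(max(_delong_var(pos, neg), 0.0)))
    cutoff, sens, spec = youden_cutoff(scores, labels, direction)
    return ROCResult(auc=float(auc), ci95=_auc_ci(float(auc), se), cutoff=cutoff,
                     sensitivity=sens, specificity=spec, direction=direction)


def youden_cutoff(scores, labels, direction: str = "auto") -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent distinct score values
    (plus open ends); among ties the cutoff with the highest specificity is
    returned.  The cutoff is reported on the original score scale, with the
    classification rule 'score >= cutoff positive' when ``direction='higher'``
    and 'score <= cutoff positive' when ``'lower'``.
    """
    oriented, lab, direction = _orient(scores, labels, direction)
    pos, neg = oriented[lab], oriented[~lab]
    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    best = None
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    cutoff = t if direction == "higher" else -t
    return float(cutoff), 100.0 * sens, 100.0 * spec


def delong_compare(scores_a, scores_b, labels,
                   direction_a: str = "auto", direction_b: str = "auto") -> float:
    """Two-sided p for the difference of two correlated (same-subject) AUCs."""
    a, lab, _ = _orient(scores_a, labels, direction_a)
    b, lab_b, _ = _orient(scores_b, labels, direction_b)
    if a.shape != b.shape:
        raise ValueError("both markers must score the same subjects")
    pa, na = a[lab], a[~lab]
    pb, nb = b[lab], b[~lab]
    v10a, v01a, auc_a = _delong_components(pa, na)
    v10b, v01b, auc_b = _delong_components(pb, nb)
    n_pos, n_neg = pa.size, na.size
    if n_pos > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n_neg > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg
    delta = auc_a - auc_b
    if var <= 1e-16:
        return 1.0 if abs(delta) <= 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    band: str


def icc_band(icc: float) -> str:
    """Qualitative agreement band: >0.80 excellent, 0.61-0.80 good,
    0.41-0.60 moderate, 0.21-0.40 general, <=0.20 poor."""
    if np.isnan(icc):
        return "undefined"
    if icc > 0.80:
        return "excellent"
    if icc >= 0.61:
        return "good"
    if icc >= 0.41:
        return "moderate"
    if icc >= 0.21:
        return "general"
    return "poor"


def icc_agreement(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an (n_subjects, n_raters) array with no missing cells.
    From the two-way ANOVA mean squares (rows=subjects MSR, columns=raters
    MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN (band 'undefined') when the ratings carry no between-subject
    variance at all.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects, n_raters>=2)")
    n, k = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(Y)):
        raise ValueError("ratings must not contain missing cells")
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((Y - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 1e-30:
        return ICCResult(float("nan"), "undefined")
    icc = (msr - mse) / denom
    return ICCResult(float(icc), icc_band(icc))


@dataclass(frozen=True)
class CombinationModel:
    """In-sample logistic combination of several markers into one score."""

    features: tuple[str, ...]
    coef: tuple[float, ...]       # on the original feature scale
    intercept: float
    scores: np.ndarray            # linear predictor per subject
    separated: bool


_SEPARATION_CAP = 20.0  # cap on standardized coefficients under perfect separation


def fit_combination(features: pd.DataFrame, labels) -> CombinationModel:
    """Fit an unpenalized in-sample logistic model over selected markers.

    The combined score is the linear predictor; its ROC AUC is the
    "combination AUC".  Under perfect separation the standardized coefficient
    vector is rescaled to a finite cap (preserving the score ordering) and the
    model flagged.
    """
    from sklearn.linear_model import LogisticRegression

    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(features)
    labels = np.asarray(labels, dtype=bool)
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    X = features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd

    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-10)
    model.fit(Xs, labels)
    coef_std = model.coef_.ravel()
    intercept_std = float(model.intercept_[0])
    separated = bool(np.max(np.abs(coef_std), initial=0.0) > _SEPARATION_CAP)
    if separated:
        scale = _SEPARATION_CAP / np.max(np.abs(coef_std))
        coef_std = coef_std * scale
        intercept_std = intercept_std * scale
    coef = coef_std / sd
    intercept = intercept_std - float((coef * mu).sum())
    scores = X @ coef + intercept
    return CombinationModel(
        features=tuple(features.columns.astype(str)),
        coef=tuple(float(c) for c in coef),
        intercept=float(intercept),
        scores=scores,
        separated=separated,
    )


def virads_classifier(scores, labels, threshold: int = 3) -> ROCResult:
    """Evaluate the ordinal VI-RADS score as a binary classifier.

    Predicts the positive (muscle-invasive) class when score >= ``threshold``
    and reports sensitivity/specificity of that rule; the AUC treats the
    ordinal score itself as the rating.
    """
    scores = np.asarray(scores)
    if not np.isin(scores, [1, 2, 3, 4, 5]).all():
        raise ValueError("VI-RADS scores must be integers in 1..5")
    _, lab, pos, neg = _split(scores.astype(float), labels)
    auc = _u_statistic(pos, neg) / (pos.size * neg.size)
    se = float(np.sqrt(max(_delong_var(pos, neg), 0.0)))
    sens = 100.0 * float(np.mean(pos >= threshold))
    spec = 100.0 * float(np.mean(neg < threshold))
    return ROCResult(
        auc=float(auc), ci95=_auc_ci(float(auc), se),
        cutoff=float(threshold), sensitivity=sens, specificity=spec,
        direction="higher",
    )


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC of two normal score distributions.

    AUC = Phi(|mu_pos - mu_neg| / sqrt(sd_pos^2 + sd_neg^2)); orientation
    (which class is higher) is the caller's concern.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf(abs(mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


def mean_binormal_empirical_auc(
    mu_pos: float, sd_pos: float, n_pos: int,
    mu_neg: float, sd_neg: float, n_neg: int,
    direction: str = "auto", n_rep: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Average empirical AUC over replicated binormal cohorts.

    Draws ``n_rep`` independent cohorts of normal scores at the given group
    means/SDs and sizes, computes the empirical (tie-1/2) AUC of each with the
    stated orientation, and returns the replicate mean.  This is the
    finite-sample simulation counterpart of :func:`binormal_auc`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aucs = np.empty(n_rep)
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    for r in range(n_rep):
        pos = rng.normal(mu_pos, sd_pos, n_pos)
        neg = rng.normal(mu_neg, sd_neg, n_neg)
        scores = np.concatenate([pos, neg])
        oriented, lab, _ = _orient(scores, labels, direction)
        aucs[r] = _u_statistic(oriented[lab], oriented[~lab]) / (n_pos * n_neg)
    return float(aucs.mean())
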