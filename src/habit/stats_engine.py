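"""Inferential statistics for the behavioural and morphometric readouts.

The central model is an ordinary least-squares regression of log-transformed
TTC on genotype with testing day and recording system as fixed-effect
categorical covariates; the genotype coefficient is tested two-sided and
families of genotype comparisons are corrected by the step-down
Bonferroni-Holm procedure.  The module also provides the Holm-Sidak
correction, one-way ANOVA with Tukey HSD, Wilcoxon rank-sum and
Kruskal-Wallis tests, the pooled-variance t-test, trapezoidal area under
the island-assay curve, and the sign-gated fatigue decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, RankDeficientError

__all__ = [
    "LmComparison",
    "FatigueVerdict",
    "IslandRun",
    "fit_log_ttc_lm",
    "fit_log_ttc_family",
    "holm_bonferroni",
    "holm_sidak",
    "one_way_anova_tukey",
    "rank_sum_test",
    "kruskal_wallis_pairwise",
    "two_sample_t_test",
    "classify_fatigue",
    "island_auc",
]

ALPHA = 0.05


@dataclass(frozen=True)
class LmComparison:
    """One genotype-vs-control contrast from the log-TTC linear model."""

    genotype_pair: tuple[str, str]  # (test, reference)
    estimate: float  # genotype effect on log TTC
    se: float
    t_stat: float
    p_raw: float
    p_adj: float
    n: int


@dataclass(frozen=True)
class FatigueVerdict:
    comparison: str
    verdict: str  # "fatigue" | "no_fatigue"
    estimate: float
    p_adj: float
    direction: int  # sign of rescue - control difference on log TTC


@dataclass(frozen=True)
class IslandRun:
    """One island-assay run: % of flies on the platform over time."""

    timepoints: tuple[float, ...]
    pct_on_platform: tuple[float, ...]

    @property
    def auc(self) -> float:
        return island_auc(self.timepoints, self.pct_on_platform)


# ---------------------------------------------------------------------------
# multiple-testing corrections


def _validated_pvals(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return p


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values, in the input order."""
    p = _validated_pvals(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, in the input order."""
    p = _validated_pvals(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


# ---------------------------------------------------------------------------
# the log-TTC linear model


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns linearly dependent on the preceding ones
        aliased = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append(names[j])
        raise RankDeficientError(
            "design matrix is rank deficient; aliased terms: " + ", ".join(aliased),
            aliased=aliased,
        )


def fit_log_ttc_lm(
    scores: pd.DataFrame,
    test: str,
    reference: str,
    covariates: Sequence[str] = ("day", "system"),
) -> LmComparison:
    """OLS of log(TTC) on genotype plus batch covariates, one contrast.

    ``scores`` must contain columns genotype, ttc and the covariates; all
    TTC values must be >= 1 (flies that never jump are excluded upstream by
    the initial-jumper filter).  The genotype coefficient (test vs
    reference, dummy coded) is tested with a two-sided t-test.  ``p_adj``
    equals ``p_raw`` here; family-level correction happens in
    :func:`fit_log_ttc_family`.
    """
    for col in ("genotype", "ttc", *covariates):
        if col not in scores.columns:
            raise InvalidInputError(f"scores frame lacks column {col!r}")
    sub = scores[scores["genotype"].isin([test, reference])].copy()
    if sub.empty or sub["genotype"].nunique() < 2:
        raise InvalidInputError(
            f"need flies from both {test!r} and {reference!r} to fit the model"
        )
    if (sub["ttc"] < 1).any():
        raise InvalidInputError("all TTC values must be >= 1 for the log transform")

    sub["log_ttc"] = np.log(sub["ttc"].astype(float))
    sub["genotype"] = pd.Categorical(sub["genotype"], categories=[reference, test])
    terms = ["C(genotype)"]
    for cov in covariates:
        if sub[cov].astype(str).nunique() > 1:  # constant covariates drop out
            sub[cov] = sub[cov].astype(str)
            terms.append(f"C({cov})")
    model = smf.ols("log_ttc ~ " + " + ".join(terms), data=sub)
    _check_full_rank(np.asarray(model.exog), list(model.exog_names))
    fit = model.fit()

    coef_name = f"C(genotype)[T.{test}]"
    return LmComparison(
        genotype_pair=(test, reference),
        estimate=float(fit.params[coef_name]),
        se=float(fit.bse[coef_name]),
        t_stat=float(fit.tvalues[coef_name]),
        p_raw=float(fit.pvalues[coef_name]),
        p_adj=float(fit.pvalues[coef_name]),
        n=int(len(sub)),
    )


def fit_log_ttc_family(
    scores: pd.DataFrame,
    reference: str,
    tests: Sequence[str] | None = None,
    covariates: Sequence[str] = ("day", "system"),
    correction: str = "holm",
) -> list[LmComparison]:
    """One mutant-vs-control model per test genotype, Holm-corrected.

    Each comparison is fit on the two genotypes involved (per-pair models
    with a shared control); the family is the set of comparisons requested
    in this invocation.
    """
    if tests is None:
        tests = [g for g in scores["genotype"].unique() if g != reference]
    raw = [fit_log_ttc_lm(scores, t, reference, covariates) for t in tests]
    adjust = holm_bonferroni if correction == "holm" else holm_sidak
    p_adj = adjust([c.p_raw for c in raw])
    return [
        LmComparison(
            genotype_pair=c.genotype_pair,
            estimate=c.estimate,
            se=c.se,
            t_stat=c.t_stat,
            p_raw=c.p_raw,
            p_adj=float(pa),
            n=c.n,
        )
        for c, pa in zip(raw, p_adj)
    ]


def classify_fatigue(
    scores: pd.DataFrame,
    test: str,
    reference: str,
    covariates: Sequence[str] = ("day", "system"),
    alpha: float = ALPHA,
    p_adj: float | None = None,
) -> FatigueVerdict:
    """Decide whether a rescue genotype shows fatigue rather than learning.

    Fatigue is concluded only when the rescue group's log-TTC is
    significantly *smaller* than the control's (negative genotype effect
    with adjusted p below ``alpha``); a significant difference in the other
    direction is not fatigue.  ``p_adj`` may be supplied when the
    comparison belongs to a larger corrected family; otherwise the raw
    model p is used (a family of one).
    """
    cmp = fit_log_ttc_lm(scores, test, reference, covariates)
    p = cmp.p_raw if p_adj is None else float(p_adj)
    direction = int(np.sign(cmp.estimate))
    verdict = "fatigue" if (cmp.estimate < 0 and p < alpha) else "no_fatigue"
    return FatigueVerdict(
        comparison=f"{test} vs {reference}",
        verdict=verdict,
        estimate=cmp.estimate,
        p_adj=p,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# classical group comparisons


def _as_groups(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]):
    if isinstance(groups, Mapping):
        names = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(data))]
    return names, data


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> dict:
    """One-way ANOVA F-test with Tukey HSD pairwise comparisons.

    Returns ``{"f": F, "p": p, "pairwise": [(name_i, name_j, p_adj), ...]}``.
    Groups with identical values everywhere give F=0, p=1 by convention.
    """
    names, data = _as_groups(groups)
    if len(data) < 2 or any(len(g) < 2 for g in data):
        raise InvalidInputError("ANOVA needs >= 2 groups with >= 2 values each")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        pairs = [
            (names[i], names[j], 1.0)
            for i in range(len(data))
            for j in range(i + 1, len(data))
        ]
        return {"f": 0.0, "p": 1.0, "pairwise": pairs}
    f, p = sps.f_oneway(*data)
    hsd = sps.tukey_hsd(*data)
    pairs = [
        (names[i], names[j], float(hsd.pvalue[i, j]))
        for i in range(len(data))
        for j in range(i + 1, len(data))
    ]
    return {"f": float(f), "p": float(p), "pairwise": pairs}


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses exact enumeration when the combined sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return 1.0
    tie_free = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def kruskal_wallis_pairwise(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> dict:
    """Kruskal-Wallis omnibus test with Holm-corrected pairwise rank-sums.

    Returns ``{"h": H, "p": p, "pairwise": [(name_i, name_j, p_adj), ...]}``.
    All observations identical is a degenerate tie-correction case and maps
    to H=0, p=1.
    """
    names, data = _as_groups(groups)
    if len(data) < 3:
        raise InvalidInputError("Kruskal-Wallis omnibus needs >= 3 groups")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*data)
    idx_pairs = [
        (i, j) for i in range(len(data)) for j in range(i + 1, len(data))
    ]
    raw = [rank_sum_test(data[i], data[j]) for i, j in idx_pairs]
    adj = holm_bonferroni(raw)
    pairs = [
        (names[i], names[j], float(pa)) for (i, j), pa in zip(idx_pairs, adj)
    ]
    return {"h": float(h), "p": float(p), "pairwise": pairs}


def two_sample_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided pooled-variance Student's t-test p-value.

    Degenerate zero-variance samples follow the edge convention p=1 for
    equal means and p=0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def island_auc(timepoints: Sequence[float], pct_on_platform: Sequence[float]) -> float:
    """Trapezoidal area under an island-assay curve (percentage x seconds)."""
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(pct_on_platform, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise InvalidInputError("need >= 2 matching timepoints")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("timepoints must be strictly increasing")
    if np.any((y < 0) | (y > 100)):
        raise InvalidInputError("percentages must lie in [0, 100]")
    return float(np.trapezoid(y, t))
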