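"""The cohort statistical layer.

Rank correlation, rank-sum and contingency tests with the conventions used
throughout the analysis (midranks, exact small-sample enumeration, Fisher's
two-sided point-probability rule), a logistic regression fitted by
iteratively reweighted least squares with an optional Firth penalty for
separation-prone outcomes, backward elimination, and the primary
association pipeline with its sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from vhitkit import classify as _classify
from vhitkit.errors import (
    ConfigError,
    InputError,
    SeparationWarning,
    UndefinedStatisticError,
)
from vhitkit.types import (
    AssociationResult,
    AssociationTerm,
    PatientRecord,
    TestResult,
)

#: Sample-size bound below which the rank-sum test enumerates exactly.
EXACT_MW_MAX_N = 20

#: Expected-count rule: Fisher's exact test when any expected cell is < 5.
CHI2_MIN_EXPECTED = 5.0

#: Default retention threshold for backward elimination. The study's final
#: model keeps a covariate at p = 0.083, which is incompatible with a 0.05
#: stay rule; 0.10 reproduces that behavior and remains configurable.
DEFAULT_ALPHA_REMOVE = 0.10

_Z975 = 1.959963984540054  # normal 97.5% quantile for Wald CIs


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with midranks and a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("at least 3 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "rank correlation is undefined for a constant vector"
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(r, float(p), "spearman", {"n": n})


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a > b) pairs + half ties, via midranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is the smaller of the two U values. For pooled
    n <= 20 the null distribution is enumerated exactly over all group
    assignments (valid under ties); larger samples use the tie-corrected
    normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    u1 = _u_statistic(a, b)
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)
    mu = n1 * n2 / 2.0

    if n <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        dev_obs = abs(u1 - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        p = hits / total
        method_detail = "exact"
    else:
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u1 - mu) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        method_detail = "normal_tie_corrected"
    return TestResult(
        u_min, float(min(p, 1.0)), "mann_whitney", {"u1": u1, "u2": u2, "n1": n1, "n2": n2, "detail": method_detail}
    )


def fisher_exact_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Fisher's exact test, two-sided by the point-probability rule."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("a 2x2 table is required")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher_exact")


def contingency_test(
    table: Sequence[Sequence[float]], continuity_correction: bool = False
) -> TestResult:
    """Chi-square or Fisher's exact test of a 2x2 table.

    Fisher's exact test (two-sided by the point-probability rule) is used
    whenever any expected or observed cell count falls below 5, otherwise
    the 1-df chi-square statistic (no continuity correction by default).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("a 2x2 table is required")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise InputError("cell counts must be nonnegative integers")
    if t.sum() == 0:
        raise InputError("all-zero table")
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if np.any(expected < CHI2_MIN_EXPECTED) or np.any(t < CHI2_MIN_EXPECTED):
        return fisher_exact_test(t)
    chi2, p, _, _ = sps.chi2_contingency(t, correction=continuity_correction)
    return TestResult(float(chi2), float(p), "chi_square")


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A fitted logistic model (first column is the intercept)."""

    names: List[str]
    params: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    model: str  # plain_mle | firth
    n: int
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self) -> np.ndarray:
        z = self.params / self.se
        return 2.0 * sps.norm.sf(np.abs(z))

    def odds_ratios(self) -> pd.DataFrame:
        se = self.se
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "odds_ratio": np.exp(self.params),
                "ci_low": np.exp(self.params - _Z975 * se),
                "ci_high": np.exp(self.params + _Z975 * se),
                "p_value": self.wald_p(),
            },
            index=self.names,
        )


def _as_design(
    X: Union[pd.DataFrame, np.ndarray], add_intercept: bool
) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i}" for i in range(mat.shape[1])]
    if add_intercept:
        mat = np.column_stack([np.ones(mat.shape[0]), mat])
        names = ["intercept"] + names
    return mat, names


def logistic_fit(
    y: Sequence[float],
    X: Union[pd.DataFrame, np.ndarray],
    model: str = "plain_mle",
    add_intercept: bool = True,
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    ``model='firth'`` applies the Jeffreys-prior penalty (score adjusted by
    the hat diagonal), which keeps estimates finite under separation — the
    relevant regime for rare outcomes. Convergence is declared when the
    maximum absolute score component drops below ``score_tol``.
    """
    if model not in ("plain_mle", "firth"):
        raise InputError(f"unknown model {model!r}")
    y = np.asarray(y, dtype=float)
    mat, names = _as_design(X, add_intercept)
    n, k = mat.shape
    if y.size != n:
        raise InputError("y and X must have equal length")
    if not (np.all((y == 0) | (y == 1))):
        raise InputError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise InputError("y must contain both classes")
    if n <= k:
        raise InputError(f"n={n} must exceed number of parameters k={k}")

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = mat @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = mat.T @ (mat * w[:, None])
        if model == "firth":
            try:
                info_inv = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                break
            h = np.einsum("ij,jk,ik->i", mat, info_inv, mat) * w
            score = mat.T @ (y - p + h * (0.5 - p))
        else:
            score = mat.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps to keep IRLS stable near separation
        step_norm = np.max(np.abs(step))
        if step_norm > 5.0:
            step *= 5.0 / step_norm
        beta = beta + step

    eta = mat @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = mat.T @ (mat * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)

    if model == "plain_mle" and (not converged or np.max(np.abs(beta)) > 15.0):
        # diverging estimates can still zero the score; both signatures of
        # (quasi-)separation get the same advice
        warnings.warn(
            "logistic fit did not converge or shows diverging estimates; "
            "data may be separated — consider model='firth'",
            SeparationWarning,
            stacklevel=2,
        )
    return LogisticFit(
        names=names,
        params=beta,
        cov=cov,
        converged=converged,
        n_iter=it,
        model=model,
        n=n,
        fitted=p,
    )


def backward_select(
    y: Sequence[float],
    X: pd.DataFrame,
    alpha_remove: float = DEFAULT_ALPHA_REMOVE,
    model: str = "plain_mle",
    outcome: str = "outcome",
) -> AssociationResult:
    """Backward elimination of covariates by Wald p-value.

    Starting from the full model, the covariate with the largest p-value
    above ``alpha_remove`` is dropped and the model refitted, until every
    remaining covariate satisfies the stay rule. The intercept is never
    dropped. An intercept-only model is a legal end state.
    """
    if not isinstance(X, pd.DataFrame):
        raise InputError("backward_select requires a named covariate DataFrame")
    current = list(X.columns)
    trace: List[Tuple[str, float]] = []
    fit = logistic_fit(y, X[current], model=model)
    while current:
        pvals = fit.wald_p()[1:]  # skip intercept
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha_remove:
            break
        dropped = current.pop(worst)
        trace.append((dropped, float(pvals[worst])))
        fit = logistic_fit(y, X[current], model=model)  # intercept-only is legal

    terms: List[AssociationTerm] = []
    table = fit.odds_ratios()
    intercept = float(fit.params[0])
    converged = fit.converged
    for name in current:
        row = table.loc[name]
        terms.append(
            AssociationTerm(
                name=name,
                coefficient=float(row["coefficient"]),
                odds_ratio=float(row["odds_ratio"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p_value=float(row["p_value"]),
            )
        )
    return AssociationResult(
        outcome=outcome,
        terms=terms,
        intercept=intercept,
        elimination_trace=trace,
        model=model,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Primary analysis pipeline
# ---------------------------------------------------------------------------

#: Candidate covariates of the multivariable models.
CANDIDATE_ROSTER = [
    "age",
    "sex_female",
    "disease_duration",
    "mds_updrs_iii",
    "kinetic_tremor",
    "orthostatic_hypotension",
    "schooling",
    "mmse",
    "scopa_pc",
    "depression",
    "anxiety",
    "cadence",
    "hc_gain",
    "ac_gain",
    "pc_gain",
]


@dataclass
class AnalysisConfig:
    """Settings of the association pipeline."""

    rcft_threshold: float = _classify.DEFAULT_RCFT_THRESHOLD
    sensitivity_threshold: float = -1.0
    alpha_remove: float = DEFAULT_ALPHA_REMOVE
    model: str = "plain_mle"
    run_sensitivity: bool = True


@dataclass
class PrimaryAnalysisResult:
    """Association models, correlations, and sensitivity reruns."""

    copy_model: AssociationResult
    recall_model: AssociationResult
    correlations: pd.DataFrame
    sensitivity: Dict[str, AssociationResult] = field(default_factory=dict)


def cohort_frame(cohort: Union[Sequence[PatientRecord], pd.DataFrame]) -> pd.DataFrame:
    """Cohort as a DataFrame with derived analysis columns.

    Adds side-averaged per-class gains (``hc_gain``/``ac_gain``/``pc_gain``)
    and the ``sex_female`` indicator.
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
    else:
        from vhitkit.io import records_to_frame

        df = records_to_frame(cohort)
    if "sex_female" not in df and "sex" in df:
        df["sex_female"] = (df["sex"] == "female").astype(float)
    for cls, (r, l) in {
        "hc": ("gain_rhc", "gain_lhc"),
        "ac": ("gain_rac", "gain_lac"),
        "pc": ("gain_rpc", "gain_lpc"),
    }.items():
        if f"{cls}_gain" not in df and r in df and l in df:
            df[f"{cls}_gain"] = 0.5 * (df[r] + df[l])
    return df


def _decreased_indicators(df: pd.DataFrame) -> pd.DataFrame:
    """Binary per-class decreased-gain flags (either side below its range)."""
    out = {}
    ranges = _classify.DEFAULT_NORMATIVE_RANGES
    for cls in ("hc", "ac", "pc"):
        r = ranges[cls.upper()]
        right = df[f"gain_r{cls}"] < r.low
        left = df[f"gain_l{cls}"] < r.low
        out[f"{cls}_decreased"] = (right | left).astype(float)
    return pd.DataFrame(out, index=df.index)


def run_primary_analysis(
    cohort: Union[Sequence[PatientRecord], pd.DataFrame],
    config: Optional[AnalysisConfig] = None,
) -> PrimaryAnalysisResult:
    """The full association analysis on a cohort table.

    Fits backward-selected logistic models for abnormal RCFT-copying and
    abnormal delayed recall on the candidate roster, computes Spearman
    correlations of the cognitive scores against the per-class gains, and
    reruns the copy model (a) at the lenient z-threshold and (b) with
    binary decreased-gain indicators replacing the continuous gains.
    """
    config = config or AnalysisConfig()
    df = cohort_frame(cohort)

    missing = [c for c in CANDIDATE_ROSTER if c not in df.columns]
    for col in ("rcft_copy_z", "rcft_recall_z"):
        if col not in df.columns:
            missing.append(col)
    if missing:
        raise ConfigError(f"cohort table is missing columns: {missing}")

    y_copy = (df["rcft_copy_z"] < config.rcft_threshold).astype(float).to_numpy()
    y_recall = (df["rcft_recall_z"] < config.rcft_threshold).astype(float).to_numpy()
    X = df[CANDIDATE_ROSTER].astype(float)

    copy_model = backward_select(
        y_copy, X, config.alpha_remove, config.model, outcome="abnormal_rcft_copy"
    )
    recall_model = backward_select(
        y_recall, X, config.alpha_remove, config.model, outcome="abnormal_rcft_recall"
    )

    rows = []
    for score in ("rcft_copy_z", "rcft_recall_z", "mmse"):
        for cls in ("hc", "ac", "pc"):
            res = spearman(df[score], df[f"{cls}_gain"])
            rows.append(
                {
                    "score": score,
                    "canal": cls.upper(),
                    "r": res.statistic,
                    "p_value": res.p_value,
                }
            )
    correlations = pd.DataFrame(rows)

    sensitivity: Dict[str, AssociationResult] = {}
    if config.run_sensitivity:
        y_copy_1sd = (
            (df["rcft_copy_z"] < config.sensitivity_threshold).astype(float).to_numpy()
        )
        sensitivity["copy_z_lt_minus1"] = backward_select(
            y_copy_1sd,
            X,
            config.alpha_remove,
            config.model,
            outcome="abnormal_rcft_copy_1sd",
        )
        X_nominal = pd.concat(
            [
                X.drop(columns=["hc_gain", "ac_gain", "pc_gain"]),
                _decreased_indicators(df),
            ],
            axis=1,
        )
        sensitivity["decreased_gain_nominal"] = backward_select(
            y_copy,
            X_nominal,
            config.alpha_remove,
            config.model,
            outcome="abnormal_rcft_copy_nominal_gain",
        )
    return PrimaryAnalysisResult(copy_model, recall_model, correlations, sensitivity)


def association_report(
    result: AssociationResult, clip_low: float = 0.001, clip_high: float = 999.0
) -> str:
    """Text table of a fitted model: OR (95% CI), p per retained covariate.

    Displayed odds ratios and CI bounds are clipped to the visible range
    used in printed tables; machine output keeps raw values.
    """

    def fmt(v: float) -> str:
        return f"{min(max(v, clip_low), clip_high):.3g}"

    lines = [f"Outcome: {result.outcome} ({result.model})"]
    if not result.terms:
        lines.append("  (intercept-only model)")
    for t in result.terms:
        lines.append(
            f"  {t.name}: OR {fmt(t.odds_ratio)} "
            f"({fmt(t.ci_low)}-{fmt(t.ci_high)}), p = {t.p_value:.3g}"
        )
    if result.elimination_trace:
        dropped = ", ".join(f"{v} (p={p:.2g})" for v, p in result.elimination_trace)
        lines.append(f"  eliminated: {dropped}")
    lines.append("  note: no multiple-testing correction applied")
    return "\n".join(lines)
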