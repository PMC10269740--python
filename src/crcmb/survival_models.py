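"""ALR survival indices, mixed-effects ALR models, logistic survival models,
and score stratification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import COVARIATE_LEVELS, FeatureTable, SampleMetadata
from .ordination import OrdinationResult

__all__ = [
    "ALRIndex",
    "RegressionResult",
    "MixedEffectEstimate",
    "PerfectSeparationError",
    "communality_select",
    "loading_quartile_sets",
    "compute_alr",
    "lme_alr",
    "logistic_survival",
    "stratify_scores",
]

ADJUSTMENT_COVARIATES = (
    "age", "sex", "asa", "location", "surgery_period", "stage",
    "radical_surgery", "differentiation",
)


class PerfectSeparationError(RuntimeError):
    """Logistic MLE does not exist; use the penalized fallback."""


@dataclass(frozen=True)
class ALRIndex:
    """log2 ratio of pseudocount-adjusted sums of two disjoint feature sets."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    pseudocount: float
    sample_ids: tuple[str, ...]
    values: np.ndarray  # per-sample log2 ratio

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator must be non-empty")
        if set(self.numerator) & set(self.denominator):
            raise ValueError("numerator and denominator must be disjoint")
        if not np.isfinite(self.values).all():
            raise ValueError("ALR values must be finite")

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.sample_ids), name="alr")

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"# numerator={','.join(self.numerator)}\n")
            fh.write(f"# denominator={','.join(self.denominator)}\n")
            fh.write(f"# pseudocount={self.pseudocount}\n")
            fh.write("sample_id\talr\n")
            for sid, v in zip(self.sample_ids, self.values):
                fh.write(f"{sid}\t{v!r}\n")


@dataclass(frozen=True)
class RegressionResult:
    """Per-term odds ratios with Wald 95% CIs."""

    terms: pd.DataFrame  # index term; columns OR, ci_low, ci_high, p
    model: str  # "crude" | "adjusted"
    covariates: tuple[str, ...]
    n: int

    def __post_init__(self) -> None:
        t = self.terms
        if ((t["OR"] <= 0) | (t["ci_low"] > t["OR"]) | (t["OR"] > t["ci_high"])).any():
            raise ValueError("odds ratios must be positive and inside their CIs")


@dataclass(frozen=True)
class MixedEffectEstimate:
    coefficients: pd.DataFrame  # index term; columns estimate, ci_low, ci_high, p (log2 scale)
    random_intercept_variance: float
    grouping: str = "subject"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.coefficients
        if ((c["ci_low"] > c["estimate"]) | (c["estimate"] > c["ci_high"])).any():
            raise ValueError("CI must bracket the coefficient")
        if self.random_intercept_variance < 0:
            raise ValueError("variance must be >= 0")


# ---------------------------------------------------------------------------
# rPCA-based candidate/quartile machinery


def communality_select(ord_result: OrdinationResult, threshold: float = 0.01) -> list[str]:
    """Features whose communality sqrt(sum_k loading_k^2) is >= threshold."""
    communality = np.sqrt((ord_result.feature_loadings**2).sum(axis=1))
    selected = [f for f, c in zip(ord_result.feature_ids, communality) if c >= threshold]
    if not selected:
        raise ValueError(f"no feature reaches communality {threshold}")
    return selected


def loading_quartile_sets(
    ord_result: OrdinationResult, pc: int, candidates: list[str]
) -> tuple[list[str], list[str]]:
    """(upper, lower) feature sets: loadings above Q3 / below Q1 of the
    candidate features' loadings on component ``pc`` (linear-interpolation
    quartiles)."""
    if not candidates:
        raise ValueError("empty candidate set")
    index = {f: i for i, f in enumerate(ord_result.feature_ids)}
    missing = [f for f in candidates if f not in index]
    if missing:
        raise KeyError(f"candidate feature(s) not in ordination: {missing}")
    loadings = ord_result.feature_loadings[[index[f] for f in candidates], pc]
    q1, q3 = np.quantile(loadings, [0.25, 0.75])
    if q1 == q3:
        raise ValueError("degenerate loading distribution (Q1 == Q3)")
    upper = [f for f, v in zip(candidates, loadings) if v > q3]
    lower = [f for f, v in zip(candidates, loadings) if v < q1]
    return upper, lower


def compute_alr(
    table: FeatureTable,
    num: list[str],
    den: list[str],
    pseudocount: float = 1.0,
) -> ALRIndex:
    """Per-sample log2( sum(num counts + pc) / sum(den counts + pc) )."""
    num, den = list(num), list(den)
    if not num or not den:
        raise ValueError("numerator and denominator sets must be non-empty")
    overlap = set(num) & set(den)
    if overlap:
        raise ValueError(f"numerator/denominator overlap: {sorted(overlap)}")
    index = {f: i for i, f in enumerate(table.feature_ids)}
    missing = [f for f in num + den if f not in index]
    if missing:
        raise ValueError(f"feature(s) not in table: {missing}")
    counts = table.counts.astype(float) + float(pseudocount)
    num_sum = counts[:, [index[f] for f in num]].sum(axis=1)
    den_sum = counts[:, [index[f] for f in den]].sum(axis=1)
    values = np.log2(num_sum / den_sum)
    return ALRIndex(tuple(num), tuple(den), float(pseudocount), table.sample_ids, values)


# ---------------------------------------------------------------------------
# models


def lme_alr(
    alr: ALRIndex, metadata: SampleMetadata, design: str = "tissue"
) -> MixedEffectEstimate:
    """Linear mixed-effects model of the ALR with a per-subject random
    intercept (REML); coefficients are on the log2 scale of the index.

    On a singular fit the model falls back (with a warning) to an ordinary
    regression on within-subject tumor-minus-normal differences.
    """
    frame = metadata.frame.loc[list(alr.sample_ids)].copy()
    frame["alr"] = alr.values
    frame["tumor"] = (frame["tissue"] == "tumor").astype(float)
    exog_cols = ["tumor"]
    if design == "tissue_x_survival":
        frame["short"] = (frame["survival"] == "short").astype(float)
        frame["tumor_x_short"] = frame["tumor"] * frame["short"]
        exog_cols += ["short", "tumor_x_short"]
    elif design != "tissue":
        raise ValueError(f"unknown design {design!r}")
    exog = sm.add_constant(frame[exog_cols])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(frame["alr"], exog, groups=frame["subject_id"])
        fit = model.fit(reml=True)
        singular = any("singular" in str(w.message).lower()
                       or "converge" in str(w.message).lower() for w in caught)
    if singular or not np.isfinite(fit.bse[exog_cols]).all():
        warnings.warn(
            "singular mixed-model fit; falling back to OLS on within-subject differences",
            stacklevel=2,
        )
        return _paired_diff_fallback(frame, design)
    ci = fit.conf_int()
    rows = {}
    for term in exog_cols:
        rows[term] = {
            "estimate": float(fit.params[term]),
            "ci_low": float(ci.loc[term, 0]),
            "ci_high": float(ci.loc[term, 1]),
            "p": float(fit.pvalues[term]),
        }
    return MixedEffectEstimate(
        coefficients=pd.DataFrame(rows).T,
        random_intercept_variance=float(max(fit.cov_re.iloc[0, 0], 0.0)),
        extras={"converged": bool(fit.converged), "n": int(len(frame))},
    )


def _paired_diff_fallback(frame: pd.DataFrame, design: str) -> MixedEffectEstimate:
    wide = frame.pivot_table(index="subject_id", columns="tissue", values="alr")
    diff = (wide["tumor"] - wide["normal"]).dropna()
    if design == "tissue":
        est = float(diff.mean())
        se = float(diff.std(ddof=1) / np.sqrt(len(diff)))
        tcrit = stats.t.ppf(0.975, len(diff) - 1)
        p = float(2 * stats.t.sf(abs(est / se), len(diff) - 1)) if se > 0 else 0.0
        coefs = pd.DataFrame(
            {"tumor": {"estimate": est, "ci_low": est - tcrit * se,
                       "ci_high": est + tcrit * se, "p": p}}
        ).T
    else:
        survival = frame.groupby("subject_id")["survival"].first().loc[diff.index]
        x = sm.add_constant((survival == "short").astype(float))
        fit = sm.OLS(diff, x).fit()
        ci = fit.conf_int()
        coefs = pd.DataFrame(
            {
                "tumor": {"estimate": float(fit.params["const"]),
                          "ci_low": float(ci.loc["const", 0]),
                          "ci_high": float(ci.loc["const", 1]),
                          "p": float(fit.pvalues["const"])},
                "tumor_x_short": {"estimate": float(fit.params.iloc[1]),
                                  "ci_low": float(ci.iloc[1, 0]),
                                  "ci_high": float(ci.iloc[1, 1]),
                                  "p": float(fit.pvalues.iloc[1])},
            }
        ).T
    return MixedEffectEstimate(
        coefficients=coefs, random_intercept_variance=0.0,
        extras={"fallback": "paired_diff"},
    )


def _subject_frame(metadata: SampleMetadata) -> pd.DataFrame:
    """One row per subject, covariates taken from the tumor sample."""
    frame = metadata.frame
    tumor_rows = frame[frame["tissue"] == "tumor"]
    out = tumor_rows.set_index("subject_id")
    return out


def logistic_survival(
    predictor: pd.Series,
    metadata: SampleMetadata,
    adjust: bool = False,
    penalized_fallback: bool = False,
) -> RegressionResult:
    """Logistic regression of short-term survival on a per-subject predictor.

    ``predictor`` is indexed by subject ID (continuous scores or category
    labels).  ``adjust=True`` adds the Table-1 covariate set (age, sex, ASA,
    location, surgery period, TNM stage, radical surgery, differentiation).
    Wald 95% CIs; ORs are exp(coefficients).
    """
    subj = _subject_frame(metadata)
    predictor = predictor.dropna()
    common = [s for s in subj.index if s in predictor.index]
    if not common:
        raise ValueError("predictor shares no subjects with the metadata")
    subj = subj.loc[common]
    y = (subj["survival"] == "short").astype(float)

    pred = predictor.loc[common]
    if pred.dtype == object or isinstance(pred.dtype, pd.CategoricalDtype):
        x = pd.get_dummies(pred.astype("category"), prefix="predictor", drop_first=True)
        x = x.astype(float)
    else:
        x = pred.astype(float).to_frame("predictor")
    covariates: tuple[str, ...] = ()
    if adjust:
        missing = [c for c in ADJUSTMENT_COVARIATES if c not in subj.columns]
        if missing:
            raise ValueError(f"metadata lacks adjustment covariate(s) {missing}")
        covariates = ADJUSTMENT_COVARIATES
        for cov in ADJUSTMENT_COVARIATES:
            cat = pd.Categorical(subj[cov], categories=COVARIATE_LEVELS[cov])
            dummies = pd.get_dummies(cat, prefix=cov, drop_first=True).astype(float)
            dummies.index = subj.index
            x = pd.concat([x, dummies], axis=1)
    exog = sm.add_constant(x)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y.to_numpy(), exog.to_numpy()).fit(disp=0, maxiter=200)
        separated = not np.isfinite(fit.bse).all() or np.abs(fit.params).max() > 30
    except Exception:
        separated = True
        fit = None
    if separated:
        if not penalized_fallback:
            raise PerfectSeparationError(
                "logistic MLE unstable (perfect or quasi-separation); "
                "re-run with penalized_fallback=True for a ridge-penalized fit"
            )
        fit = sm.GLM(y.to_numpy(), exog.to_numpy(), family=sm.families.Binomial()).fit_regularized(
            alpha=1.0 / len(y), L1_wt=0.0
        )
        # regularized fits lack covariance; report without CIs via a refit trick
        params = np.asarray(fit.params)
        se = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    else:
        params = np.asarray(fit.params)
        se = np.asarray(fit.bse)
        pvals = np.asarray(fit.pvalues)

    z = stats.norm.ppf(0.975)
    terms = {}
    for i, name in enumerate(exog.columns):
        if name == "const":
            continue
        est = params[i]
        lo = est - z * se[i] if np.isfinite(se[i]) else est
        hi = est + z * se[i] if np.isfinite(se[i]) else est
        terms[name] = {
            "OR": float(np.exp(est)),
            "ci_low": float(np.exp(lo)),
            "ci_high": float(np.exp(hi)),
            "p": float(pvals[i]) if np.isfinite(pvals[i]) else np.nan,
        }
    return RegressionResult(
        terms=pd.DataFrame(terms).T,
        model="adjusted" if adjust else "crude",
        covariates=covariates,
        n=int(len(y)),
    )


def stratify_scores(
    scores: pd.Series, mode: str = "median_split", second: pd.Series | None = None
) -> pd.Series:
    """Categorize per-subject scores.

    ``median_split`` -> {low, high} around the median; ``tertiles`` -> three
    near-equal groups {T1, T2, T3}; ``quadrants`` crosses the median splits of
    ``scores`` and ``second``.
    """
    scores = scores.astype(float)
    if scores.nunique() <= 1:
        raise ValueError("all scores tied; cannot stratify")
    if mode == "median_split":
        if len(scores) < 3:
            raise ValueError("median_split needs >= 3 subjects")
        med = scores.median()
        return pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    if mode == "tertiles":
        if len(scores) < 3:
            raise ValueError("tertiles need >= 3 subjects")
        labels = pd.qcut(scores.rank(method="first"), 3, labels=["T1", "T2", "T3"])
        return pd.Series(labels.astype(str), index=scores.index)
    if mode == "quadrants":
        if second is None:
            raise ValueError("quadrants require a second score vector")
        if len(scores) < 4:
            raise ValueError("quadrants need >= 4 subjects")
        a = stratify_scores(scores, "median_split")
        b = stratify_scores(second.loc[scores.index], "median_split")
        return a.str.cat(b, sep="/")
    raise ValueError(f"unknown mode {mode!r}")
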