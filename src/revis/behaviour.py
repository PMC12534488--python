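"""Behavioural analytics: accuracy profiles, masking effects, consistency.

All statistics consume long-format trial tables (one row per trial) with
columns ``subject, condition, masked, true, response, rt, correct``; human
and model tables share the schema (model tables may carry NaN RTs, which RT
analytics skip).  The comparison surfaces are

* the 17-condition accuracy profile and its masking effect
  (unmasked minus masked accuracy per condition),
* the easy/hard condition split at the 0.9 accuracy threshold,
* consistency: Pearson correlation between a model's and the humans'
  17-condition accuracy profiles,
* confusion-matrix correlation over the 56 off-diagonal cells, and
* split-half reliability of either surface over random subject halves,
  the noise ceiling for model fits.

Seed-level aggregation reports a mean and a percentile 95% confidence
interval across fine-tuning seeds, never across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .stimuli import condition_labels


class AnalysisError(ValueError):
    pass


class UndefinedCorrelationError(AnalysisError):
    """Pearson correlation is undefined for zero-variance input."""


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


@dataclass
class ConditionProfile:
    """Per-condition mean accuracy plus the trial counts behind it."""

    conditions: list[str]
    accuracy: np.ndarray
    n_trials: np.ndarray

    def series(self) -> pd.Series:
        return pd.Series(self.accuracy, index=self.conditions)


@dataclass
class ConfusionMatrix:
    """Stimulus x response counts; rows are presented categories."""

    categories: list[str]
    counts: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def proportions(self) -> np.ndarray:
        """Rows normalised to response proportions (zero rows stay zero)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return np.divide(self.counts, sums, out=np.zeros_like(self.counts,
                                                              dtype=float),
                         where=sums > 0)


def exclude_participants(trials: pd.DataFrame, threshold: float = 0.7,
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Drop all trials of subjects whose overall accuracy is below threshold.

    A subject at exactly the threshold is retained (strict less-than)."""
    if trials.empty:
        return trials.copy(), []
    acc = trials.groupby("subject")["correct"].mean()
    excluded = sorted(acc.index[acc < threshold])
    return trials[~trials["subject"].isin(excluded)].copy(), list(excluded)


def accuracy_profile(trials: pd.DataFrame, masked: bool | None = None,
                     conditions: Sequence[str] | None = None,
                     ) -> ConditionProfile:
    """Per-condition mean accuracy, optionally restricted by masking flag.

    Conditions with no trials get NaN accuracy and zero count; downstream
    correlations drop them."""
    conditions = list(conditions or condition_labels())
    t = trials if masked is None else trials[trials["masked"] == masked]
    by = t.groupby("condition")["correct"]
    m, n = by.mean(), by.size()
    acc = np.array([m.get(c, np.nan) for c in conditions], dtype=float)
    cnt = np.array([int(n.get(c, 0)) for c in conditions])
    return ConditionProfile(conditions, acc, cnt)


def masking_effect(trials: pd.DataFrame,
                   conditions: Sequence[str] | None = None) -> np.ndarray:
    """Per-condition accuracy drop under backward masking
    (unmasked minus masked); NaN where either cell is missing."""
    conditions = list(conditions or condition_labels())
    un = accuracy_profile(trials, masked=False, conditions=conditions)
    ma = accuracy_profile(trials, masked=True, conditions=conditions)
    return un.accuracy - ma.accuracy


def rt_profile(trials: pd.DataFrame, masked: bool | None = None,
               conditions: Sequence[str] | None = None) -> np.ndarray:
    """Per-condition mean RT over trials that carry one."""
    conditions = list(conditions or condition_labels())
    t = trials if masked is None else trials[trials["masked"] == masked]
    t = t.dropna(subset=["rt"])
    m = t.groupby("condition")["rt"].mean()
    return np.array([m.get(c, np.nan) for c in conditions], dtype=float)


def easy_hard_split(profile: ConditionProfile, threshold: float = 0.9,
                    ) -> tuple[list[str], list[str]]:
    """Partition conditions into easy (accuracy strictly above threshold)
    and hard (the rest)."""
    easy = [c for c, a in zip(profile.conditions, profile.accuracy)
            if a > threshold]
    hard = [c for c in profile.conditions if c not in easy]
    return easy, hard


# ---------------------------------------------------------------------------
# Correlation statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise AnalysisError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return PearsonResult(float(r), float(p))


def consistency(model_profile: ConditionProfile,
                human_profile: ConditionProfile) -> PearsonResult:
    """Correlation between a model's and the humans' accuracy patterns
    across the shared conditions."""
    if model_profile.conditions != human_profile.conditions:
        raise AnalysisError("profiles must share the same condition index")
    return pearson(model_profile.accuracy, human_profile.accuracy)


def summarize_seeds(values: Sequence[float],
                    ci: float = 0.95) -> dict[str, float]:
    """Mean and percentile confidence interval over fine-tuning seeds."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return {"mean": float(v.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "n_seeds": int(v.size)}


def confusion_matrix(trials: pd.DataFrame,
                     categories: Sequence[str] | None = None,
                     ) -> ConfusionMatrix:
    """Counts of responses per presented category."""
    if categories is None:
        categories = sorted(set(trials["true"]) | set(trials["response"]))
    categories = list(categories)
    idx = {c: i for i, c in enumerate(categories)}
    unknown = (set(trials["true"]) | set(trials["response"])) - set(categories)
    if unknown:
        raise AnalysisError(f"unknown category labels: {sorted(unknown)}")
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for t, r in zip(trials["true"], trials["response"]):
        counts[idx[t], idx[r]] += 1
    return ConfusionMatrix(categories, counts)


def _offdiag(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    return a[~np.eye(n, dtype=bool)]


def confusion_correlation(a: ConfusionMatrix, b: ConfusionMatrix,
                          proportions: bool = True) -> PearsonResult:
    """Pearson correlation over the off-diagonal confusion cells.

    With ``proportions=True`` (default) each matrix's rows are first
    normalised to response proportions, so tables with different trial
    counts are comparable; raw-count mode is available."""
    if a.counts.shape != b.counts.shape:
        raise AnalysisError("confusion matrices must share shape")
    xa = a.proportions() if proportions else a.counts.astype(float)
    xb = b.proportions() if proportions else b.counts.astype(float)
    return pearson(_offdiag(xa), _offdiag(xb))


def split_half_reliability(trials: pd.DataFrame, unit: str = "condition_profile",
                           n_iter: int = 100, seed: int = 0,
                           conditions: Sequence[str] | None = None,
                           categories: Sequence[str] | None = None) -> float:
    """Mean correlation between the unit statistic computed on random
    subject halves, over ``n_iter`` iterations.

    ``unit='condition_profile'`` correlates the per-condition accuracies;
    ``unit='confusion'`` the off-diagonal confusion proportions."""
    if unit not in ("condition_profile", "confusion"):
        raise AnalysisError(f"unknown reliability unit {unit!r}")
    subjects = np.array(sorted(set(trials["subject"])))
    if subjects.size < 2:
        raise AnalysisError("split-half reliability needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    by_subject = dict(tuple(trials.groupby("subject")))
    rs = []
    for _ in range(n_iter):
        perm = rng.permutation(subjects)
        halves = perm[: subjects.size // 2], perm[subjects.size // 2:]
        stats = []
        for half in halves:
            sub = pd.concat([by_subject[s] for s in half], ignore_index=True)
            if unit == "condition_profile":
                stats.append(accuracy_profile(sub, conditions=conditions).accuracy)
            else:
                stats.append(_offdiag(
                    confusion_matrix(sub, categories=categories).proportions()))
        rs.append(pearson(stats[0], stats[1]).r)
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# Size / architecture effects
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series


def size_effect_regression(summaries: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares of accuracy on log10 size and architecture.

    ``summaries`` needs columns ``accuracy`` (per-model mean),
    ``n_parameters`` and ``recurrent`` (bool).  Size enters as
    log10(parameters); with one observation per model the random-effects
    structure of richer mixed models is unidentifiable, so OLS carries the
    same fixed-effect contrast."""
    df = summaries
    if len(df) < 4 or df["recurrent"].nunique() < 2:
        raise AnalysisError(
            "need >= 4 models spanning recurrent and feedforward classes")
    X = pd.DataFrame({
        "const": 1.0,
        "log10_size": np.log10(df["n_parameters"].astype(float)),
        "recurrent": df["recurrent"].astype(float),
    })
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise AnalysisError("collinear predictors: design matrix rank-deficient")
    fit = sm.OLS(df["accuracy"].astype(float), X).fit()
    return RegressionResult(params=fit.params, bse=fit.bse, pvalues=fit.pvalues)


def condition_ranking_consistency(per_condition: pd.DataFrame) -> pd.Series:
    """Per-condition agreement with the overall model performance order.

    ``per_condition`` is a conditions x models accuracy grid.  For each
    condition, the Pearson correlation between that condition's per-model
    accuracies and the models' overall (mean across conditions) accuracies;
    NaN where a condition has zero variance across models."""
    overall = per_condition.mean(axis=0)
    out = {}
    for cond, row in per_condition.iterrows():
        try:
            out[cond] = pearson(row.to_numpy(), overall.to_numpy()).r
        except UndefinedCorrelationError:
            out[cond] = np.nan
    return pd.Series(out)


def compare_groups(a: Sequence[float], b: Sequence[float] | None = None,
                   design: str = "paired_t",
                   groups: Sequence[Sequence[float]] | None = None,
                   ) -> tuple[float, float]:
    """Classical two-sided group comparison.

    ``design`` is ``paired_t``, ``independent_t`` (both need ``a``/``b``),
    or ``anova`` (needs ``groups``).  Returns (statistic, p)."""
    if design == "anova":
        groups = [np.asarray(g, dtype=float) for g in (groups or [])]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise AnalysisError("ANOVA needs >= 2 groups of >= 2 values")
        f, p = scipy.stats.f_oneway(*groups)
        return float(f), float(p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("group sizes must be >= 2")
    if design == "paired_t":
        if len(a) != len(b):
            raise AnalysisError("paired design needs equal-length groups")
        if (a == b).all():  # identical groups: no effect by construction
            return 0.0, 1.0
        t, p = scipy.stats.ttest_rel(a, b)
    elif design == "independent_t":
        t, p = scipy.stats.ttest_ind(a, b)
    else:
        raise AnalysisError(f"unknown design {design!r}")
    if np.isnan(t):
        raise AnalysisError("degenerate variance in group comparison")
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Benchmark report
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkReport:
    """Per-model behavioural benchmark against the (simulated) human data."""

    human: dict = field(default_factory=dict)
    models: list[dict] = field(default_factory=list)

    def to_json(self) -> dict:
        return {"human": self.human, "models": self.models}

    @classmethod
    def from_json(cls, payload: dict) -> "BenchmarkReport":
        return cls(human=payload.get("human", {}),
                   models=payload.get("models", []))

    def tidy(self) -> pd.DataFrame:
        """One row per model x metric x seed."""
        rows = []
        for m in self.models:
            for metric, values in m.get("per_seed", {}).items():
                for seed, value in zip(m["seeds"], values):
                    rows.append({"model": m["name"], "metric": metric,
                                 "seed": seed, "value": value})
        return pd.DataFrame(rows, columns=["model", "metric", "seed", "value"])


def build_benchmark_report(human_trials: pd.DataFrame,
                           model_tables: dict[str, list[pd.DataFrame]],
                           model_info: dict[str, dict],
                           conditions: Sequence[str] | None = None,
                           categories: Sequence[str] | None = None,
                           reliability_seed: int = 0) -> BenchmarkReport:
    """Assemble the full benchmark: human profile/reliability plus per-model
    accuracy, consistency, and confusion correlation summarised over seeds.

    ``model_tables`` maps model name to one trial table per fine-tuning
    seed; ``model_info`` supplies ``n_parameters``, ``recurrent`` and
    ``seeds`` per model.  Confidence intervals are computed over seeds.
    """
    conditions = list(conditions or condition_labels())
    hp = accuracy_profile(human_trials, conditions=conditions)
    hcm = confusion_matrix(human_trials, categories=categories)
    n_subj = human_trials["subject"].nunique()
    human = {
        "accuracy": float(np.nanmean(hp.accuracy)),
        "profile": dict(zip(hp.conditions, hp.accuracy.tolist())),
        "masking_effect": masking_effect(human_trials, conditions).tolist(),
    }
    if n_subj >= 2:
        human["reliability_profile"] = split_half_reliability(
            human_trials, "condition_profile", n_iter=25,
            seed=reliability_seed, conditions=conditions,
            categories=categories)
        human["reliability_confusion"] = split_half_reliability(
            human_trials, "confusion", n_iter=25,
            seed=reliability_seed, conditions=conditions,
            categories=categories)
    models = []
    for name, tables in model_tables.items():
        info = model_info.get(name, {})
        accs, cons, confr = [], [], []
        for t in tables:
            mp = accuracy_profile(t, conditions=conditions)
            accs.append(float(np.nanmean(t["correct"])))
            try:
                cons.append(consistency(mp, hp).r)
            except UndefinedCorrelationError:
                cons.append(np.nan)  # flat profile: consistency undefined
            try:
                confr.append(confusion_correlation(
                    confusion_matrix(t, categories=categories), hcm).r)
            except UndefinedCorrelationError:
                confr.append(np.nan)
        models.append({
            "name": name,
            "seeds": list(info.get("seeds", range(len(tables)))),
            "n_parameters": int(info.get("n_parameters", 0)),
            "recurrent": bool(info.get("recurrent", False)),
            "accuracy": summarize_seeds(accs),
            "consistency": summarize_seeds(cons),
            "confusion_correlation": summarize_seeds(confr),
            "per_seed": {"accuracy": accs, "consistency": cons,
                         "confusion_correlation": confr},
        })
    return BenchmarkReport(human=human, models=models)
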