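"""Statistical pipeline for the one-critical-trial behavioural experiments.

Implements, in order: the participant exclusion cascade; signal-detection
sensitivity estimates from the 40-trial discrimination block (with the
detection-d' conversion d'_detection = d'_discrimination / sqrt(2)); a
binary logistic regression of the reality judgment with backwards model
selection by BIC; a proportional-odds (cumulative logit) model of the
critical-trial vividness rating by judgment and condition; and group t-tests
of pre-critical vividness split by the correctness of the reality judgment.

Conventions that the underlying experiments leave open are fixed here and
documented: left tilt is treated as "signal" in the d' estimator, with the
log-linear correction (0.5 added to each response cell, 1 to each
denominator) so empty cells stay finite; condition is treatment-coded with
incongruent as the reference level (configurable); t-tests pool variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic_data import BehaviouralDataset

__all__ = [
    "ExclusionReport",
    "LogisticFit",
    "OrdinalContrast",
    "GroupTest",
    "dprime_from_block",
    "detection_from_discrimination",
    "apply_exclusions",
    "fit_reality_logistic",
    "fit_vividness_ordinal",
    "group_vividness_tests",
    "subject_measures",
    "analyze_experiment",
]

LOW_PERFORMANCE_THRESHOLD = 0.55

FULL_MODEL_TERMS = (
    "condition",
    "dprime_det",
    "vividness",
    "vividness:condition",
    "dprime_det:condition",
    "dprime_det:vividness",
)


class InvalidInputError(ValueError):
    """Input data do not satisfy an operation's preconditions."""


# ---------------------------------------------------------------------------
# sensitivity


def dprime_from_block(trials: pd.DataFrame) -> tuple[float, float]:
    """Discrimination d' and proportion correct from a 2AFC block.

    Left tilt is treated as signal: d' = z(hit rate) - z(false-alarm rate),
    where a hit is a "left" response to a left tilt and a false alarm a
    "left" response to a right tilt.  The log-linear correction (add 0.5 to
    each cell count, 1 to each denominator) keeps d' finite for perfect or
    empty cells.
    """
    left = trials[trials["true_tilt"] == "left"]
    right = trials[trials["true_tilt"] == "right"]
    if len(left) == 0 or len(right) == 0:
        raise InvalidInputError("block must contain both tilts")
    hits = (left["response_tilt"] == "left").sum()
    fas = (right["response_tilt"] == "left").sum()
    h = (hits + 0.5) / (len(left) + 1)
    fa = (fas + 0.5) / (len(right) + 1)
    d = float(stats.norm.ppf(h) - stats.norm.ppf(fa))
    pc = float(trials["correct"].mean())
    return d, pc


def detection_from_discrimination(dprime_disc: float | np.ndarray):
    """Convert discrimination d' to detection d' (divide by sqrt(2))."""
    return dprime_disc / np.sqrt(2.0)


def subject_measures(dataset: BehaviouralDataset) -> pd.DataFrame:
    """Per-subject derived measures used throughout the pipeline.

    Adds discrimination d' and proportion correct, detection d', mean
    pre-critical vividness, the binary reality judgment, and the
    wrong-grating indicator (a "real" report of the orientation orthogonal
    to the presented one; only defined when a stimulus was presented).
    """
    s = dataset.subjects.copy()
    pre_cols = [c for c in s.columns if c.startswith("pre_rating_")]
    s["mean_pre_vividness"] = s[pre_cols].mean(axis=1)

    disc = dataset.discrimination
    is_left = disc["true_tilt"] == "left"
    resp_left = disc["response_tilt"] == "left"
    g = pd.DataFrame(
        {
            "subject_id": disc["subject_id"],
            "hit": (is_left & resp_left).astype(int),
            "fa": (~is_left & resp_left).astype(int),
            "n_left": is_left.astype(int),
            "n_right": (~is_left).astype(int),
            "correct": disc["correct"],
        }
    ).groupby("subject_id")
    agg = g.sum()
    if (agg["n_left"] == 0).any() or (agg["n_right"] == 0).any():
        raise InvalidInputError("every block must contain both tilts")
    h = (agg["hit"] + 0.5) / (agg["n_left"] + 1)
    fa = (agg["fa"] + 0.5) / (agg["n_right"] + 1)
    agg["dprime_disc"] = stats.norm.ppf(h) - stats.norm.ppf(fa)
    agg["prop_correct"] = agg["correct"] / (agg["n_left"] + agg["n_right"])
    s = s.merge(
        agg[["dprime_disc", "prop_correct"]].reset_index(), on="subject_id"
    )
    s["dprime_det"] = detection_from_discrimination(s["dprime_disc"])
    s["judged_real"] = (s["immediate_response"] != "none").astype(int)
    s["wrong_grating"] = (
        (s["presented_class"] != "absent")
        & (s["immediate_response"] != "none")
        & (s["immediate_response"] != s["presented_class"])
    ).astype(int)
    return s


# ---------------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionReport:
    n_initial: int
    counts: dict[str, int]
    n_final: int

    def summary(self) -> str:
        lines = [f"initial subjects: {self.n_initial}"]
        lines += [f"  excluded ({k}): {v}" for k, v in self.counts.items()]
        lines.append(f"final subjects: {self.n_final}")
        return "\n".join(lines)


def apply_exclusions(
    dataset: BehaviouralDataset,
) -> tuple[BehaviouralDataset, ExclusionReport]:
    """Apply the participant exclusion cascade, in the reported order.

    1. technical issues; 2. multiple participation; 3. discrimination
    performance below 55% (strict); 4. self-reported non-imaginers;
    5. (stimulus-present experiments only) "real" reports of the orthogonal
    grating.  Each criterion is counted on the survivors of the previous
    one.  With no stimulus presented there is no orthogonal grating, so any
    "real" report is an analysable false alarm and nobody is excluded at
    step 5.
    """
    required = {"technical_issue", "multi_participation", "non_imaginer"}
    missing = required - set(dataset.subjects.columns)
    if missing:
        from .synthetic_data import SchemaError

        raise SchemaError(f"subjects table missing flag column(s): {sorted(missing)}")
    s = subject_measures(dataset)
    counts: dict[str, int] = {}
    keep = pd.Series(True, index=s.index)

    def exclude(name: str, mask: pd.Series) -> None:
        hit = keep & mask
        counts[name] = int(hit.sum())
        keep[hit] = False

    exclude("technical", s["technical_issue"] == 1)
    exclude("multi_participation", s["multi_participation"] == 1)
    exclude(
        "low_discrimination", s["prop_correct"] < LOW_PERFORMANCE_THRESHOLD
    )
    exclude("non_imaginer", s["non_imaginer"] == 1)
    exclude("wrong_grating", s["wrong_grating"] == 1)

    report = ExclusionReport(
        n_initial=len(s), counts=counts, n_final=int(keep.sum())
    )
    return dataset.subset(keep.to_numpy()), report


# ---------------------------------------------------------------------------
# logistic regression of reality judgments


@dataclass
class LogisticFit:
    """Backwards-BIC-selected logistic model of the reality judgment."""

    selected_terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    odds_ratios: pd.Series
    bic: float
    nagelkerke_r2: float
    classification_accuracy: float
    n_obs: int
    separation_flag: bool
    elimination_path: list[tuple[str, float]] = field(default_factory=list)

    def summary(self) -> str:
        rows = [
            f"{name:<28s} beta={self.params[name]: .3f} "
            f"SE={self.bse[name]:.3f} OR={self.odds_ratios[name]:.3f} "
            f"CI=[{self.conf_int.loc[name, 0]: .3f}, "
            f"{self.conf_int.loc[name, 1]: .3f}]"
            for name in self.params.index
        ]
        head = (
            f"logistic reality-judgment model (n={self.n_obs})\n"
            f"selected terms: {', '.join(self.selected_terms) or '(intercept only)'}\n"
            f"BIC={self.bic:.2f}  Nagelkerke R2={self.nagelkerke_r2:.3f}  "
            f"accuracy@0.5={self.classification_accuracy:.3f}"
        )
        if self.separation_flag:
            head += "\nWARNING: (quasi-)separation detected; estimates unstable"
        return head + "\n" + "\n".join(rows)


def _design_matrix(
    s: pd.DataFrame, terms: tuple[str, ...], condition_coding: str
) -> pd.DataFrame:
    if condition_coding == "treatment":
        cond = (s["condition"] == "congruent").astype(float)
    elif condition_coding == "effects":
        cond = np.where(s["condition"] == "congruent", 0.5, -0.5)
    else:
        raise InvalidInputError(f"unknown condition_coding {condition_coding!r}")
    # continuous covariates are mean-centred so that, when an interaction
    # survives selection, main effects stay interpretable at the sample mean
    dp = s["dprime_det"].astype(float)
    viv = s["mean_pre_vividness"].astype(float)
    base = {
        "condition": pd.Series(cond, index=s.index),
        "dprime_det": dp - dp.mean(),
        "vividness": viv - viv.mean(),
    }
    X = pd.DataFrame({"const": 1.0}, index=s.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = base[a] * base[b]
        else:
            X[term] = base[term]
    return X


def _nagelkerke(llf: float, llnull: float, n: int) -> float:
    cs = 1.0 - np.exp(2.0 / n * (llnull - llf))
    max_cs = 1.0 - np.exp(2.0 / n * llnull)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cs / max_cs, 0.0, 1.0))


def _hierarchy_ok(terms: tuple[str, ...], drop: str) -> bool:
    """A main effect may only leave once no interaction still contains it."""
    if ":" in drop:
        return True
    remaining = [t for t in terms if t != drop and ":" in t]
    return all(drop not in t.split(":") for t in remaining)


def fit_reality_logistic(
    dataset: BehaviouralDataset,
    condition_coding: str = "treatment",
) -> LogisticFit:
    """Backwards-BIC logistic regression of the reality judgment.

    The dependent variable codes "imagined" as 0 and "real" as 1.  The full
    model contains condition, detection d', mean pre-critical vividness and
    their pairwise interactions; terms are removed one at a time, each step
    dropping the term whose removal lowers BIC the most (respecting the
    marginality of main effects under their interactions), until no removal
    lowers BIC.
    """
    s = subject_measures(dataset)
    y = s["judged_real"].astype(float)
    for cond in s["condition"].unique():
        if (s["condition"] == cond).sum() < 2:
            raise InvalidInputError("need >= 2 subjects per condition")
    if y.nunique() < 2:
        raise InvalidInputError("both response classes must be present")

    def fit(terms: tuple[str, ...]):
        X = _design_matrix(s, terms, condition_coding)
        model = sm.Logit(y, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=False, maxiter=200)
            except (np.linalg.LinAlgError, PerfectSeparationError):
                # separation makes the Newton Hessian singular; BFGS still
                # yields the (boundary-drifting) estimates and likelihood
                res = model.fit(method="bfgs", disp=False, maxiter=500)
        return res

    terms = FULL_MODEL_TERMS
    res = fit(terms)
    path = [("(full)", res.bic)]
    while terms:
        candidates = []
        for drop in terms:
            if not _hierarchy_ok(terms, drop):
                continue
            reduced = tuple(t for t in terms if t != drop)
            candidates.append((fit(reduced).bic, drop, reduced))
        if not candidates:
            break
        best_bic, best_drop, best_terms = min(candidates)
        if best_bic >= res.bic:
            break
        terms = best_terms
        res = fit(terms)
        path.append((f"-{best_drop}", res.bic))

    try:
        bse = res.bse
        conf_int = res.conf_int()
    except (ValueError, np.linalg.LinAlgError):
        bse = pd.Series(np.nan, index=res.params.index)
        conf_int = pd.DataFrame(
            np.nan, index=res.params.index, columns=[0, 1]
        )
    separation = bool(
        (~np.isfinite(bse)).any() or (np.abs(res.params) > 15).any()
    )
    if separation:
        warnings.warn("possible (quasi-)separation in logistic fit", stacklevel=2)
    pred = (res.predict() >= 0.5).astype(float)
    return LogisticFit(
        selected_terms=terms,
        params=res.params,
        bse=bse,
        conf_int=conf_int,
        odds_ratios=np.exp(res.params),
        bic=float(res.bic),
        nagelkerke_r2=_nagelkerke(res.llf, res.llnull, int(res.nobs)),
        classification_accuracy=float((pred == y.to_numpy()).mean()),
        n_obs=int(res.nobs),
        separation_flag=separation,
        elimination_path=path,
    )


# ---------------------------------------------------------------------------
# ordinal model of critical-trial vividness


@dataclass
class OrdinalContrast:
    """Real-minus-imagined contrast on the latent vividness scale."""

    condition: str
    estimate: float
    se: float
    conf_int: tuple[float, float]
    p_value: float


def fit_vividness_ordinal(
    dataset: BehaviouralDataset,
    experiment: int,
    link: str = "logit",
) -> dict[str, OrdinalContrast]:
    """Proportional-odds model of the 1-5 critical-trial vividness rating.

    Experiment 1 regresses the rating on judgment (real=1), condition
    (congruent=1) and their interaction and returns the real-minus-imagined
    contrast within each condition; Experiment 2 (no stimulus) has a single
    judgment term and returns the contrast under "absent".  Positive
    contrasts mean higher vividness on real-judged trials.
    """
    s = subject_measures(dataset)
    ratings = s["critical_rating"].astype(int)
    if ratings.nunique() < 2:
        raise InvalidInputError("all critical ratings identical: degenerate outcome")
    judged = s["judged_real"].astype(float).to_numpy()
    if experiment == 1:
        cond = (s["condition"] == "congruent").astype(float).to_numpy()
        X = pd.DataFrame(
            {
                "judged_real": judged,
                "condition": cond,
                "judged_real:condition": judged * cond,
            },
            index=s.index,
        )
    elif experiment == 2:
        X = pd.DataFrame({"judged_real": judged}, index=s.index)
    else:
        raise InvalidInputError("experiment must be 1 or 2")

    y = pd.Categorical(ratings, categories=sorted(ratings.unique()), ordered=True)
    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = OrderedModel(y, X, distr=link).fit(
                method="bfgs", disp=False, maxiter=500
            )
        beta = res.params[:k].to_numpy()
        cov = res.cov_params().iloc[:k, :k].to_numpy()
    except (ValueError, np.linalg.LinAlgError):
        # singular Hessian (e.g. the judgment quasi-separates the ratings):
        # no usable estimates or uncertainty for the contrasts
        beta = np.full(k, np.nan)
        cov = np.full((k, k), np.nan)
    z = stats.norm.ppf(0.975)

    def contrast(weights: np.ndarray, condition: str) -> OrdinalContrast:
        est = float(weights @ beta)
        se = float(np.sqrt(weights @ cov @ weights))
        zval = est / se if se > 0 else np.nan
        return OrdinalContrast(
            condition=condition,
            estimate=est,
            se=se,
            conf_int=(est - z * se, est + z * se),
            p_value=float(2 * stats.norm.sf(abs(zval))),
        )

    if experiment == 1:
        return {
            "congruent": contrast(np.array([1.0, 0.0, 1.0]), "congruent"),
            "incongruent": contrast(np.array([1.0, 0.0, 0.0]), "incongruent"),
        }
    return {"absent": contrast(np.array([1.0]), "absent")}


# ---------------------------------------------------------------------------
# group vividness tests


@dataclass
class GroupTest:
    condition: str
    mean_real: float
    mean_imagined: float
    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    conf_int: tuple[float, float]
    n_real: int
    n_imagined: int


def group_vividness_tests(
    dataset: BehaviouralDataset,
    strict: bool = True,
) -> tuple[dict[str, GroupTest], dict[str, float]]:
    """Pre-critical vividness split by the reality judgment, per condition.

    Two-sided pooled-variance (Student) t-tests on subject-mean pre-critical
    vividness, comparing subjects who judged the critical trial real against
    those who judged it imagined, within each condition (conditions collapse
    to "absent" when no stimulus was presented).  Also returns the Pearson
    correlation between pre-critical vividness and discrimination d'.
    """
    s = subject_measures(dataset)
    cond_label = np.where(
        s["presented_class"] == "absent", "absent", s["condition"]
    )
    out: dict[str, GroupTest] = {}
    for cond in pd.unique(cond_label):
        sub = s[cond_label == cond]
        real = sub.loc[sub["judged_real"] == 1, "mean_pre_vividness"]
        imag = sub.loc[sub["judged_real"] == 0, "mean_pre_vividness"]
        if len(real) < 2 or len(imag) < 2:
            if strict:
                raise InvalidInputError(
                    f"condition {cond!r}: need >= 2 subjects per judgment group"
                )
            continue  # too few judgments of one kind: no test for this condition
        n1, n2 = len(real), len(imag)
        t, p = stats.ttest_ind(real, imag, equal_var=True)
        df = n1 + n2 - 2
        if not np.isfinite(t) and real.mean() == imag.mean():
            # zero pooled variance with equal means: exactly null
            t, p = 0.0, 1.0
        sp2 = (
            (n1 - 1) * real.var(ddof=1) + (n2 - 1) * imag.var(ddof=1)
        ) / df
        sp = np.sqrt(sp2)
        diff = real.mean() - imag.mean()
        se_diff = sp * np.sqrt(1 / n1 + 1 / n2)
        tcrit = stats.t.ppf(0.975, df)
        out[cond] = GroupTest(
            condition=cond,
            mean_real=float(real.mean()),
            mean_imagined=float(imag.mean()),
            t_statistic=float(t),
            df=df,
            p_value=float(p),
            cohens_d=float(diff / sp) if sp > 0 else 0.0,
            conf_int=(float(diff - tcrit * se_diff), float(diff + tcrit * se_diff)),
            n_real=n1,
            n_imagined=n2,
        )
    r, p = stats.pearsonr(s["mean_pre_vividness"], s["dprime_disc"])
    return out, {"r": float(r), "p": float(p), "n": int(len(s))}


# ---------------------------------------------------------------------------
# orchestration


def analyze_experiment(
    dataset: BehaviouralDataset,
    experiment: int,
    condition_coding: str = "treatment",
) -> dict:
    """Run the full pipeline on a raw dataset; returns a JSON-able report."""
    filtered, report = apply_exclusions(dataset)
    out: dict = {
        "experiment": experiment,
        "exclusions": {
            "n_initial": report.n_initial,
            "counts": report.counts,
            "n_final": report.n_final,
        },
    }
    s = subject_measures(filtered)
    out["p_real_by_condition"] = (
        s.groupby("condition")["judged_real"].mean().to_dict()
    )
    if experiment == 1:
        logit = fit_reality_logistic(filtered, condition_coding=condition_coding)
        cond_in = "condition" in logit.selected_terms
        out["logistic"] = {
            "selected_terms": list(logit.selected_terms),
            "coefficients": logit.params.to_dict(),
            "se": logit.bse.to_dict(),
            "odds_ratios": logit.odds_ratios.to_dict(),
            "bic": logit.bic,
            "nagelkerke_r2": logit.nagelkerke_r2,
            "classification_accuracy": logit.classification_accuracy,
            "condition_selected": cond_in,
            "condition_beta": float(logit.params.get("condition", 0.0)),
            "condition_se": float(logit.bse.get("condition", np.nan))
            if cond_in
            else None,
        }
    contrasts = fit_vividness_ordinal(filtered, experiment)
    out["vividness_contrasts"] = {
        c.condition: {
            "estimate": c.estimate,
            "se": c.se,
            "conf_int": list(c.conf_int),
            "p_value": c.p_value,
        }
        for c in contrasts.values()
    }
    tests, corr = group_vividness_tests(filtered, strict=False)
    out["group_vividness"] = {
        k: {
            "mean_real": v.mean_real,
            "mean_imagined": v.mean_imagined,
            "t": v.t_statistic,
            "df": v.df,
            "p": v.p_value,
            "cohens_d": v.cohens_d,
            "conf_int": list(v.conf_int),
        }
        for k, v in tests.items()
    }
    out["vividness_dprime_correlation"] = corr
    return out
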