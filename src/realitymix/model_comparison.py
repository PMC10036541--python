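"""Qualitative adjudication among the candidate reality-monitoring accounts.

The three canonical accounts (source separation, Perky-style suppression,
complete source mixing) make qualitatively different predictions for four
contrasts: the condition effect on the "real"-judgment rate (congruent minus
incongruent) and the real-minus-imagined vividness contrast within the
congruent, incongruent and stimulus-absent conditions.  This module turns an
empirical analysis report into a sign pattern, scores it against each
model's predicted signature, sweeps the task-engagement gains to check the
signatures are robust to disengagement, and validates the whole procedure by
simulation (model recovery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavioural_analysis as ba
from . import synthetic_data as syn
from .sdt_models import (
    InvalidParameterError,
    ModelSpec,
    SignaturePattern,
    predicted_signature,
)

__all__ = [
    "SignaturePattern",
    "CORE_MODELS",
    "observed_signature",
    "match_models",
    "engagement_sweep",
    "model_recovery",
]

#: the three theoretical accounts the adjudication distinguishes
CORE_MODELS = ("source_separation", "perky", "mixing")

DEFAULT_ALPHA_GRID = (0.5, 1.0, 2.0)
DEFAULT_GAIN_GRID = (0.25, 0.5, 0.75, 1.0)

#: zero-band on estimate/SE: a contrast counts as a non-zero sign only when
#: statistically distinguishable from zero at this |z|.  The default holds
#: the familywise false-sign rate over the four contrasts near 5%
#: (Bonferroni 0.05/4 -> |z| = 2.50); see docs/methods.md.
DEFAULT_Z_BAND = 2.50


def _sign_z(estimate: float, se: float | None, z_band: float) -> int:
    if se is None or not np.isfinite(estimate):
        return 0
    if not np.isfinite(se):
        return 0  # unidentified contrast carries no sign information
    if se == 0:
        return int(np.sign(estimate))
    z = estimate / se
    if abs(z) <= z_band:
        return 0
    return 1 if z > 0 else -1


def observed_signature(
    report_exp1: dict,
    report_exp2: dict | None = None,
    z_band: float = DEFAULT_Z_BAND,
) -> SignaturePattern:
    """Sign pattern of the empirical contrasts from analysis report(s).

    The condition effect comes from the selected logistic model (a term
    removed by BIC backwards selection counts as 0); the vividness contrasts
    come from the ordinal real-minus-imagined estimates.  Each estimate is
    mapped to a sign with the standardized zero-band ``z_band``.
    """
    try:
        logit = report_exp1["logistic"]
        viv1 = report_exp1["vividness_contrasts"]
    except KeyError as err:
        raise ba.InvalidInputError(f"report missing section: {err}") from err
    if logit.get("condition_selected", False):
        sign_cond = _sign_z(
            logit["condition_beta"], logit.get("condition_se"), z_band
        )
    else:
        sign_cond = 0

    def viv_sign(report_section: dict, condition: str) -> int:
        if condition not in report_section:
            raise ba.InvalidInputError(f"missing vividness contrast: {condition}")
        c = report_section[condition]
        return _sign_z(c["estimate"], c["se"], z_band)

    sign_absent = 0
    if report_exp2 is not None:
        sign_absent = viv_sign(report_exp2["vividness_contrasts"], "absent")
    return SignaturePattern(
        sign_condition_effect=sign_cond,
        sign_vividness_by_judgment_congruent=viv_sign(viv1, "congruent"),
        sign_vividness_by_judgment_incongruent=viv_sign(viv1, "incongruent"),
        sign_vividness_by_judgment_absent=sign_absent,
    )


def _match_score(observed: SignaturePattern, predicted: SignaturePattern) -> int:
    """Weighted sign agreement between observed and predicted contrasts.

    A reliably observed (non-zero) effect is strong evidence: +2 when the
    model predicts the same sign, -2 when the model predicts the opposite
    sign or no effect at all.  An observed zero is weak evidence: +1 when
    the model also predicts no effect, 0 when the model predicts one (the
    data may simply be underpowered for that contrast).
    """
    score = 0
    for o, p in zip(observed.as_tuple(), predicted.as_tuple()):
        if o != 0:
            score += 2 if o == p else -2
        else:
            score += 1 if p == 0 else 0
    return score


def match_models(
    observed: SignaturePattern,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    models: tuple[str, ...] = CORE_MODELS,
    n_sim: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Score the observed signature against each model's predictions.

    For each model and each mixture weight alpha on the grid the predicted
    signature is computed (analytically by default, by Monte-Carlo when
    ``n_sim`` is given) and compared with the observed pattern.  A model's
    score is its best score over the grid.  Returns the per-cell table and
    the list of best models — ties are all reported, never broken.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for model_id in models:
        for alpha in alpha_grid:
            spec = ModelSpec(model_id, alpha=alpha)
            pred = predicted_signature(
                spec, n_sim=n_sim, seed=rng if n_sim else 0
            )
            rows.append(
                {
                    "model": model_id,
                    "alpha": alpha,
                    "predicted": pred.as_tuple(),
                    "score": _match_score(observed, pred),
                }
            )
    table = pd.DataFrame(rows)
    per_model = table.groupby("model")["score"].max()
    best_score = per_model.max()
    best = sorted(per_model[per_model == best_score].index)
    return table, best


def engagement_sweep(
    model: ModelSpec,
    attention_grid: tuple[float, ...] = DEFAULT_GAIN_GRID,
    imagery_grid: tuple[float, ...] = DEFAULT_GAIN_GRID,
    n_sim: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Signature of ``model`` at every task-engagement gain combination.

    The attention gain scales the stimulus input, the imagery gain scales
    the imagery signal.  Each grid cell's signature is compared against the
    full-engagement cell (both gains 1); ``signs_changed`` flags cells whose
    non-zero signs differ, i.e. where disengagement would alter the
    qualitative prediction.
    """
    if min(attention_grid) < 0 or min(imagery_grid) < 0:
        raise InvalidParameterError("gains must be >= 0")
    rng = np.random.default_rng(seed)

    def signature(ag: float, ig: float) -> SignaturePattern:
        return predicted_signature(
            model.with_gains(ag, ig), n_sim=n_sim, seed=rng if n_sim else 0
        )

    reference = signature(1.0, 1.0).as_tuple()
    rows = []
    for ag in attention_grid:
        for ig in imagery_grid:
            sig = signature(ag, ig).as_tuple()
            changed = any(
                s != r for s, r in zip(sig, reference) if s != 0 and r != 0
            ) or any(
                (s == 0) != (r == 0) for s, r in zip(sig, reference)
            )
            rows.append(
                {
                    "attention_gain": ag,
                    "imagery_gain": ig,
                    "signature": sig,
                    "signs_changed": changed,
                }
            )
    return pd.DataFrame(rows)


def model_recovery(
    n_replicates: int = 20,
    n_per_condition: int = 500,
    seed: int = 0,
    models: tuple[str, ...] = CORE_MODELS,
    alpha: float = 1.0,
    design: syn.BehaviouralDesign | None = None,
) -> pd.DataFrame:
    """Confusion matrix of generative model vs best-matched model.

    For every replicate and generative account: synthesize Experiment 1 and
    Experiment 2 datasets, run the full behavioural pipeline (exclusions,
    BIC-selected logistic, ordinal contrasts), extract the observed
    signature and match it against the candidate signatures.  Ties split
    their replicate evenly across the tied models, so rows sum to the
    replicate count.
    """
    if n_per_condition < 50:
        raise InvalidParameterError("n_per_condition must be >= 50")
    rng = np.random.default_rng(seed)
    confusion = pd.DataFrame(
        0.0, index=list(models), columns=list(models)
    )
    for gen_id in models:
        spec = ModelSpec(gen_id, alpha=alpha)
        for _ in range(n_replicates):
            ds1 = syn.generate_experiment(
                spec, 1, n_per_condition, design=design, seed=rng
            )
            ds2 = syn.generate_experiment(
                spec, 2, n_per_condition, design=design, seed=rng
            )
            rep1 = ba.analyze_experiment(ds1, 1)
            rep2 = ba.analyze_experiment(ds2, 2)
            obs = observed_signature(rep1, rep2)
            _, best = match_models(obs, models=models)
            for b in best:
                confusion.loc[gen_id, b] += 1.0 / len(best)
    return confusion
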