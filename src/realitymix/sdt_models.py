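"""Generative signal-detection models of perceptual reality monitoring.

Four candidate accounts of how an imagined and a perceived signal combine
into a single subjective experience are implemented on a common two-channel
(left-tilt / right-tilt) Gaussian signal-detection scaffold:

``source_separation``
    Percept and imagery are read out independently: ``P = X``, ``I = V``.
``perky``
    Imagery suppresses (explains away) matching external input:
    ``P = alpha*X - V``, ``I = V``.
``mixing``
    External and internal signals sum into one inseparable experience:
    ``P = I = V + alpha*X``.
``mixing_2param``
    Two-parameter mixing with separate weights for the source judgment and
    the vividness judgment: ``P = X + alpha*V``, ``I = V + beta*X``.
    Reduces to ``mixing`` at ``alpha = beta = 1``.

On every trial the perceptual sample ``X`` is drawn from a bivariate Gaussian
whose mean is ``[1, 0]`` (left-tilted stimulus), ``[0, 1]`` (right-tilted) or
``[0, 0]`` (stimulus absent), and the vividness sample ``V`` from a bivariate
Gaussian with mean ``[V_S, 0]`` or ``[0, V_S]`` on the imagined channel,
where the subject's mean vividness ``V_S ~ N(2.5, 1)``.  The integrated
percept is compared against a fixed reality threshold ``T = 2.5``: the trial
is judged *real* iff ``max(P) > T`` (strictly), otherwise *imagined*.

Besides a Monte-Carlo cohort simulator, the module provides closed-form /
quadrature oracles for the probability of a "real" judgment and for the
expected reported vividness conditional on the judgment, which together give
each model's qualitative signature (the pattern in the simulated figure
panels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "MODEL_IDS",
    "CONDITIONS",
    "StimulusSpec",
    "ImagerySpec",
    "ModelSpec",
    "TrialOutcome",
    "ConditionPrediction",
    "SignaturePattern",
    "sample_trial_components",
    "combine_sources",
    "judge_and_rate",
    "simulate_cohort",
    "analytic_p_real",
    "conditional_vividness_oracle",
    "predicted_signature",
    "condition_prediction",
]

MODEL_IDS = ("source_separation", "perky", "mixing", "mixing_2param")
CONDITIONS = ("congruent", "incongruent", "absent")

#: population distribution of mean imagery vividness across subjects
V_S_MEAN = 2.5
V_S_SD = 1.0

_CLASS_MEANS = {
    "left": np.array([1.0, 0.0]),
    "right": np.array([0.0, 1.0]),
    "absent": np.array([0.0, 0.0]),
}

# condition -> stimulus class, given that imagery is always for left tilt
_CONDITION_STIMULUS = {"congruent": "left", "incongruent": "right", "absent": "absent"}


class InvalidParameterError(ValueError):
    """A model / simulation parameter is outside its valid domain."""


class UnsupportedConfigurationError(ValueError):
    """The analytic oracles only support identity channel covariances."""


def _check_pd(sigma: np.ndarray, name: str) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (2, 2) or not np.allclose(sigma, sigma.T):
        raise InvalidParameterError(f"{name} must be a symmetric 2x2 matrix")
    eigvals = np.linalg.eigvalsh(sigma)
    if np.any(eigvals < -1e-12):
        raise InvalidParameterError(f"{name} must be positive (semi-)definite")
    return sigma


@dataclass(frozen=True)
class StimulusSpec:
    """External stimulus on a trial: tilt class and channel-noise model."""

    stimulus_class: Literal["left", "right", "absent"]
    Sigma_X: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        if self.stimulus_class not in _CLASS_MEANS:
            raise InvalidParameterError(
                f"unknown stimulus_class {self.stimulus_class!r}"
            )
        object.__setattr__(self, "Sigma_X", _check_pd(self.Sigma_X, "Sigma_X"))

    @property
    def mu_X(self) -> np.ndarray:
        return _CLASS_MEANS[self.stimulus_class].copy()


@dataclass(frozen=True)
class ImagerySpec:
    """Imagery instruction on a trial: imagined tilt and subject vividness."""

    imagined_class: Literal["left", "right"] = "left"
    V_S: float = V_S_MEAN
    Sigma_V: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        if self.imagined_class not in ("left", "right"):
            raise InvalidParameterError(
                f"unknown imagined_class {self.imagined_class!r}"
            )
        object.__setattr__(self, "Sigma_V", _check_pd(self.Sigma_V, "Sigma_V"))

    @property
    def mu_V(self) -> np.ndarray:
        mu = np.zeros(2)
        mu[self.channel] = self.V_S
        return mu

    @property
    def channel(self) -> int:
        """Index of the imagined orientation channel (0 = left, 1 = right)."""
        return 0 if self.imagined_class == "left" else 1


@dataclass(frozen=True)
class ModelSpec:
    """Which generative account to use and its parameters.

    Parameters
    ----------
    model_id
        One of :data:`MODEL_IDS`.
    alpha, beta
        Non-negative mixture weights.  ``beta`` is only meaningful for
        ``mixing_2param``; the one-parameter ``mixing`` model ties the
        percept and imagery weights together.
    T
        Reality threshold in vividness-rating units (default 2.5, the
        population-mean vividness).
    attention_gain
        Multiplies the stimulus channel mean ``mu_X`` (task-engagement /
        external-attention scaling).
    imagery_gain
        Multiplies the subject's mean vividness ``V_S`` (imagery-engagement
        scaling).
    """

    model_id: str
    alpha: float = 1.0
    beta: float = 1.0
    T: float = 2.5
    attention_gain: float = 1.0
    imagery_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise InvalidParameterError(f"unknown model_id {self.model_id!r}")
        for name in ("alpha", "beta", "attention_gain", "imagery_gain"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    def with_gains(self, attention_gain: float, imagery_gain: float) -> "ModelSpec":
        return replace(
            self, attention_gain=attention_gain, imagery_gain=imagery_gain
        )


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated critical trial."""

    X_sample: np.ndarray
    V_sample: np.ndarray
    P: np.ndarray
    I: np.ndarray
    judged_real: bool
    reported_class: Literal["left", "right", "none"]
    vividness_raw: float
    vividness_rating: int


@dataclass(frozen=True)
class ConditionPrediction:
    """Model prediction for one condition (one simulated figure panel)."""

    condition: str
    p_real: float
    mean_vividness_given_real: float
    mean_vividness_given_imagined: float
    n_effective: int


@dataclass(frozen=True)
class SignaturePattern:
    """Qualitative direction pattern that adjudicates between the accounts.

    Each field is a sign in {-1, 0, +1}: the condition effect on the "real"
    rate (congruent minus incongruent) and the real-minus-imagined vividness
    contrast within each condition.
    """

    sign_condition_effect: int
    sign_vividness_by_judgment_congruent: int
    sign_vividness_by_judgment_incongruent: int
    sign_vividness_by_judgment_absent: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.sign_condition_effect,
            self.sign_vividness_by_judgment_congruent,
            self.sign_vividness_by_judgment_incongruent,
            self.sign_vividness_by_judgment_absent,
        )


def stimulus_for_condition(condition: str) -> StimulusSpec:
    """Stimulus class implied by a condition when imagery is for left tilt."""
    if condition not in _CONDITION_STIMULUS:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    return StimulusSpec(_CONDITION_STIMULUS[condition])


def sample_trial_components(
    stimulus: StimulusSpec,
    imagery: ImagerySpec,
    model: ModelSpec,
    rng: np.random.Generator,
    size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the perceptual sample X and vividness sample V for trial(s).

    ``X ~ N(attention_gain * mu_X, Sigma_X)`` and
    ``V ~ N(mu_V with V_S scaled by imagery_gain, Sigma_V)``, independently.
    With ``size=None`` returns two 2-vectors, otherwise ``(size, 2)`` arrays.
    """
    n = 1 if size is None else int(size)
    mu_x = model.attention_gain * stimulus.mu_X
    mu_v = np.zeros(2)
    mu_v[imagery.channel] = model.imagery_gain * imagery.V_S
    # allow degenerate (zero) covariance for exact-limit tests
    lx = np.linalg.cholesky(stimulus.Sigma_X + 1e-300 * np.eye(2))
    lv = np.linalg.cholesky(imagery.Sigma_V + 1e-300 * np.eye(2))
    X = mu_x + rng.standard_normal((n, 2)) @ lx.T
    V = mu_v + rng.standard_normal((n, 2)) @ lv.T
    if size is None:
        return X[0], V[0]
    return X, V


def combine_sources(
    model: ModelSpec, X: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Form the integrated percept P and imagery experience I.

    Accepts single 2-vectors or ``(n, 2)`` arrays (vectorised).
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(V))):
        raise InvalidParameterError("X and V must be finite")
    if model.model_id == "source_separation":
        return X.copy(), V.copy()
    if model.model_id == "perky":
        return model.alpha * X - V, V.copy()
    if model.model_id == "mixing":
        P = V + model.alpha * X
        return P, P.copy()
    if model.model_id == "mixing_2param":
        return X + model.alpha * V, V + model.beta * X
    raise InvalidParameterError(f"unknown model_id {model.model_id!r}")


def _rate(raw: np.ndarray | float, lo: int = 1, hi: int = 5) -> np.ndarray | int:
    """Clip to the rating scale then round half-up to the nearest integer."""
    clipped = np.clip(raw, lo, hi)
    rating = np.floor(clipped + 0.5).astype(int)
    return np.clip(rating, lo, hi)


def judge_and_rate(
    P: np.ndarray,
    I: np.ndarray,
    imagery: ImagerySpec,
    model: ModelSpec,
) -> tuple[bool, str, float, int]:
    """Apply the reality-threshold readout to one trial.

    The trial is judged real iff the maximum percept channel strictly
    exceeds T; the reported orientation is the argmax channel.  The
    vividness report is the imagined-orientation channel of I, discretised
    to the 1-5 scale.
    """
    P = np.asarray(P, dtype=float)
    I = np.asarray(I, dtype=float)
    judged_real = bool(np.max(P) > model.T)
    if judged_real:
        reported = "left" if P[0] >= P[1] else "right"
    else:
        reported = "none"
    raw = float(I[imagery.channel])
    return judged_real, reported, raw, int(_rate(raw))


def simulate_cohort(
    model: ModelSpec,
    condition: str,
    n_subjects: int,
    seed: int | np.random.Generator,
    truncate_vs: bool = False,
) -> pd.DataFrame:
    """Simulate one critical trial for each of ``n_subjects`` subjects.

    Each subject contributes a single trial with their own mean vividness
    ``V_S ~ N(2.5, 1)``; imagery is always for the left tilt and the
    stimulus class follows the condition.  Returns a tidy frame, one row per
    subject, with samples, percepts, judgments and vividness reports.

    ``truncate_vs`` optionally clips negative V_S draws at 0 (sensitivity
    analysis; off by default, matching the untruncated population model).
    """
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    stimulus = stimulus_for_condition(condition)
    rng = np.random.default_rng(seed)
    v_s = V_S_MEAN + V_S_SD * rng.standard_normal(n_subjects)
    if truncate_vs:
        v_s = np.maximum(v_s, 0.0)

    mu_x = model.attention_gain * stimulus.mu_X
    X = mu_x + rng.standard_normal((n_subjects, 2))
    V = rng.standard_normal((n_subjects, 2))
    V[:, 0] += model.imagery_gain * v_s  # imagined channel = left
    P, I = combine_sources(model, X, V)

    judged_real = np.max(P, axis=1) > model.T
    argmax_left = P[:, 0] >= P[:, 1]
    reported = np.where(
        judged_real, np.where(argmax_left, "left", "right"), "none"
    )
    raw = I[:, 0]
    rating = _rate(raw)

    return pd.DataFrame(
        {
            "subject_id": np.arange(n_subjects),
            "model": model.model_id,
            "condition": condition,
            "alpha": model.alpha,
            "beta": model.beta,
            "T": model.T,
            "attention_gain": model.attention_gain,
            "imagery_gain": model.imagery_gain,
            "V_S": v_s,
            "X1": X[:, 0],
            "X2": X[:, 1],
            "V1": V[:, 0],
            "V2": V[:, 1],
            "P1": P[:, 0],
            "P2": P[:, 1],
            "I1": I[:, 0],
            "I2": I[:, 1],
            "judged_real": judged_real.astype(int),
            "reported_class": reported,
            "vividness_raw": raw,
            "vividness_rating": rating,
        }
    )


def _channel_moments(model: ModelSpec, condition: str) -> dict[str, float]:
    """Moments of (P1, P2, I1) with V_S marginalised, identity covariances.

    Channel 1 is the imagined (left) channel.  Every percept channel is a
    linear combination of independent Gaussians: X_k ~ N(x_k, 1) with x_1 =
    attention_gain for the congruent condition (x_2 for incongruent), and
    V_1 ~ N(imagery_gain * 2.5, 1 + imagery_gain^2) after marginalising
    V_S ~ N(2.5, 1); V_2 ~ N(0, 1).
    """
    if condition not in CONDITIONS:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    gx, gi, a, b = model.attention_gain, model.imagery_gain, model.alpha, model.beta
    x1 = gx if condition == "congruent" else 0.0
    x2 = gx if condition == "incongruent" else 0.0
    mv1, vv1 = gi * V_S_MEAN, 1.0 + gi**2 * V_S_SD**2

    if model.model_id == "source_separation":
        return dict(mP1=x1, vP1=1.0, mP2=x2, vP2=1.0, mI1=mv1, vI1=vv1, cov=0.0)
    if model.model_id == "perky":
        return dict(
            mP1=a * x1 - mv1, vP1=a**2 + vv1,
            mP2=a * x2, vP2=a**2 + 1.0,
            mI1=mv1, vI1=vv1, cov=-vv1,
        )
    if model.model_id == "mixing":
        vP1 = vv1 + a**2
        return dict(
            mP1=mv1 + a * x1, vP1=vP1,
            mP2=a * x2, vP2=1.0 + a**2,
            mI1=mv1 + a * x1, vI1=vP1, cov=vP1,
        )
    if model.model_id == "mixing_2param":
        return dict(
            mP1=x1 + a * mv1, vP1=1.0 + a**2 * vv1,
            mP2=x2, vP2=1.0 + a**2,
            mI1=mv1 + b * x1, vI1=vv1 + b**2,
            cov=b + a * vv1,
        )
    raise InvalidParameterError(f"unknown model_id {model.model_id!r}")


def _require_identity_covariances(
    Sigma_X: np.ndarray | None, Sigma_V: np.ndarray | None
) -> None:
    for name, sigma in (("Sigma_X", Sigma_X), ("Sigma_V", Sigma_V)):
        if sigma is not None and not np.allclose(sigma, np.eye(2)):
            raise UnsupportedConfigurationError(
                f"analytic oracle requires identity {name}"
            )


def analytic_p_real(
    model: ModelSpec,
    condition: str,
    Sigma_X: np.ndarray | None = None,
    Sigma_V: np.ndarray | None = None,
) -> float:
    """Closed-form probability of a "real" judgment, V_S marginalised.

    With identity channel covariances the two percept channels are
    independent Gaussians, so
    ``p_real = 1 - Phi((T - mu1)/s1) * Phi((T - mu2)/s2)``.
    """
    _require_identity_covariances(Sigma_X, Sigma_V)
    m = _channel_moments(model, condition)
    return float(
        1.0
        - norm.cdf((model.T - m["mP1"]) / np.sqrt(m["vP1"]))
        * norm.cdf((model.T - m["mP2"]) / np.sqrt(m["vP2"]))
    )


def conditional_vividness_oracle(
    model: ModelSpec,
    condition: str,
    judgment: Literal["real", "imagined"],
    Sigma_X: np.ndarray | None = None,
    Sigma_V: np.ndarray | None = None,
    tol: float = 1e-6,
) -> float:
    """Expected raw vividness report conditional on the reality judgment.

    Integrates ``E[I1 | max(P) > T]`` (or ``<= T``) by deterministic 2-D
    quadrature over the joint Gaussian of the imagined-channel percept P1
    and imagery experience I1, combined with the independent exceedance
    probability of the other percept channel.
    """
    if judgment not in ("real", "imagined"):
        raise InvalidParameterError(f"unknown judgment {judgment!r}")
    _require_identity_covariances(Sigma_X, Sigma_V)
    m = _channel_moments(model, condition)
    T = model.T
    if m["cov"] == 0.0:
        # I1 independent of both percept channels: conditioning is inert
        return float(m["mI1"])
    sP1, sI1 = np.sqrt(m["vP1"]), np.sqrt(m["vI1"])
    rho = m["cov"] / (sP1 * sI1)
    rho = float(np.clip(rho, -1.0, 1.0))
    q2 = float(1.0 - norm.cdf((T - m["mP2"]) / np.sqrt(m["vP2"])))  # P(P2 > T)

    if abs(rho) > 1 - 1e-12:
        # degenerate joint (e.g. mixing, where I1 == P1): integrate in 1-D
        def weight(p: np.ndarray) -> np.ndarray:
            above = p > T
            w_real = np.where(above, 1.0, q2)
            return w_real if judgment == "real" else np.where(above, 0.0, 1.0)

        def num_int(p):
            i1 = m["mI1"] + m["cov"] / m["vP1"] * (p - m["mP1"])
            return i1 * norm.pdf(p, m["mP1"], sP1) * weight(np.asarray(p))

        def den_int(p):
            return norm.pdf(p, m["mP1"], sP1) * weight(np.asarray(p))

        lo, hi = m["mP1"] - 10 * sP1, m["mP1"] + 10 * sP1
        num = sum(
            integrate.quad(num_int, a, b, epsabs=tol, epsrel=tol)[0]
            for a, b in ((lo, T), (T, hi))
        )
        den = sum(
            integrate.quad(den_int, a, b, epsabs=tol, epsrel=tol)[0]
            for a, b in ((lo, T), (T, hi))
        )
        return float(num / den)

    # full 2-D quadrature over the joint density of (P1, I1)
    det = m["vP1"] * m["vI1"] - m["cov"] ** 2
    inv = np.linalg.inv(np.array([[m["vP1"], m["cov"]], [m["cov"], m["vI1"]]]))

    def density(i: float, p: float) -> float:
        d = np.array([p - m["mP1"], i - m["mI1"]])
        return np.exp(-0.5 * d @ inv @ d) / (2 * np.pi * np.sqrt(det))

    def w(p: float) -> float:
        if judgment == "real":
            return 1.0 if p > T else q2
        return 0.0 if p > T else 1.0

    i_lo, i_hi = m["mI1"] - 10 * sI1, m["mI1"] + 10 * sI1
    p_lo, p_hi = m["mP1"] - 10 * sP1, m["mP1"] + 10 * sP1
    num = den = 0.0
    for a, b in ((p_lo, min(T, p_hi)), (min(T, p_hi), p_hi)):
        if b <= a:
            continue
        num += integrate.dblquad(
            lambda i, p: i * density(i, p) * w(p), a, b, i_lo, i_hi,
            epsabs=tol, epsrel=tol,
        )[0]
        den += integrate.dblquad(
            lambda i, p: density(i, p) * w(p), a, b, i_lo, i_hi,
            epsabs=tol, epsrel=tol,
        )[0]
    return float(num / den)


def condition_prediction(
    model: ModelSpec,
    condition: str,
    n_sim: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ConditionPrediction:
    """Predicted "real" rate and judgment-conditional vividness.

    Analytic (oracle) when ``n_sim`` is None, Monte-Carlo otherwise.
    """
    if n_sim is None:
        return ConditionPrediction(
            condition=condition,
            p_real=analytic_p_real(model, condition),
            mean_vividness_given_real=conditional_vividness_oracle(
                model, condition, "real"
            ),
            mean_vividness_given_imagined=conditional_vividness_oracle(
                model, condition, "imagined"
            ),
            n_effective=0,
        )
    df = simulate_cohort(model, condition, n_sim, seed)
    real = df["judged_real"] == 1
    return ConditionPrediction(
        condition=condition,
        p_real=float(real.mean()),
        mean_vividness_given_real=float(df.loc[real, "vividness_raw"].mean()),
        mean_vividness_given_imagined=float(df.loc[~real, "vividness_raw"].mean()),
        n_effective=int(len(df)),
    )


def _sign(x: float, band: float) -> int:
    if not np.isfinite(x) or abs(x) <= band:
        return 0
    return 1 if x > 0 else -1


def predicted_signature(
    model: ModelSpec,
    n_sim: int | None = None,
    seed: int | np.random.Generator = 0,
    band_p: float = 0.02,
    band_vividness: float = 0.05,
) -> SignaturePattern:
    """Qualitative signature of a model across the three conditions.

    Signs of (p_real congruent - incongruent) and of the real-minus-imagined
    vividness contrast within each condition.  Analytic signatures use an
    effectively exact zero-band (1e-9); Monte-Carlo signatures (``n_sim``
    given) use ``band_p`` / ``band_vividness`` to absorb sampling noise.
    """
    if n_sim is None:
        # tiny band absorbing quadrature error (real effects are >= ~1e-2)
        band_p = band_vividness = 1e-5
        preds = {c: condition_prediction(model, c) for c in CONDITIONS}
    else:
        rng = np.random.default_rng(seed)
        preds = {
            c: condition_prediction(model, c, n_sim=n_sim, seed=rng)
            for c in CONDITIONS
        }
    viv = {
        c: preds[c].mean_vividness_given_real
        - preds[c].mean_vividness_given_imagined
        for c in CONDITIONS
    }
    return SignaturePattern(
        sign_condition_effect=_sign(
            preds["congruent"].p_real - preds["incongruent"].p_real, band_p
        ),
        sign_vividness_by_judgment_congruent=_sign(viv["congruent"], band_vividness),
        sign_vividness_by_judgment_incongruent=_sign(
            viv["incongruent"], band_vividness
        ),
        sign_vividness_by_judgment_absent=_sign(viv["absent"], band_vividness),
    )
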