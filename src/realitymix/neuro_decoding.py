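"""Cross-decoding analyses of subjective strength and stimulus content.

Tests the neural-level prediction of the source-mixing account: if imagery
vividness and perceptual visibility index one shared "strength" variable,
a classifier trained to separate low from high vividness during imagery
should transfer to low versus high visibility during perception (and vice
versa), once overall amplitude differences between the modalities are
removed.

Pipeline, per participant: 4-point ratings are binarised (1-2 = low,
3-4 = high); participants with too few trials per class are excluded; the
majority class is down-sampled to balance low/high within each modality;
each modality's feature means are removed (mean-centring).  Decoding uses a
shrinkage-regularised linear discriminant (features may outnumber trials),
training on one modality and testing on the other, averaging the two
directions.  Group inference permutes class labels prior to decoding (25
permutations per participant) and bootstraps a group null distribution of
mean accuracies.  Stimulus content is decoded pairwise over the six
stimulus pairs, trained on low- or high-rating trials of one modality and
tested on all trials of the other, which probes whether perception looks
like high-vividness imagery and imagery like low-visibility perception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .sdt_models import InvalidParameterError
from .synthetic_data import MODALITIES, N_STIMULI, ParticipantPatterns, PatternDataset

__all__ = [
    "DecodePrep",
    "PreparedParticipant",
    "DecodingResult",
    "EmptyCohortError",
    "prepare_patterns",
    "cross_decode_strength",
    "permutation_group_test",
    "pairwise_content_crossdecode",
    "univariate_modulation",
]

MIN_TRIALS_PER_CLASS = 10  # strength decoding
MIN_TRIALS_PER_STIMULUS_LEVEL = 2  # content decoding


class EmptyCohortError(ValueError):
    """No participant satisfies the task's minimum trial counts."""


@dataclass
class PreparedParticipant:
    participant_id: int
    data: np.ndarray  # (n_trials, n_features), centred within modality
    modality: np.ndarray
    level: np.ndarray  # "low" / "high" binarised rating
    rating: np.ndarray
    stimulus: np.ndarray

    def mask(self, modality: str) -> np.ndarray:
        return self.modality == modality


@dataclass
class DecodePrep:
    task: str
    participants: list[PreparedParticipant]
    excluded: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.participants)

    def to_dataset(self) -> PatternDataset:
        """Re-wrap as a raw dataset (e.g. to check prepare() idempotence)."""
        return PatternDataset(
            [
                ParticipantPatterns(
                    participant_id=p.participant_id,
                    data=p.data.copy(),
                    modality=p.modality.copy(),
                    rating=p.rating.copy(),
                    stimulus=p.stimulus.copy(),
                )
                for p in self.participants
            ]
        )


def _binarise(rating: np.ndarray) -> np.ndarray:
    if rating.min() < 1 or rating.max() > 4:
        raise InvalidParameterError("ratings must lie in 1..4")
    return np.where(rating <= 2, "low", "high")


def prepare_patterns(
    dataset: PatternDataset,
    task: str = "strength",
    rng: np.random.Generator | int = 0,
) -> DecodePrep:
    """Binarise, screen, balance and mean-centre a pattern dataset.

    ``task="strength"`` drops participants with fewer than 10 trials in
    either the low or the high class within either modality, then
    down-samples the majority class to equality within each modality.
    ``task="content"`` drops participants with fewer than 2 trials of any
    stimulus at any rating level within either modality and keeps all
    trials.  In both cases each modality's feature means are subtracted, so
    only relative (within-modality) pattern differences remain.
    """
    if task not in ("strength", "content"):
        raise InvalidParameterError(f"unknown task {task!r}")
    rng = np.random.default_rng(rng)
    prepared: list[PreparedParticipant] = []
    excluded: list[int] = []
    for part in dataset:
        level = _binarise(part.rating)
        keep = np.ones(len(level), dtype=bool)
        ok = True
        for mod in MODALITIES:
            m = part.modality == mod
            if task == "strength":
                counts = {
                    lv: int(np.sum(m & (level == lv))) for lv in ("low", "high")
                }
                if min(counts.values()) < MIN_TRIALS_PER_CLASS:
                    ok = False
                    break
                n_min = min(counts.values())
                for lv in ("low", "high"):
                    idx = np.flatnonzero(m & (level == lv))
                    if idx.size > n_min:
                        drop = rng.choice(
                            idx, size=idx.size - n_min, replace=False
                        )
                        keep[drop] = False
            else:
                for stim in range(1, N_STIMULI + 1):
                    for lv in ("low", "high"):
                        n = int(
                            np.sum(m & (level == lv) & (part.stimulus == stim))
                        )
                        if n < MIN_TRIALS_PER_STIMULUS_LEVEL:
                            ok = False
                if not ok:
                    break
        if not ok:
            excluded.append(part.participant_id)
            continue
        data = part.data[keep].astype(float)
        modality = part.modality[keep]
        # mean-centre within modality: removes overall amplitude differences
        for mod in MODALITIES:
            m = modality == mod
            if m.any():
                data[m] -= data[m].mean(axis=0, keepdims=True)
        prepared.append(
            PreparedParticipant(
                participant_id=part.participant_id,
                data=data,
                modality=modality,
                level=level[keep],
                rating=part.rating[keep],
                stimulus=part.stimulus[keep],
            )
        )
    if not prepared:
        raise EmptyCohortError(f"no participant eligible for {task} decoding")
    return DecodePrep(task=task, participants=prepared, excluded=excluded)


def _ledoit_wolf_cov(Xc: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrunk covariance of one class, on standardised features.

    Features are standardised before estimating the shrinkage intensity and
    the covariance rescaled afterwards, so the shrinkage target is the
    correlation-scale identity.  Shrinkage keeps the pooled scatter
    invertible when features outnumber trials.
    """
    n, p = Xc.shape
    mu_x = Xc.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xc - mu_x) / sd
    emp = Xs.T @ Xs / n
    mu = np.trace(emp) / p
    delta = float(((emp - mu * np.eye(p)) ** 2).sum()) / p
    X2 = Xs**2
    beta_ = float(np.sum(X2.T @ X2 / n - emp**2)) / (n * p)
    if beta_ == 0.0 or delta == 0.0:
        shrink = 0.0
    else:
        shrink = min(beta_, delta) / delta
    shrunk = (1.0 - shrink) * emp + shrink * mu * np.eye(p)
    return sd[:, None] * shrunk * sd[None, :]


def _direction_accuracy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> float:
    """Linear discriminant with automatic shrinkage; held-out accuracy.

    Equivalent to a least-squares LDA on a Ledoit-Wolf-regularised pooled
    within-class covariance (ties in the discriminant scores resolve to the
    first class in sorted label order - a measure-zero event).
    """
    classes = np.unique(y_train)
    n = len(y_train)
    means, priors = [], []
    cov = np.zeros((X_train.shape[1], X_train.shape[1]))
    for c in classes:
        Xc = X_train[y_train == c]
        means.append(Xc.mean(axis=0))
        priors.append(len(Xc) / n)
        cov += len(Xc) / n * _ledoit_wolf_cov(Xc)
    means = np.asarray(means)
    priors = np.asarray(priors)
    coef = np.linalg.solve(cov, means.T).T
    intercept = -0.5 * np.einsum("ij,ij->i", means, coef) + np.log(priors)
    scores = X_test @ coef.T + intercept
    predicted = classes[np.argmax(scores, axis=1)]
    return float(np.mean(predicted == y_test))


def _participant_strength_accuracy(
    p: PreparedParticipant, level: np.ndarray | None = None
) -> float:
    level = p.level if level is None else level
    accs = []
    for train_mod, test_mod in (MODALITIES, MODALITIES[::-1]):
        tr, te = p.mask(train_mod), p.mask(test_mod)
        accs.append(
            _direction_accuracy(p.data[tr], level[tr], p.data[te], level[te])
        )
    return float(np.mean(accs))


def cross_decode_strength(prep: DecodePrep) -> dict[int, float]:
    """Cross-modal low/high strength decoding accuracy per participant.

    Trains the discriminant on one modality's low-vs-high labels, tests on
    the other modality, and averages the two directions.
    """
    for p in prep.participants:
        for mod in MODALITIES:
            if not p.mask(mod).any():
                raise InvalidParameterError(
                    f"participant {p.participant_id}: modality {mod} missing"
                )
    return {
        p.participant_id: _participant_strength_accuracy(p)
        for p in prep.participants
    }


@dataclass
class DecodingResult:
    accuracies: dict[int, float]
    group_mean: float
    null_distribution: np.ndarray
    p_value: float
    effect_size: float  # Cohen's d of accuracies against chance (0.5)
    n_permutations: int
    n_bootstrap: int

    def summary(self) -> str:
        return (
            f"group mean accuracy {self.group_mean:.3f} over "
            f"{len(self.accuracies)} participants; one-sided p = "
            f"{self.p_value:.4f} ({self.n_permutations} permutations x "
            f"{self.n_bootstrap} bootstraps), d = {self.effect_size:.2f}"
        )


def permutation_group_test(
    prep: DecodePrep,
    n_perm_per_participant: int = 25,
    n_bootstrap: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> DecodingResult:
    """Group-level permutation/bootstrap test of cross-decoding accuracy.

    Class labels are permuted within each modality prior to decoding,
    ``n_perm_per_participant`` times per participant.  The group null is
    built by bootstrapping: each of ``n_bootstrap`` samples draws
    participants with replacement and, for each, one of their permuted
    accuracies, then takes the mean.  One-sided p-value with add-one
    smoothing: p = (1 + #{null >= observed}) / (1 + n_bootstrap).
    """
    if n_perm_per_participant < 1:
        raise InvalidParameterError("n_perm_per_participant must be >= 1")
    if len(prep) < 2:
        raise InvalidParameterError("need >= 2 participants")
    rng = np.random.default_rng(seed)
    observed = cross_decode_strength(prep)
    group_mean = float(np.mean(list(observed.values())))

    perm_acc = np.empty((len(prep), n_perm_per_participant))
    for i, p in enumerate(prep.participants):
        for j in range(n_perm_per_participant):
            shuffled = p.level.copy()
            for mod in MODALITIES:
                m = p.mask(mod)
                shuffled[m] = rng.permutation(shuffled[m])
            perm_acc[i, j] = _participant_strength_accuracy(p, level=shuffled)

    # group null: every participant enters each bootstrap sample once, with
    # one of their permuted accuracies drawn at random (with replacement)
    n_part = len(prep)
    perm_idx = rng.integers(0, n_perm_per_participant, size=(n_bootstrap, n_part))
    null = perm_acc[np.arange(n_part), perm_idx].mean(axis=1)

    p_value = float((1 + np.sum(null >= group_mean)) / (1 + n_bootstrap))
    accs = np.array(list(observed.values()))
    sd = accs.std(ddof=1)
    d = float((accs.mean() - 0.5) / sd) if sd > 0 else 0.0
    return DecodingResult(
        accuracies=observed,
        group_mean=group_mean,
        null_distribution=null,
        p_value=p_value,
        effect_size=d,
        n_permutations=n_perm_per_participant,
        n_bootstrap=n_bootstrap,
    )


def pairwise_content_crossdecode(
    prep: DecodePrep,
    train_modality: str = "imagery",
    train_level: str = "high",
) -> dict[int, float]:
    """Stimulus-identity decoding generalised across modalities.

    For each of the 6 unordered stimulus pairs: train on the trials of
    ``train_modality`` restricted to ``train_level`` (low or high rating),
    test on all trials of the other modality showing either stimulus of the
    pair; per-participant accuracy is the average over pairs.
    """
    if train_modality not in MODALITIES:
        raise InvalidParameterError(f"unknown modality {train_modality!r}")
    if train_level not in ("low", "high"):
        raise InvalidParameterError(f"unknown level {train_level!r}")
    test_modality = MODALITIES[1 - MODALITIES.index(train_modality)]
    out: dict[int, float] = {}
    for p in prep.participants:
        accs = []
        for s1, s2 in combinations(range(1, N_STIMULI + 1), 2):
            pair = np.isin(p.stimulus, (s1, s2))
            tr = (
                p.mask(train_modality)
                & (p.level == train_level)
                & pair
            )
            te = p.mask(test_modality) & pair
            if len(np.unique(p.stimulus[tr])) < 2 or not te.any():
                raise InvalidParameterError(
                    f"participant {p.participant_id}: missing stimulus class "
                    f"in pair ({s1},{s2})"
                )
            accs.append(
                _direction_accuracy(
                    p.data[tr], p.stimulus[tr], p.data[te], p.stimulus[te]
                )
            )
        out[p.participant_id] = float(np.mean(accs))
    return out


@dataclass
class SlopeTest:
    slopes: np.ndarray
    mean_slope: float
    t_statistic: float
    p_value: float
    df: int


def univariate_modulation(dataset: PatternDataset) -> dict[str, SlopeTest]:
    """Mean-activation slope on rating per modality, with a group test.

    For each participant and modality, the least-squares slope of the
    trialwise feature-mean (ROI-average analogue) on the 1-4 rating; group
    one-sample two-sided t-test of the slopes against 0.
    """
    slopes: dict[str, list[float]] = {mod: [] for mod in MODALITIES}
    for part in dataset:
        roi_mean = part.data.mean(axis=1)
        for mod in MODALITIES:
            m = part.modality == mod
            if len(np.unique(part.rating[m])) < 2:
                raise InvalidParameterError(
                    f"participant {part.participant_id}: constant ratings"
                )
            slope = np.polyfit(part.rating[m].astype(float), roi_mean[m], 1)[0]
            slopes[mod].append(float(slope))
    out = {}
    for mod, vals in slopes.items():
        arr = np.asarray(vals)
        t, p = stats.ttest_1samp(arr, 0.0)
        out[mod] = SlopeTest(
            slopes=arr,
            mean_slope=float(arr.mean()),
            t_statistic=float(t),
            p_value=float(p),
            df=len(arr) - 1,
        )
    return out
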