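"""Synthetic behavioural and neural datasets with the assumed structure.

The behavioural generator emulates the one-critical-trial online experiments:
each simulated subject performs 9 pre-critical imagery trials (vividness
rated 1-5), one critical trial on which a grating congruent or orthogonal to
the imagined one is embedded in noise (Experiment 1) or no grating at all
(Experiment 2), an immediate 3-way reality judgment (no / left / right) with
5-point confidence, and a 40-trial left/right discrimination block.  The
critical trial itself is generated by one of the generative accounts in
:mod:`realitymix.sdt_models`, so planted condition effects follow that
model's predictions exactly.

Across subjects, mean vividness ``V_S ~ N(2.5, 1)`` and discrimination
sensitivity are drawn jointly with a configurable negative correlation
(default -0.2).  Sensitivity is a two-component mixture: most subjects are
"engaged" with d' ~ N(2.1, 0.73) (the values observed among included online
participants), while a configurable fraction (default 25%) view under
conditions too poor to see the gratings (near-chance d'), so that after
binomial measurement noise roughly the study's ~18% of subjects fall below
the 55% discrimination-performance exclusion threshold.  Debrief flags (technical issue,
multiple participation, non-imaginer) drive the remaining exclusions.

The neural generator emits per-participant trial-by-feature activation
patterns in which a *shared strength axis* loads both imagery vividness and
perceptual visibility, a stimulus-content direction carries identity
information whose fidelity grows with the rating, and a modality-specific
offset separates imagery from perception overall (removed downstream by
mean-centring).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sdt_models import (
    ImagerySpec,
    InvalidParameterError,
    ModelSpec,
    _rate,
    combine_sources,
    stimulus_for_condition,
    V_S_MEAN,
    V_S_SD,
)

__all__ = [
    "BehaviouralDesign",
    "SubjectProfile",
    "BehaviouralDataset",
    "ParticipantPatterns",
    "PatternDataset",
    "NeuralDesign",
    "generate_experiment",
    "simulate_discrimination_block",
    "generate_neural",
    "write_dataset",
    "read_dataset",
    "SchemaError",
]


class SchemaError(ValueError):
    """A dataset file does not match the documented column schema."""


@dataclass(frozen=True)
class BehaviouralDesign:
    """Tunable design parameters of the behavioural generator.

    Defaults follow the study conditions: 9 pre-critical imagery trials plus
    one critical trial, 40 discrimination trials, d' ~ N(2.1, 0.73) among
    engaged subjects, vividness-sensitivity correlation -0.2, and debrief
    flag rates near the observed exclusion proportions (~1% technical, ~1%
    multiple participation, ~3% non-imaginers, and a 25% near-chance
    sensitivity group yielding ~18% measured below-55% performers).
    """

    n_pre_trials: int = 9
    n_disc_trials: int = 40
    vividness_noise_sd: float = 1.0
    dprime_mean: float = 2.1
    dprime_sd: float = 0.73
    low_sensitivity_rate: float = 0.25
    low_sensitivity_scale: float = 0.1
    vividness_dprime_corr: float = -0.2
    technical_rate: float = 0.01
    multi_participation_rate: float = 0.01
    non_imaginer_rate: float = 0.03
    confidence_slope: float = 2.0
    confidence_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "low_sensitivity_rate",
            "technical_rate",
            "multi_participation_rate",
            "non_imaginer_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.vividness_dprime_corr <= 1.0:
            raise InvalidParameterError("vividness_dprime_corr must be in [-1, 1]")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    condition: str
    experiment: int
    V_S: float
    true_dprime_disc: float
    multi_participation: bool
    non_imaginer: bool
    technical_issue: bool


SUBJECT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "experiment",
    "condition",
    "V_S",
    "true_dprime_disc",
    "technical_issue",
    "multi_participation",
    "non_imaginer",
    *(f"pre_rating_{i}" for i in range(1, 10)),
    "critical_rating",
    "critical_vividness_raw",
    "presented_class",
    "immediate_response",
    "confidence",
)

DISCRIMINATION_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "trial",
    "true_tilt",
    "response_tilt",
    "correct",
)


@dataclass
class BehaviouralDataset:
    """Subject-level table plus long-format discrimination trials."""

    subjects: pd.DataFrame
    discrimination: pd.DataFrame

    def __post_init__(self) -> None:
        _check_columns(self.subjects, SUBJECT_COLUMNS, "subjects")
        _check_columns(self.discrimination, DISCRIMINATION_COLUMNS, "discrimination")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subset(self, keep: pd.Series | np.ndarray) -> "BehaviouralDataset":
        """Dataset restricted to the subjects flagged True in ``keep``."""
        kept = self.subjects.loc[np.asarray(keep, dtype=bool)]
        ids = set(kept["subject_id"])
        disc = self.discrimination[self.discrimination["subject_id"].isin(ids)]
        return BehaviouralDataset(
            kept.reset_index(drop=True), disc.reset_index(drop=True)
        )


def _check_columns(df: pd.DataFrame, expected: Sequence[str], name: str) -> None:
    got = list(df.columns)
    missing = [c for c in expected if c not in got]
    unknown = [c for c in got if c not in expected]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing column(s): {missing}")
        if unknown:
            parts.append(f"unknown column(s): {unknown}")
        raise SchemaError(f"{name} table schema mismatch - " + "; ".join(parts))


def _sample_sensitivity(
    z_latent: np.ndarray, design: BehaviouralDesign
) -> np.ndarray:
    """Map latent normal scores to d' via the mixture quantile function.

    A Gaussian copula couples d' to the latent vividness score: the mixture
    CDF (low-sensitivity half-normal component plus truncated-normal engaged
    component) is inverted on a fine grid, so the target correlation holds
    over the full population and d' >= 0 by construction.
    """
    p_low = design.low_sensitivity_rate
    grid = np.linspace(0.0, design.dprime_mean + 8 * design.dprime_sd, 4001)
    lo_cdf = 2 * norm.cdf(grid / max(design.low_sensitivity_scale, 1e-12)) - 1
    trunc_at_0 = norm.cdf(-design.dprime_mean / design.dprime_sd)
    hi_cdf = (
        norm.cdf((grid - design.dprime_mean) / design.dprime_sd) - trunc_at_0
    ) / (1 - trunc_at_0)
    mix_cdf = p_low * lo_cdf + (1 - p_low) * np.clip(hi_cdf, 0.0, 1.0)
    u = norm.cdf(z_latent)
    return np.interp(u, mix_cdf, grid)


def simulate_discrimination_block(
    true_dprime_disc: float | np.ndarray,
    n_trials: int = 40,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Simulate balanced 2AFC left/right discrimination blocks.

    Equal-variance SDT identification: on a left-tilt trial the decision
    variable is N(+d'/2, 1), on a right-tilt trial N(-d'/2, 1), with an
    unbiased criterion at 0, so expected accuracy is Phi(d'/2).  The tilt
    sequence is balanced (n_trials/2 each) then shuffled per subject.
    Accepts a scalar d' (one block) or a vector (one block per subject);
    returns a long-format frame with one row per trial.
    """
    rng = np.random.default_rng(rng)
    d = np.atleast_1d(np.asarray(true_dprime_disc, dtype=float))
    if np.any(d < 0):
        raise InvalidParameterError("true_dprime_disc must be >= 0")
    n_subj = d.shape[0]
    half = n_trials // 2
    tilts = np.tile(
        np.array([1] * half + [-1] * (n_trials - half)), (n_subj, 1)
    )
    tilts = rng.permuted(tilts, axis=1)  # +1 = left, -1 = right
    dv = tilts * d[:, None] / 2.0 + rng.standard_normal((n_subj, n_trials))
    responses = np.where(dv > 0, 1, -1)
    tilt_lab = np.where(tilts == 1, "left", "right")
    resp_lab = np.where(responses == 1, "left", "right")
    return pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n_subj), n_trials),
            "trial": np.tile(np.arange(1, n_trials + 1), n_subj),
            "true_tilt": tilt_lab.ravel(),
            "response_tilt": resp_lab.ravel(),
            "correct": (tilts == responses).astype(int).ravel(),
        }
    )


def generate_experiment(
    model: ModelSpec,
    experiment: int,
    n_per_condition: int,
    design: BehaviouralDesign | None = None,
    seed: int | np.random.Generator = 0,
) -> BehaviouralDataset:
    """Generate a full synthetic one-critical-trial experiment.

    Experiment 1 assigns ``n_per_condition`` subjects to each of the
    congruent and incongruent conditions (stimulus present on the critical
    trial); Experiment 2 uses the same arms but never presents a stimulus.
    Pre-critical ratings are the subject's discretised ``V_S`` plus
    trial-to-trial noise; the critical trial (percept, reality judgment,
    vividness and confidence reports) is produced by the generative model.
    """
    if experiment not in (1, 2):
        raise InvalidParameterError("experiment must be 1 or 2")
    if n_per_condition < 1:
        raise InvalidParameterError("n_per_condition must be >= 1")
    design = design or BehaviouralDesign()
    rng = np.random.default_rng(seed)

    conditions = np.repeat(["congruent", "incongruent"], n_per_condition)
    n = conditions.shape[0]

    # latent bivariate normal couples V_S and sensitivity
    z1 = rng.standard_normal(n)
    r = design.vividness_dprime_corr
    z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
    v_s = V_S_MEAN + V_S_SD * z1
    dprime = _sample_sensitivity(z2, design)

    flags = {
        "technical_issue": rng.random(n) < design.technical_rate,
        "multi_participation": rng.random(n) < design.multi_participation_rate,
        "non_imaginer": rng.random(n) < design.non_imaginer_rate,
    }

    # 9 pre-critical vividness ratings: discretised V_S + per-trial noise
    pre_raw = v_s[:, None] + design.vividness_noise_sd * rng.standard_normal(
        (n, design.n_pre_trials)
    )
    pre_ratings = _rate(pre_raw)

    # critical trial under the generative account (vectorised per condition)
    presented = np.empty(n, dtype=object)
    response = np.empty(n, dtype=object)
    crit_raw = np.empty(n)
    p_max = np.empty(n)
    imagery_channel = ImagerySpec().channel  # imagery always left tilt
    for cond in ("congruent", "incongruent"):
        idx = np.flatnonzero(conditions == cond)
        stim_cond = cond if experiment == 1 else "absent"
        stimulus = stimulus_for_condition(stim_cond)
        mu_x = model.attention_gain * stimulus.mu_X
        X = mu_x + rng.standard_normal((idx.size, 2))
        V = rng.standard_normal((idx.size, 2))
        V[:, imagery_channel] += model.imagery_gain * v_s[idx]
        P, I = combine_sources(model, X, V)
        judged_real = np.max(P, axis=1) > model.T
        reported = np.where(
            judged_real, np.where(P[:, 0] >= P[:, 1], "left", "right"), "none"
        )
        presented[idx] = stimulus.stimulus_class
        response[idx] = reported
        crit_raw[idx] = I[:, imagery_channel]
        p_max[idx] = np.max(P, axis=1)
    crit_rating = _rate(crit_raw)

    confidence = _rate(
        1.0
        + design.confidence_slope * np.abs(p_max - model.T)
        + design.confidence_noise_sd * rng.standard_normal(n)
    )

    disc = simulate_discrimination_block(dprime, design.n_disc_trials, rng)

    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "experiment": experiment,
            "condition": conditions,
            "V_S": v_s,
            "true_dprime_disc": dprime,
            "technical_issue": flags["technical_issue"].astype(int),
            "multi_participation": flags["multi_participation"].astype(int),
            "non_imaginer": flags["non_imaginer"].astype(int),
            **{
                f"pre_rating_{i + 1}": pre_ratings[:, i]
                for i in range(design.n_pre_trials)
            },
            "critical_rating": crit_rating,
            "critical_vividness_raw": crit_raw,
            "presented_class": presented,
            "immediate_response": response,
            "confidence": confidence,
        }
    )
    return BehaviouralDataset(subjects, disc)


# ---------------------------------------------------------------------------
# neural pattern data


@dataclass(frozen=True)
class NeuralDesign:
    """Geometry and planted effects of the synthetic pattern generator.

    ``strength_loading`` scales the shared subjective-strength axis: the
    low/high class means sit at -/+ ``strength_loading`` along a unit vector
    common to imagery and perception, so the planted projected separation is
    ``2 * strength_loading / noise_sd`` noise SDs.  ``content_snr_by_rating``
    gives the length of the stimulus-content component at each rating level;
    the default doubles per step, making content fidelity grow with rated
    strength as the mixing account predicts.
    """

    n_features: int = 50
    n_trials_per_modality: int = 200
    strength_loading: float = 0.5
    content_snr_by_rating: tuple[float, float, float, float] = (0.1, 0.2, 0.4, 0.8)
    noise_sd: float = 1.0
    modality_offset_sd: float = 1.0
    #: uniform (all-features) activation increase per rating step; models an
    #: overall ROI-amplitude modulation by subjective strength (default off:
    #: strength is carried by pattern geometry, not overall amplitude)
    amplitude_slope: float = 0.0
    rating_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shared_strength_axis: bool = True
    shared_content_axes: bool = True

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise InvalidParameterError("n_features must be >= 2")
        if abs(sum(self.rating_probs) - 1.0) > 1e-9 or min(self.rating_probs) < 0:
            raise InvalidParameterError("rating_probs must be a distribution")


MODALITIES = ("imagery", "perception")
N_STIMULI = 4


@dataclass
class ParticipantPatterns:
    """Trial x feature activations plus trial metadata for one participant."""

    participant_id: int
    data: np.ndarray  # (n_trials, n_features)
    modality: np.ndarray  # str array
    rating: np.ndarray  # int 1-4
    stimulus: np.ndarray  # int 1-4

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if not (
            len(self.modality) == len(self.rating) == len(self.stimulus) == n
        ):
            raise SchemaError("metadata length must match trial count")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.data, columns=[f"f{j}" for j in range(self.data.shape[1])]
        )
        df.insert(0, "stimulus", self.stimulus)
        df.insert(0, "rating", self.rating)
        df.insert(0, "modality", self.modality)
        return df


@dataclass
class PatternDataset:
    participants: list[ParticipantPatterns]

    def __iter__(self):
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_neural(
    n_participants: int,
    design: NeuralDesign | None = None,
    seed: int | np.random.Generator = 0,
) -> PatternDataset:
    """Generate synthetic activation patterns for the decoding analyses.

    Each trial's pattern is::

        strength_axis * strength_loading * (rating - 2.5)
        + content_direction[stimulus] * content_snr[rating]
        + modality_offset + iid N(0, noise_sd) noise

    With ``shared_strength_axis=False`` imagery and perception get
    independent strength axes (cross-decoding then carries no signal);
    likewise ``shared_content_axes=False`` decouples the stimulus-content
    geometry across modalities.
    """
    design = design or NeuralDesign()
    rng = np.random.default_rng(seed)
    participants = []
    ratings_support = np.arange(1, 5)
    for pid in range(n_participants):
        axes = {}
        content = {}
        u_shared = _unit(rng.standard_normal(design.n_features))
        c_shared = rng.standard_normal((N_STIMULI, design.n_features))
        c_shared /= np.linalg.norm(c_shared, axis=1, keepdims=True)
        for mod in MODALITIES:
            axes[mod] = (
                u_shared
                if design.shared_strength_axis
                else _unit(rng.standard_normal(design.n_features))
            )
            if design.shared_content_axes:
                content[mod] = c_shared
            else:
                c = rng.standard_normal((N_STIMULI, design.n_features))
                content[mod] = c / np.linalg.norm(c, axis=1, keepdims=True)

        blocks, mods, rats, stims = [], [], [], []
        for mod in MODALITIES:
            nt = design.n_trials_per_modality
            rating = rng.choice(ratings_support, size=nt, p=design.rating_probs)
            if len(np.unique(rating)) == 1:
                import warnings

                warnings.warn(
                    f"participant {pid} {mod}: all ratings identical",
                    stacklevel=2,
                )
            stimulus = rng.integers(1, N_STIMULI + 1, size=nt)
            offset = design.modality_offset_sd * rng.standard_normal(
                design.n_features
            )
            snr = np.asarray(design.content_snr_by_rating)[rating - 1]
            patterns = (
                design.strength_loading
                * (rating - 2.5)[:, None]
                * axes[mod][None, :]
                + design.amplitude_slope * (rating - 2.5)[:, None]
                + snr[:, None] * content[mod][stimulus - 1]
                + offset[None, :]
                + design.noise_sd
                * rng.standard_normal((nt, design.n_features))
            )
            blocks.append(patterns)
            mods.append(np.full(nt, mod))
            rats.append(rating)
            stims.append(stimulus)
        participants.append(
            ParticipantPatterns(
                participant_id=pid,
                data=np.vstack(blocks),
                modality=np.concatenate(mods),
                rating=np.concatenate(rats).astype(int),
                stimulus=np.concatenate(stims).astype(int),
            )
        )
    return PatternDataset(participants)


# ---------------------------------------------------------------------------
# on-disk round trip


def write_dataset(
    dataset: BehaviouralDataset | PatternDataset, outdir: str | Path
) -> list[Path]:
    """Write a dataset to its documented CSV schema; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(dataset, BehaviouralDataset):
        for name, df in (
            ("subjects.csv", dataset.subjects),
            ("discrimination.csv", dataset.discrimination),
        ):
            path = outdir / name
            df.to_csv(path, index=False)
            written.append(path)
    elif isinstance(dataset, PatternDataset):
        for part in dataset:
            path = outdir / f"neural_{part.participant_id:03d}.csv"
            part.to_frame().to_csv(path, index=False)
            written.append(path)
    else:
        raise TypeError(f"cannot write {type(dataset).__name__}")
    return written


def read_dataset(
    indir: str | Path, kind: str = "behavioural"
) -> BehaviouralDataset | PatternDataset:
    """Read a dataset written by :func:`write_dataset`, enforcing the schema."""
    indir = Path(indir)
    if kind == "behavioural":
        # exact float round-trip so that write(read(x)) is byte-identical
        subjects = pd.read_csv(indir / "subjects.csv", float_precision="round_trip")
        disc = pd.read_csv(indir / "discrimination.csv")
        if subjects.empty:
            subjects = subjects.astype(
                {c: object for c in subjects.columns}
            )
        return BehaviouralDataset(subjects, disc)
    if kind == "neural":
        participants = []
        for path in sorted(indir.glob("neural_*.csv")):
            df = pd.read_csv(path)
            meta = ("modality", "rating", "stimulus")
            missing = [c for c in meta if c not in df.columns]
            if missing:
                raise SchemaError(f"{path.name}: missing column(s): {missing}")
            feats = [c for c in df.columns if c not in meta]
            bad = [c for c in feats if not c.startswith("f")]
            if bad:
                raise SchemaError(f"{path.name}: unknown column(s): {bad}")
            participants.append(
                ParticipantPatterns(
                    participant_id=int(path.stem.split("_")[1]),
                    data=df[feats].to_numpy(dtype=float),
                    modality=df["modality"].to_numpy(),
                    rating=df["rating"].to_numpy(dtype=int),
                    stimulus=df["stimulus"].to_numpy(dtype=int),
                )
            )
        return PatternDataset(participants)
    raise ValueError(f"unknown dataset kind {kind!r}")
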