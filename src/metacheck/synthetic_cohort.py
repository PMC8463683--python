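"""Seeded synthetic cohorts of metacognitive observers.

Two generation modes are provided:

* **mechanistic mode** -- a signal-detection observer with a coherence-dependent
  evidence distribution and a noisy second-order (confidence) readout.  Used to
  exercise the psychometric and metacognition estimators end to end.
* **GLMM mode** -- trial tables whose generative truth is exactly the Poisson
  checking model (subject intercept + observation-level random effect) and the
  logistic accuracy model, for coefficient-recovery studies.

Difficulty coding convention: ``difficulty`` is the *negative* z-scored
coherence within the relevant design, so that "higher = harder" and the
difficulty slope of the checking model is positive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

TASKS = ("calibration", "checking", "implicit", "explicit")

TRAITS = ("m_ratio", "cmi", "padua", "mistrust")

#: Columns of the cohort CSV schema, in canonical order.
COHORT_COLUMNS = [
    "subject_id",
    "task",
    "coherence",
    "difficulty",
    "direction",
    "response",
    "correct",
    "n_checks",
    "confidence",
    "pair_id",
    "chosen",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """Generative traits of one simulated observer."""

    subject_id: str
    sensitivity_k: float
    meta_noise_sigma: float
    confidence_thresholds: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)
    random_intercept_m1: float = 0.0
    padua_score: int = 0
    mistrust_score: int = 0
    trait_mratio: float = 0.0
    trait_cmi: float = 0.0

    def __post_init__(self) -> None:
        if not self.sensitivity_k > 0:
            raise ValueError("sensitivity_k must be > 0")
        if self.meta_noise_sigma < 0:
            raise ValueError("meta_noise_sigma must be >= 0")
        thr = np.asarray(self.confidence_thresholds, dtype=float)
        if thr.size != 5 or np.any(np.diff(thr) <= 0):
            raise ValueError("confidence_thresholds must be 5 strictly increasing cutpoints")
        if not 0 <= self.padua_score <= 240:
            raise ValueError("padua_score outside instrument range [0, 240]")


@dataclass
class TrialRecord:
    """One behavioral trial."""

    subject_id: str
    task: str
    coherence: float
    difficulty: float
    direction: int
    response: int
    correct: int
    n_checks: int | None = None
    confidence: int | None = None
    pair_id: int | None = None
    chosen: bool | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task kind {self.task!r}; expected one of {TASKS}")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        if self.correct != int(self.response == self.direction):
            raise ValueError("correct flag inconsistent with response/direction")
        if self.n_checks is not None and self.n_checks < 0:
            raise ValueError("n_checks must be nonnegative")
        if self.confidence is not None and self.confidence not in range(1, 7):
            raise ValueError("confidence must be an integer in 1..6")


@dataclass(frozen=True)
class Instrument:
    """Truncated-Gaussian questionnaire generator settings."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("instrument SD must be >= 0")
        if self.lower >= self.upper:
            raise ValueError("instrument range must satisfy lower < upper")


#: Padua Inventory total (60 items, 0-4 Likert) and MCQ cognitive-mistrust
#: subscale, configured to the published sample moments.
DEFAULT_INSTRUMENTS: dict[str, Instrument] = {
    "padua": Instrument(mean=57.6, sd=28.8, lower=0.0, upper=240.0),
    "mistrust": Instrument(mean=20.5, sd=6.3, lower=10.0, upper=40.0),
}


@dataclass(frozen=True)
class CheckingPolicy:
    """Log-linear Poisson policy for per-trial check counts.

    eta = intercept + difficulty * z + sum_k trait_main[k] * t_k
          + sum_k trait_by_difficulty[k] * t_k * z + u_subject + e_olre
    """

    intercept: float = -1.0
    difficulty: float = 0.90
    trait_main: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRAITS}
    )
    trait_by_difficulty: dict[str, float] = field(
        default_factory=lambda: {"m_ratio": 0.08, "cmi": -0.05, "padua": 0.10, "mistrust": -0.09}
    )
    subject_sd: float = 0.30
    olre_sd: float = 0.20

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.olre_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")


@dataclass(frozen=True)
class AccuracyModel:
    """Logistic model of trial accuracy given difficulty and checking."""

    intercept: float = 0.90
    difficulty: float = -0.90
    checks: float = -0.26
    checks_by_difficulty: float = 0.20
    trait_main: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRAITS}
    )
    trait_by_checks: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRAITS}
    )
    subject_sd: float = 0.40

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("random-effect SD must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration for a synthetic cohort."""

    n_subjects: int = 28
    n_trials_calibration: int = 120
    n_trials_checking: int = 218
    n_pairs_implicit: int = 123
    n_trials_explicit: int = 113
    checking_policy: CheckingPolicy = field(default_factory=CheckingPolicy)
    accuracy_model: AccuracyModel = field(default_factory=AccuracyModel)
    instruments: dict[str, Instrument] = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENTS)
    )
    trait_correlation: float = 0.0  # correlation planted between m_ratio and cmi traits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not -1.0 <= self.trait_correlation <= 1.0:
            raise ValueError("trait_correlation must lie in [-1, 1]")

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(o)

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


# ---------------------------------------------------------------------------
# mechanistic SDT observer
# ---------------------------------------------------------------------------


def _draw_direction(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2)) * 2 - 1


def simulate_observer_trial(
    profile: SubjectProfile,
    coherence: float,
    task: str,
    rng: np.random.Generator,
    difficulty: float = np.nan,
    direction: int | None = None,
) -> TrialRecord:
    """Simulate one 2AFC trial of a signal-detection observer.

    Sensory evidence is drawn from a unit-variance Gaussian centered at
    ``direction * sensitivity_k * coherence``; the response is the evidence
    sign.  For the explicit task, confidence evidence ``|evidence| +
    N(0, meta_noise_sigma)`` is mapped through the subject's thresholds to a
    1-6 rating.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError(f"coherence must lie in [0, 1], got {coherence}")
    if task not in TASKS:
        raise ValueError(f"unknown task kind {task!r}; expected one of {TASKS}")
    if direction is None:
        direction = _draw_direction(rng)
    evidence = rng.normal(direction * profile.sensitivity_k * coherence, 1.0)
    response = 1 if evidence >= 0 else -1
    confidence = None
    if task == "explicit":
        conf_evidence = abs(evidence) + rng.normal(0.0, profile.meta_noise_sigma)
        confidence = 1 + int(np.searchsorted(profile.confidence_thresholds, conf_evidence))
    return TrialRecord(
        subject_id=profile.subject_id,
        task=task,
        coherence=float(coherence),
        difficulty=float(difficulty),
        direction=direction,
        response=response,
        correct=int(response == direction),
        confidence=confidence,
    )


def simulate_implicit_pair(
    profile: SubjectProfile,
    coherence_a: float,
    coherence_b: float,
    rng: np.random.Generator,
    pair_id: int = 0,
    choice_noise: float = 0.0,
) -> tuple[TrialRecord, TrialRecord]:
    """Simulate a confidence forced-choice pair.

    The chosen trial is the one with the larger confidence evidence; with
    ``choice_noise > 0`` the comparison passes through a logistic choice rule,
    and ``choice_noise = inf`` yields a uniformly random chooser.  Exactly one
    trial of the pair is flagged chosen.
    """
    trials: list[TrialRecord] = []
    conf_ev: list[float] = []
    for coherence in (coherence_a, coherence_b):
        if not 0.0 <= coherence <= 1.0:
            raise ValueError(f"coherence must lie in [0, 1], got {coherence}")
        direction = _draw_direction(rng)
        evidence = rng.normal(direction * profile.sensitivity_k * coherence, 1.0)
        response = 1 if evidence >= 0 else -1
        # second-order readout shared with the explicit task
        conf_ev.append(abs(evidence) + rng.normal(0.0, profile.meta_noise_sigma))
        trials.append(
            TrialRecord(
                subject_id=profile.subject_id,
                task="implicit",
                coherence=float(coherence),
                difficulty=np.nan,
                direction=direction,
                response=response,
                correct=int(response == direction),
            )
        )
    delta = conf_ev[0] - conf_ev[1]
    if choice_noise == 0.0:
        choose_first = delta >= 0
    elif np.isinf(choice_noise):
        choose_first = rng.random() < 0.5
    else:
        p_first = 1.0 / (1.0 + np.exp(-delta / choice_noise))
        choose_first = rng.random() < p_first
    trials[0].pair_id = trials[1].pair_id = pair_id
    trials[0].chosen = bool(choose_first)
    trials[1].chosen = bool(not choose_first)
    return trials[0], trials[1]


# ---------------------------------------------------------------------------
# GLMM-mode generators
# ---------------------------------------------------------------------------


def _trait_matrix(df: pd.DataFrame) -> dict[str, np.ndarray]:
    missing = [t for t in TRAITS if t not in df.columns]
    if missing:
        raise ValueError(f"design table missing trait columns: {missing}")
    return {t: df[t].to_numpy(dtype=float) for t in TRAITS}


def simulate_checking_counts(
    policy: CheckingPolicy,
    design: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-trial check counts from the log-linear Poisson policy.

    ``design`` needs columns ``subject_id``, ``difficulty`` and the four trait
    columns (standardized).  Subject intercepts and the observation-level
    random effect (OLRE, Gaussian on the log scale) are drawn here.
    """
    out = design.copy()
    z = out["difficulty"].to_numpy(dtype=float)
    traits = _trait_matrix(out)
    eta = policy.intercept + policy.difficulty * z
    for name, t in traits.items():
        eta = eta + policy.trait_main.get(name, 0.0) * t
        eta = eta + policy.trait_by_difficulty.get(name, 0.0) * t * z
    subjects, subj_idx = np.unique(out["subject_id"].to_numpy(), return_inverse=True)
    u = rng.normal(0.0, policy.subject_sd, size=subjects.size)
    e = rng.normal(0.0, policy.olre_sd, size=len(out))
    eta = eta + u[subj_idx] + e
    if not np.all(np.isfinite(eta)):
        bad = np.flatnonzero(~np.isfinite(eta))[:5]
        raise ValueError(
            "non-finite Poisson linear predictor at rows "
            f"{bad.tolist()} (check policy coefficients "
            f"intercept={policy.intercept}, difficulty={policy.difficulty})"
        )
    out["n_checks"] = rng.poisson(np.exp(eta))
    return out


def simulate_accuracy(
    model: AccuracyModel,
    trials: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw trial accuracy from the logistic model given generated check counts.

    The checks covariate enters standardized (z-scored over the input table),
    matching how the fitting pipeline standardizes predictors.
    """
    if "n_checks" not in trials.columns or trials["n_checks"].isna().any():
        raise ValueError("simulate_accuracy requires generated n_checks on every row")
    out = trials.copy()
    z = out["difficulty"].to_numpy(dtype=float)
    checks = out["n_checks"].to_numpy(dtype=float)
    sd = checks.std(ddof=0)
    checks_z = (checks - checks.mean()) / sd if sd > 0 else np.zeros_like(checks)
    traits = _trait_matrix(out)
    eta = (
        model.intercept
        + model.difficulty * z
        + model.checks * checks_z
        + model.checks_by_difficulty * checks_z * z
    )
    for name, t in traits.items():
        eta = eta + model.trait_main.get(name, 0.0) * t
        eta = eta + model.trait_by_checks.get(name, 0.0) * t * checks_z
    subjects, subj_idx = np.unique(out["subject_id"].to_numpy(), return_inverse=True)
    u = rng.normal(0.0, model.subject_sd, size=subjects.size)
    eta = eta + u[subj_idx]
    p = 1.0 / (1.0 + np.exp(-eta))
    direction = rng.integers(0, 2, size=len(out)) * 2 - 1
    correct = (rng.random(len(out)) < p).astype(int)
    out["direction"] = direction
    out["response"] = np.where(correct == 1, direction, -direction)
    out["correct"] = correct
    return out


def _match_truncnorm(inst: Instrument) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncated moments equal the instrument's."""
    if inst.sd == 0:
        return inst.mean, 0.0

    def moments(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (inst.lower - mu) / sigma, (inst.upper - mu) / sigma
        with np.errstate(invalid="ignore", over="ignore"):
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
            sd = np.sqrt(v)
        if not (np.isfinite(m) and np.isfinite(sd)):
            return [1e6, 1e6]
        return [m - inst.mean, sd - inst.sd]

    sol = optimize.root(moments, x0=[inst.mean, np.log(inst.sd)], method="hybr")
    resid = moments(sol.x)
    if not sol.success or abs(resid[0]) > 1e-6 * max(1, abs(inst.mean)) or abs(
        resid[1]
    ) > 1e-6 * max(1, inst.sd):
        # infeasible targets (e.g. SD larger than the range supports):
        # fall back to the nominal parameters
        import warnings

        warnings.warn(
            f"could not moment-match truncated normal for {inst}; "
            "sampling with nominal (mean, sd)"
        )
        return inst.mean, inst.sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def sample_questionnaires(
    instruments: dict[str, Instrument],
    n_subjects: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw integer questionnaire scores from calibrated truncated Gaussians.

    The underlying Gaussian is moment-matched so the *truncated* distribution
    reproduces the configured mean/SD; draws are clipped to the instrument
    range and rounded to integers.
    """
    cols: dict[str, np.ndarray] = {}
    for name, inst in instruments.items():
        if inst.sd == 0:
            x = np.full(n_subjects, inst.mean)
        else:
            mu, sigma = _match_truncnorm(inst)
            a, b = (inst.lower - mu) / sigma, (inst.upper - mu) / sigma
            x = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n_subjects, random_state=rng)
        cols[name] = np.clip(np.rint(x), inst.lower, inst.upper).astype(int)
    return pd.DataFrame(cols)


def make_glmm_cohort(
    config: CohortConfig,
    n_trials: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cohort whose generative truth is exactly the checking/accuracy GLMMs.

    Difficulty is drawn N(0, 1) per trial; the four trait covariates are drawn
    standardized per subject, with ``trait_correlation`` planted between the
    ``m_ratio`` and ``cmi`` traits.  Returns one row per checking-task trial.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_trials = config.n_trials_checking if n_trials is None else n_trials
    n = config.n_subjects
    rho = config.trait_correlation
    cov = np.eye(4)
    cov[0, 1] = cov[1, 0] = rho
    traits = rng.multivariate_normal(np.zeros(4), cov, size=n)
    subjects = pd.DataFrame(traits, columns=list(TRAITS))
    subjects.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
    rows = subjects.loc[subjects.index.repeat(n_trials)].reset_index(drop=True)
    rows["task"] = "checking"
    rows["difficulty"] = rng.normal(0.0, 1.0, size=len(rows))
    rows["coherence"] = np.nan
    rows = simulate_checking_counts(config.checking_policy, rows, rng)
    rows = simulate_accuracy(config.accuracy_model, rows, rng)
    return rows


def make_subject_profiles(
    config: CohortConfig, rng: np.random.Generator
) -> list[SubjectProfile]:
    """Draw mechanistic observer profiles for a cohort.

    ``meta_noise_sigma`` decreases with the latent M-ratio trait so that trait
    and estimated explicit sensitivity are positively coupled.
    """
    n = config.n_subjects
    rho = config.trait_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    tm, tc = rng.multivariate_normal([0.0, 0.0], cov, size=n).T
    scores = sample_questionnaires(config.instruments, n, rng)
    profiles = []
    for i in range(n):
        k = float(np.exp(rng.normal(np.log(3.0), 0.35)))
        sigma = float(np.exp(-0.9 - 0.5 * tm[i] + rng.normal(0.0, 0.15)))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                sensitivity_k=k,
                meta_noise_sigma=sigma,
                random_intercept_m1=float(
                    rng.normal(0.0, config.checking_policy.subject_sd)
                ),
                padua_score=int(scores["padua"].iloc[i]) if "padua" in scores else 0,
                mistrust_score=int(scores["mistrust"].iloc[i]) if "mistrust" in scores else 0,
                trait_mratio=float(tm[i]),
                trait_cmi=float(tc[i]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(t) for t in trials])
    return df.reindex(columns=COHORT_COLUMNS)


def write_cohort(df: pd.DataFrame, config: CohortConfig, path: str | Path) -> None:
    """Write the cohort CSV plus a JSON sidecar echoing the full config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)
    path.with_suffix(".config.json").write_text(config.to_json())


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
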