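"""End-to-end orchestration: simulate -> calibrate -> estimate -> fit -> report.

Every stage is seeded from a single root seed via ``numpy.random.SeedSequence``
spawning, so a fixed :class:`RunConfig` regenerates byte-identical artifacts.
A JSON-lines run log records one entry per stage with the config hash and the
seed in use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metacognition, psychometrics, synthetic_cohort
from .inference import (
    ModelSpec,
    TestResult,
    fit_glmm,
    lrt_equal_coefficients,
    pearson_correlation_test,
    wald_table,
    wilcoxon_signed_rank,
)
from .synthetic_cohort import CohortConfig

__all__ = [
    "RunConfig",
    "ReportTable",
    "PipelineError",
    "M1_SPEC",
    "M2_SPEC",
    "run_pipeline",
    "tercile_descriptives",
    "correlate_measures",
    "load_osf_export",
]

#: Poisson model of per-trial check counts: difficulty, trait main effects,
#: trait-by-difficulty interactions, subject intercept + OLRE.
M1_SPEC = ModelSpec(
    outcome="n_checks",
    fixed=("difficulty", "m_ratio", "cmi", "padua", "mistrust"),
    interactions=(
        ("m_ratio", "difficulty"),
        ("cmi", "difficulty"),
        ("padua", "difficulty"),
        ("mistrust", "difficulty"),
    ),
    family="poisson-log",
    olre=True,
)

#: Logistic model of trial accuracy: difficulty, checks, checks-by-difficulty,
#: trait main effects and trait-by-checks interactions, subject intercept.
M2_SPEC = ModelSpec(
    outcome="correct",
    fixed=("difficulty", "n_checks", "m_ratio", "cmi", "padua", "mistrust"),
    interactions=(
        ("n_checks", "difficulty"),
        ("m_ratio", "n_checks"),
        ("cmi", "n_checks"),
        ("padua", "n_checks"),
        ("mistrust", "n_checks"),
    ),
    family="binomial-logit",
    olre=False,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(n_subjects=37))
    seed: int = 0
    out_dir: str = "metacheck_out"
    exclusion_rule: str = "se"
    m1_spec: ModelSpec = M1_SPEC
    m2_spec: ModelSpec = M2_SPEC
    write_outputs: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class ReportTable:
    subjects: pd.DataFrame
    trials: pd.DataFrame
    m1_table: pd.DataFrame
    m2_table: pd.DataFrame
    group_tests: list[TestResult]
    terciles: dict[str, pd.DataFrame]
    discarded: pd.DataFrame
    m1_vif: pd.Series
    log: list[dict]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def tercile_descriptives(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Within-subject difficulty terciles, averaged across subjects.

    Returns mean checks per tercile and mean accuracy per tercile by
    checks-count bin {0, 1, >=2}, each with across-subject SEM.  Subjects with
    fewer than three distinct difficulty values are skipped with a warning.
    """
    check_rows, acc_rows = [], []
    for sid, sub in trials.groupby("subject_id"):
        if sub["difficulty"].nunique() < 3:
            warnings.warn(f"subject {sid}: fewer than 3 distinct difficulties; skipped")
            continue
        terc = pd.qcut(sub["difficulty"].rank(method="first"), 3, labels=[0, 1, 2])
        sub = sub.assign(tercile=terc.astype(int))
        check_rows.append(sub.groupby("tercile")["n_checks"].mean().rename(sid))
        bins = np.where(sub["n_checks"] >= 2, 2, sub["n_checks"]).astype(int)
        acc = sub.assign(checks_bin=bins).groupby(["tercile", "checks_bin"])["correct"].mean()
        acc_rows.append(acc.rename(sid))
    if not check_rows:
        raise ValueError("no subject had enough distinct difficulty levels")
    checks = pd.concat(check_rows, axis=1)
    acc = pd.concat(acc_rows, axis=1)
    sem = lambda df: df.std(axis=1, ddof=1) / np.sqrt(df.notna().sum(axis=1))  # noqa: E731
    return {
        "checks_by_tercile": pd.DataFrame(
            {"mean": checks.mean(axis=1), "sem": sem(checks), "n_subjects": checks.notna().sum(axis=1)}
        ),
        "accuracy_by_tercile_checks": pd.DataFrame(
            {"mean": acc.mean(axis=1), "sem": sem(acc), "n_subjects": acc.notna().sum(axis=1)}
        ),
    }


def correlate_measures(
    subjects: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[TestResult]:
    """Pearson correlation tests between per-subject measure columns."""
    results = []
    for a, b in pairs:
        for c in (a, b):
            if c not in subjects.columns:
                raise KeyError(f"missing measure column {c!r}")
        sub = subjects[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete subjects for ({a}, {b})")
        res = pearson_correlation_test(sub[a].to_numpy(), sub[b].to_numpy())
        res.name = f"pearson[{a},{b}]"
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _calibrate_subjects(profiles, n_trials, seeds):
    fits = {}
    for profile, seed in zip(profiles, seeds):
        rng = np.random.default_rng(seed)

        def respond(coherence, _p=profile, _r=rng):
            t = synthetic_cohort.simulate_observer_trial(_p, coherence, "calibration", _r)
            return t.correct

        _, fit = psychometrics.adaptive_calibration(respond, n_trials=n_trials)
        fits[profile.subject_id] = fit
    return fits


def _simulate_tasks(config: RunConfig, profiles, fits, rng):
    """Checking, implicit, and explicit task tables for the kept subjects."""
    cc = config.cohort
    padua = _zscore(np.array([p.padua_score for p in profiles], dtype=float))
    mistrust = _zscore(np.array([p.mistrust_score for p in profiles], dtype=float))

    checking_frames, implicit_frames, explicit = [], [], []
    for i, profile in enumerate(profiles):
        coherences = psychometrics.select_test_coherences(fits[profile.subject_id])
        draw = rng.choice(coherences, size=cc.n_trials_checking)
        frame = pd.DataFrame(
            {
                "subject_id": profile.subject_id,
                "task": "checking",
                "coherence": draw,
                "difficulty": -_zscore(draw),
                "m_ratio": profile.trait_mratio,
                "cmi": profile.trait_cmi,
                "padua": padua[i],
                "mistrust": mistrust[i],
            }
        )
        checking_frames.append(frame)

        pair_trials = []
        for j in range(cc.n_pairs_implicit):
            ca, cb = rng.choice(coherences, size=2)
            a, b = synthetic_cohort.simulate_implicit_pair(
                profile, float(ca), float(cb), rng, pair_id=j
            )
            pair_trials.extend([a, b])
        implicit_frames.append(synthetic_cohort.trials_to_frame(pair_trials))

        exp_trials = [
            synthetic_cohort.simulate_observer_trial(
                profile, float(rng.choice(coherences)), "explicit", rng
            )
            for _ in range(cc.n_trials_explicit)
        ]
        explicit.append(synthetic_cohort.trials_to_frame(exp_trials))

    checking = pd.concat(checking_frames, ignore_index=True)
    checking = synthetic_cohort.simulate_checking_counts(cc.checking_policy, checking, rng)
    checking = synthetic_cohort.simulate_accuracy(cc.accuracy_model, checking, rng)
    return checking, pd.concat(implicit_frames, ignore_index=True), pd.concat(explicit, ignore_index=True)


def _estimate_measures(profiles, implicit, explicit):
    rows = []
    for profile in profiles:
        sid = profile.subject_id
        table = metacognition.build_rating_table(explicit[explicit["subject_id"] == sid])
        explicit_est = metacognition.fit_meta_d(table)
        implicit_est = metacognition.compute_cmi(implicit[implicit["subject_id"] == sid])
        rows.append(
            {
                "subject_id": sid,
                "d_prime": explicit_est.d_prime,
                "meta_d": explicit_est.meta_d,
                "m_ratio": explicit_est.m_ratio,
                "cmi": implicit_est.cmi,
                "padua": profile.padua_score,
                "mistrust": profile.mistrust_score,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportTable:
    """Run the full analysis on a freshly simulated mechanistic cohort."""
    log: list[dict] = []
    chash = config.config_hash()
    out = Path(config.out_dir)

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise PipelineError(name, exc) from exc
        log.append(
            {"stage": name, "config": chash, "seed": config.seed,
             "elapsed_s": round(time.perf_counter() - t0, 3)}
        )
        return result

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)
    profile_rng = np.random.default_rng(seeds[0])
    task_rng = np.random.default_rng(seeds[2])

    profiles = stage(
        "profiles", synthetic_cohort.make_subject_profiles, config.cohort, profile_rng
    )
    calib_fits = stage(
        "calibration",
        _calibrate_subjects,
        profiles,
        config.cohort.n_trials_calibration,
        seeds[1].spawn(len(profiles)),
    )
    kept_ids, discarded = stage(
        "exclusion",
        psychometrics.reject_outlier_subjects,
        {sid: f for sid, f in calib_fits.items()},
        config.exclusion_rule,
    )
    kept = [p for p in profiles if p.subject_id in set(kept_ids)]

    checking, implicit, explicit = stage(
        "tasks", _simulate_tasks, config, kept, calib_fits, task_rng
    )
    subjects = stage("metacognition", _estimate_measures, kept, implicit, explicit)
    subjects["slope"] = [calib_fits[s].slope for s in subjects["subject_id"]]
    subjects["inflexion"] = [calib_fits[s].inflexion for s in subjects["subject_id"]]

    # model covariates are the *estimated* per-subject measures, standardized
    trials = checking.drop(columns=["m_ratio", "cmi", "padua", "mistrust"]).merge(
        subjects[["subject_id", "m_ratio", "cmi", "padua", "mistrust"]], on="subject_id"
    )
    m1 = stage("m1", fit_glmm, config.m1_spec, trials)
    m2 = stage("m2", fit_glmm, config.m2_spec, trials)
    m1_table, m2_table = wald_table(m1), wald_table(m2)

    def group_tests():
        tests = []
        t = wilcoxon_signed_rank(subjects["m_ratio"].dropna().to_numpy(), method="normal-cc")
        t.name = "wilcoxon[m_ratio>0]"
        tests.append(t)
        t = wilcoxon_signed_rank(subjects["cmi"].dropna().to_numpy(), method="normal-cc")
        t.name = "wilcoxon[cmi>0]"
        tests.append(t)
        tests.extend(
            correlate_measures(subjects, [("m_ratio", "cmi"), ("padua", "mistrust")])
        )
        tests.append(
            lrt_equal_coefficients(
                config.m1_spec, trials, "m_ratio:difficulty", "cmi:difficulty"
            )
        )
        return tests

    tests = stage("group_tests", group_tests)
    terciles = stage("terciles", tercile_descriptives, trials)

    report = ReportTable(
        subjects=subjects,
        trials=trials,
        m1_table=m1_table,
        m2_table=m2_table,
        group_tests=tests,
        terciles=terciles,
        discarded=discarded,
        m1_vif=m1.vif,
        log=log,
    )
    if config.write_outputs:
        stage("write", _write_outputs, config, report, out)
    return report


def _write_outputs(config: RunConfig, report: ReportTable, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    synthetic_cohort.write_cohort(report.trials, config.cohort, out / "cohort.csv")
    report.subjects.to_csv(out / "subjects.csv", index=False)
    report.m1_table.to_csv(out / "m1_coefficients.csv", index=False)
    report.m2_table.to_csv(out / "m2_coefficients.csv", index=False)
    report.discarded.to_csv(out / "excluded_subjects.csv", index=False)
    pd.DataFrame([dataclasses.asdict(t) for t in report.group_tests]).to_csv(
        out / "group_tests.csv", index=False
    )
    for name, df in report.terciles.items():
        df.to_csv(out / f"{name}.csv")
    with open(out / "run_log.jsonl", "w") as fh:
        for rec in report.log:
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# external-data adapter (stub)
# ---------------------------------------------------------------------------

OSF_EXPECTED_SCHEMA = {
    "trials": [
        "subject_id", "task", "coherence", "direction", "response",
        "confidence", "n_checks", "pair_id", "chosen",
    ],
    "subjects": ["subject_id", "padua", "mistrust"],
}


def load_osf_export(path: str) -> None:
    """Adapter stub for the deposited behavioral dataset.

    The deposit's file layout is not documented in machine-readable form;
    this function records the trial/subject schema the pipeline expects (see
    ``OSF_EXPECTED_SCHEMA``) and raises until a concrete mapping is written.
    """
    raise NotImplementedError(
        "No adapter for the external deposit is implemented; provide CSVs with "
        f"columns {OSF_EXPECTED_SCHEMA} and use the regular entry points."
    )
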