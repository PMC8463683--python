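"""Psychometric curve fitting, adaptive calibration, and subject exclusion.

2AFC accuracy curves are parameterized as

    P(correct | c) = F(slope * (c - inflexion))

with F the logistic or standard-normal CDF; ``inflexion`` is the coherence at
the curve's steepest point (accuracy 0.5).  A probit observer with accuracy
Phi(k * c) is recovered exactly as (slope, inflexion) = (k, 0).  Lapse rates
are not modelled.  ``predict(..., folded=True)`` reports accuracy folded at
chance (clipped to [0.5, 1]), the scale on which a 2AFC observer performs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, ndtr, ndtri

__all__ = [
    "PsychometricFit",
    "CalibrationState",
    "fit_psychometric",
    "adaptive_calibration",
    "select_test_coherences",
    "reject_outlier_subjects",
]

_LINKS = {
    "logit": (expit, logit),
    "probit": (ndtr, ndtri),
}

_SLOPE_DIVERGED = 1e3


@dataclass
class PsychometricFit:
    link: str
    slope: float
    inflexion: float
    covariance: np.ndarray
    n_trials: int
    loglik: float
    converged: bool = True
    diverged: bool = False
    message: str = ""

    def predict(self, coherence, folded: bool = False) -> np.ndarray:
        f = _LINKS[self.link][0]
        p = f(self.slope * (np.asarray(coherence, dtype=float) - self.inflexion))
        return np.maximum(p, 0.5) if folded else p

    def inverse(self, accuracy) -> np.ndarray:
        """Coherence at which the fitted curve reaches ``accuracy``."""
        finv = _LINKS[self.link][1]
        a = np.asarray(accuracy, dtype=float)
        with np.errstate(divide="ignore"):
            return self.inflexion + finv(a) / self.slope


def _prepare_trials(trials, coherence_col="coherence", correct_col="correct"):
    if isinstance(trials, pd.DataFrame):
        c = trials[coherence_col].to_numpy(dtype=float)
        y = trials[correct_col].to_numpy(dtype=float)
    else:
        c, y = (np.asarray(a, dtype=float) for a in trials)
    if c.shape != y.shape:
        raise ValueError("coherence and correctness arrays must align")
    return c, y


def _nll(params, c, y, f):
    slope, inflexion = params
    p = f(slope * (c - inflexion))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def _num_hessian(fun, x, eps=1e-4):
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.empty((n, n))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return h


def fit_psychometric(trials, link: str = "logit") -> PsychometricFit:
    """Maximum-likelihood fit of the 2AFC psychometric curve.

    ``trials`` is a DataFrame with ``coherence``/``correct`` columns or a
    ``(coherence, correct)`` pair of arrays.  Separation (e.g. all-correct
    data) is reported through the ``diverged`` flag rather than silently
    returning an unstable estimate.
    """
    if link not in _LINKS:
        raise ValueError(f"link must be one of {sorted(_LINKS)}")
    c, y = _prepare_trials(trials)
    if np.unique(c).size < 2:
        raise ValueError("need responses at >= 2 distinct coherence levels")
    f = _LINKS[link][0]

    best = None
    for slope0 in (1.0, 5.0, 20.0):
        for infl0 in (0.0, float(np.median(c))):
            res = optimize.minimize(
                _nll, x0=[slope0, infl0], args=(c, y, f), method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
    slope, inflexion = best.x
    loglik = -best.fun

    diverged = bool(abs(slope) > _SLOPE_DIVERGED)
    if np.all(y == 1) or np.all(y == 0):
        diverged = True
    cov = np.full((2, 2), np.nan)
    if not diverged:
        h = _num_hessian(lambda p: _nll(p, c, y, f), best.x)
        try:
            cov = np.linalg.inv(h)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                diverged = True
        except np.linalg.LinAlgError:
            diverged = True
    return PsychometricFit(
        link=link,
        slope=float(slope),
        inflexion=float(inflexion),
        covariance=cov,
        n_trials=int(c.size),
        loglik=float(loglik),
        converged=bool(best.success),
        diverged=diverged,
        message="separation or non-identified fit" if diverged else "",
    )


# ---------------------------------------------------------------------------
# adaptive calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationState:
    """Grid posterior over (slope, inflexion) during adaptive calibration."""

    slope_grid: np.ndarray
    inflexion_grid: np.ndarray
    log_posterior: np.ndarray  # shape (n_slope, n_inflexion), normalized
    candidates: np.ndarray
    history: list[tuple[float, int]] = field(default_factory=list)
    link: str = "logit"

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    def entropy(self) -> float:
        from scipy.special import xlogy

        w = self.posterior
        return float(-np.sum(xlogy(w, w)))

    def posterior_mean(self) -> tuple[float, float]:
        w = self.posterior
        s = float(np.sum(w.sum(axis=1) * self.slope_grid))
        a = float(np.sum(w.sum(axis=0) * self.inflexion_grid))
        return s, a

    def posterior_cov(self) -> np.ndarray:
        w = self.posterior
        ss, aa = np.meshgrid(self.slope_grid, self.inflexion_grid, indexing="ij")
        ms, ma = self.posterior_mean()
        ds, da = ss - ms, aa - ma
        return np.array(
            [
                [np.sum(w * ds * ds), np.sum(w * ds * da)],
                [np.sum(w * ds * da), np.sum(w * da * da)],
            ]
        )


def _binary_entropy(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(p * np.log(p) + (1 - p) * np.log1p(-p))


def adaptive_calibration(
    respond,
    n_trials: int,
    link: str = "logit",
    slope_grid: np.ndarray | None = None,
    inflexion_grid: np.ndarray | None = None,
    candidates: np.ndarray | None = None,
    state: CalibrationState | None = None,
) -> tuple[CalibrationState, PsychometricFit]:
    """Adaptive calibration by greedy expected-information-gain selection.

    Each trial presents the candidate coherence maximizing the mutual
    information between the upcoming binary response and the psychometric
    parameters under the current grid posterior, then performs a Bayesian
    update with the observed response.  ``respond`` maps a coherence to a 0/1
    correctness outcome.  The returned fit uses posterior moments.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if state is None:
        slope_grid = np.geomspace(0.4, 25.0, 45) if slope_grid is None else np.asarray(slope_grid)
        inflexion_grid = (
            np.linspace(-0.4, 0.6, 45) if inflexion_grid is None else np.asarray(inflexion_grid)
        )
        candidates = (
            np.linspace(0.01, 1.0, 40) if candidates is None else np.asarray(candidates, dtype=float)
        )
        if candidates.size == 0:
            raise ValueError("candidate coherence set must be nonempty")
        logw = np.zeros((slope_grid.size, inflexion_grid.size))
        logw -= np.log(logw.size)
        state = CalibrationState(
            slope_grid=slope_grid,
            inflexion_grid=inflexion_grid,
            log_posterior=logw,
            candidates=candidates,
            link=link,
        )
    f = _LINKS[state.link][0]
    # p[c, i, j] = P(correct | candidate c, slope i, inflexion j)
    p_table = f(
        state.slope_grid[None, :, None]
        * (state.candidates[:, None, None] - state.inflexion_grid[None, None, :])
    )
    for _ in range(n_trials):
        w = np.exp(state.log_posterior)
        p_bar = np.tensordot(p_table, w, axes=([1, 2], [0, 1]))
        info_gain = _binary_entropy(p_bar) - np.tensordot(
            _binary_entropy(p_table), w, axes=([1, 2], [0, 1])
        )
        k = int(np.argmax(info_gain))
        coherence = float(state.candidates[k])
        y = int(respond(coherence))
        lik = p_table[k] if y == 1 else 1.0 - p_table[k]
        state.log_posterior = state.log_posterior + np.log(np.clip(lik, 1e-300, None))
        state.log_posterior -= np.max(state.log_posterior)
        state.log_posterior -= np.log(np.sum(np.exp(state.log_posterior)))
        state.history.append((coherence, y))

    slope, inflexion = state.posterior_mean()
    c_hist = np.array([h[0] for h in state.history])
    y_hist = np.array([h[1] for h in state.history])
    loglik = -_nll([slope, inflexion], c_hist, y_hist, f)
    fit = PsychometricFit(
        link=state.link,
        slope=slope,
        inflexion=inflexion,
        covariance=state.posterior_cov(),
        n_trials=len(state.history),
        loglik=float(loglik),
    )
    return state, fit


def select_test_coherences(
    fit: PsychometricFit,
    accuracies: np.ndarray | None = None,
) -> np.ndarray:
    """Coherences at which the fitted curve attains target accuracies.

    Defaults to 9 evenly spaced accuracy targets 0.55..0.95, spanning the
    50-100% performance range around a ~75% average.  Results are clipped to
    the physical coherence range [0, 1]; a target of exactly 0.5 maps to the
    curve's inflexion (chance) point.
    """
    if fit.slope <= 0:
        raise ValueError("cannot invert a psychometric fit with slope <= 0")
    if accuracies is None:
        accuracies = np.linspace(0.55, 0.95, 9)
    accuracies = np.asarray(accuracies, dtype=float)
    if np.any(accuracies < 0.5) or np.any(accuracies >= 1.0):
        raise ValueError("target accuracies must lie in [0.5, 1.0)")
    return np.clip(fit.inverse(accuracies), 0.0, 1.0)


def reject_outlier_subjects(
    fits: dict[str, PsychometricFit] | pd.DataFrame,
    rule: str = "se",
) -> tuple[list[str], pd.DataFrame]:
    """Partition subjects by the calibration exclusion rules.

    A subject is discarded when the fitted slope falls strictly more than two
    standard errors of the group mean below that mean, or the inflexion point
    strictly more than two such standard errors above it; the two rules apply
    independently.  ``rule='sd'`` swaps the dispersion measure for the group
    SD.  Returns the kept subject ids and a table of (subject_id, rule,
    margin) rows for the discarded ones.
    """
    if rule not in ("se", "sd"):
        raise ValueError("rule must be 'se' or 'sd'")
    if isinstance(fits, pd.DataFrame):
        table = fits[["subject_id", "slope", "inflexion"]].copy()
    else:
        table = pd.DataFrame(
            {
                "subject_id": list(fits),
                "slope": [f.slope for f in fits.values()],
                "inflexion": [f.inflexion for f in fits.values()],
            }
        )
    n = len(table)
    if n < 3:
        raise ValueError("group statistics undefined with fewer than 3 subjects")
    scale = np.sqrt(n) if rule == "se" else 1.0
    slope_cut = table["slope"].mean() - 2 * table["slope"].std(ddof=1) / scale
    infl_cut = table["inflexion"].mean() + 2 * table["inflexion"].std(ddof=1) / scale

    records = []
    for _, row in table.iterrows():
        if row["slope"] < slope_cut:
            records.append((row["subject_id"], "slope_below_2se", slope_cut - row["slope"]))
        if row["inflexion"] > infl_cut:
            records.append((row["subject_id"], "inflexion_above_2se", row["inflexion"] - infl_cut))
    discarded = pd.DataFrame(records, columns=["subject_id", "rule", "margin"])
    kept = [s for s in table["subject_id"] if s not in set(discarded["subject_id"])]
    return kept, discarded
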