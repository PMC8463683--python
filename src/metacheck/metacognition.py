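"""Explicit (meta-d'/M-ratio) and implicit (CMI) metacognitive sensitivity.

The meta-d' fit follows the equal-variance Gaussian rating model: type-1
sensitivity and criterion come from the response margins of the rating table;
meta-d' is the type-1 sensitivity a metacognitively ideal observer would need
to produce the observed confidence-rating distributions, estimated by maximum
likelihood over rating probabilities conditional on (stimulus, response) with
the type-1 criterion held at its proportional location c' = c * meta_d / d'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from .psychometrics import PsychometricFit, fit_psychometric

__all__ = [
    "RatingTable",
    "MetacogEstimates",
    "build_rating_table",
    "fit_meta_d",
    "type2_roc",
    "compute_cmi",
]


@dataclass(frozen=True)
class RatingTable:
    """Counts indexed by (stimulus direction, response, confidence).

    ``counts[s, r, k]``: s and r index direction -1 (0) and +1 (1); k indexes
    confidence 1..n_levels.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3 or c.shape[:2] != (2, 2):
            raise ValueError("counts must have shape (2, 2, n_levels)")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(float))

    @property
    def n_levels(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    def type1_margins(self) -> np.ndarray:
        """2x2 (stimulus x response) table summed over confidence."""
        return self.counts.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per stimulus class, columns resp x confidence."""
        k = self.n_levels
        cols = [f"resp{r:+d}_conf{j + 1}" for r in (-1, 1) for j in range(k)]
        data = self.counts.reshape(2, 2 * k)
        return pd.DataFrame(data, index=["stim-1", "stim+1"], columns=cols)


@dataclass
class MetacogEstimates:
    d_prime: float = np.nan
    criterion: float = np.nan
    meta_d: float = np.nan
    m_ratio: float = np.nan
    cmi: float = np.nan
    loglik: float = np.nan
    converged: bool = False
    undefined: bool = False
    message: str = ""
    fit_chosen: PsychometricFit | None = None
    fit_discarded: PsychometricFit | None = None
    extras: dict = field(default_factory=dict)


def build_rating_table(trials: pd.DataFrame, n_levels: int = 6) -> RatingTable:
    """Cross-tabulate explicit-task trials into a rating table.

    No padding is applied here; padding (if any) happens inside the meta-d'
    fit only.
    """
    missing = trials.index[trials["confidence"].isna()]
    if len(missing):
        raise ValueError(f"trials missing confidence ratings at rows {missing.tolist()[:10]}")
    conf = trials["confidence"].to_numpy()
    if np.any((conf < 1) | (conf > n_levels) | (conf != np.rint(conf))):
        raise ValueError(f"confidence ratings must be integers in 1..{n_levels}")
    counts = np.zeros((2, 2, n_levels))
    s_idx = (trials["direction"].to_numpy() > 0).astype(int)
    r_idx = (trials["response"].to_numpy() > 0).astype(int)
    np.add.at(counts, (s_idx, r_idx, conf.astype(int) - 1), 1.0)
    return RatingTable(counts)


# ---------------------------------------------------------------------------
# meta-d'
# ---------------------------------------------------------------------------


def _type1_sdt(padded: np.ndarray) -> tuple[float, float]:
    margins = padded.sum(axis=2)
    hr = margins[1, 1] / margins[1].sum()
    far = margins[0, 1] / margins[0].sum()
    d = ndtri(hr) - ndtri(far)
    c = -0.5 * (ndtri(hr) + ndtri(far))
    return float(d), float(c)


def _rating_probs(meta_d: float, c_prime: float, t_minus: np.ndarray, t_plus: np.ndarray):
    """P(conf = k | stim, resp) under the meta-level Gaussian model.

    ``t_minus`` descending boundaries below c'; ``t_plus`` ascending above.
    Returns array (2 stim, 2 resp, K) of conditional probabilities.
    """
    k = t_plus.size + 1
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    probs = np.empty((2, 2, k))
    upper = np.concatenate([[c_prime], t_plus, [np.inf]])
    lower = np.concatenate([[-np.inf], t_minus[::-1], [c_prime]])
    for s, mu in enumerate(mus):
        cdf_up = ndtr(upper - mu)
        cdf_lo = ndtr(lower - mu)
        p_resp_pos = 1.0 - ndtr(c_prime - mu)
        p_resp_neg = ndtr(c_prime - mu)
        # response +1: intervals (c', t1), ..., (t_{K-1}, inf) map to conf 1..K
        probs[s, 1, :] = np.diff(cdf_up) / max(p_resp_pos, 1e-300)
        # response -1: intervals (-inf, t_{K-1}) .. (t_1, c'): conf K..1
        probs[s, 0, :] = np.diff(cdf_lo)[::-1] / max(p_resp_neg, 1e-300)
    return np.clip(probs, 1e-300, 1.0)


def _unpack(params: np.ndarray, k: int, c_over_d: float):
    meta_d = params[0]
    c_prime = c_over_d * meta_d
    gaps_minus = np.exp(params[1:k])
    gaps_plus = np.exp(params[k : 2 * k - 1])
    t_minus = c_prime - np.cumsum(gaps_minus)
    t_plus = c_prime + np.cumsum(gaps_plus)
    return meta_d, c_prime, t_minus, t_plus


def meta_d_nll(params: np.ndarray, padded: np.ndarray, c_over_d: float) -> float:
    """Negative conditional log-likelihood of confidence ratings."""
    k = padded.shape[2]
    meta_d, c_prime, t_minus, t_plus = _unpack(params, k, c_over_d)
    probs = _rating_probs(meta_d, c_prime, t_minus, t_plus)
    return float(-np.sum(padded * np.log(probs)))


def fit_meta_d(table: RatingTable, padding: float | None = None) -> MetacogEstimates:
    """Maximum-likelihood meta-d' and M-ratio from a rating table.

    ``padding`` (default ``1 / (2 * n_levels)``) is added to every cell before
    fitting to regularize empty cells; the stored table is never modified.
    """
    k = table.n_levels
    if padding is None:
        padding = 1.0 / (2.0 * k)
    padded = table.counts + padding
    margins = padded.sum(axis=2)
    if np.any(margins.sum(axis=0) <= 0):
        raise ValueError("both response classes must be present after padding")
    d_prime, criterion = _type1_sdt(padded)
    est = MetacogEstimates(d_prime=d_prime, criterion=criterion)
    if d_prime <= 0:
        est.undefined = True
        est.message = "type-1 d' <= 0: meta-d'/M-ratio undefined"
        return est
    c_over_d = criterion / d_prime

    best = None
    for scale in (0.5, 1.0, 1.5):
        x0 = np.concatenate([[d_prime * scale], np.full(2 * (k - 1), np.log(0.4))])
        res = optimize.minimize(
            meta_d_nll,
            x0,
            args=(padded, c_over_d),
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    meta_d = float(best.x[0])
    est.meta_d = meta_d
    est.m_ratio = meta_d / d_prime
    est.loglik = -float(best.fun)
    est.converged = bool(best.success)
    est.extras["params"] = best.x
    return est


def type2_roc(table: RatingTable) -> dict[str, np.ndarray]:
    """Type-1 and type-2 ROC point sets from a rating table.

    Type-1 points sweep the 2K-point ordinal response axis; type-2 points
    sweep confidence cutpoints with hits defined on correct trials.  All
    curves run from (0, 0) to (1, 1) and are monotone nondecreasing.
    """
    if table.n_trials == 0:
        raise ValueError("rating table is empty")
    c = table.counts
    k = table.n_levels
    # ordinal evidence axis for the +1 response: (-1, conf K..1), (+1, conf 1..K)
    axis_pos = np.concatenate([c[:, 0, ::-1], c[:, 1, :]], axis=1)  # (2, 2K)
    with np.errstate(invalid="ignore", divide="ignore"):
        rev = axis_pos[:, ::-1].cumsum(axis=1) / axis_pos.sum(axis=1, keepdims=True)
    t1_far = np.concatenate([[0.0], rev[0]])
    t1_hit = np.concatenate([[0.0], rev[1]])

    s_idx, r_idx = np.meshgrid([0, 1], [0, 1], indexing="ij")
    correct_mask = (s_idx == r_idx)[:, :, None]
    conf_correct = np.where(correct_mask, c, 0.0).sum(axis=(0, 1))
    conf_error = np.where(~correct_mask, c, 0.0).sum(axis=(0, 1))
    n_corr, n_err = conf_correct.sum(), conf_error.sum()
    t2_hit = np.concatenate([[0.0], conf_correct[::-1].cumsum() / max(n_corr, 1e-300)])
    t2_far = np.concatenate([[0.0], conf_error[::-1].cumsum() / max(n_err, 1e-300)])
    return {
        "type1_far": t1_far,
        "type1_hit": t1_hit,
        "type2_far": t2_far,
        "type2_hit": t2_hit,
        "type2_auc": float(np.trapezoid(t2_hit, t2_far)),
    }


# ---------------------------------------------------------------------------
# CMI
# ---------------------------------------------------------------------------


def _validate_pairs(pairs: pd.DataFrame) -> None:
    grp = pairs.groupby("pair_id")
    sizes = grp.size()
    if not (sizes == 2).all():
        bad = sizes.index[sizes != 2].tolist()[:5]
        raise ValueError(f"each pair_id must group exactly two trials; offending: {bad}")
    chosen_counts = grp["chosen"].sum()
    if not (chosen_counts == 1).all():
        bad = chosen_counts.index[chosen_counts != 1].tolist()[:5]
        raise ValueError(f"each pair must have exactly one chosen trial; offending: {bad}")


def compute_cmi(pairs: pd.DataFrame, link: str = "probit") -> MetacogEstimates:
    """Confidence modulation index from confidence forced-choice pairs.

    Fits one psychometric curve to the chosen trials and one to the discarded
    trials and returns ``(slope_chosen - slope_discarded) / mean slope``.
    Positive CMI = good implicit metacognition.
    """
    _validate_pairs(pairs)
    fit_c = fit_psychometric(pairs[pairs["chosen"].astype(bool)], link=link)
    fit_d = fit_psychometric(pairs[~pairs["chosen"].astype(bool)], link=link)
    est = MetacogEstimates(fit_chosen=fit_c, fit_discarded=fit_d)
    mean_slope = 0.5 * (fit_c.slope + fit_d.slope)
    if mean_slope <= 0 or fit_c.diverged or fit_d.diverged:
        est.undefined = True
        est.message = "non-positive average slope or diverged psychometric fit"
        return est
    est.cmi = (fit_c.slope - fit_d.slope) / mean_slope
    est.converged = fit_c.converged and fit_d.converged
    return est
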