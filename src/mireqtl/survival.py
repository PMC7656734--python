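"""Survival-analysis core.

Cox proportional-hazards fitting (Efron tie correction, via lifelines),
prognostic index, Harrell's concordance index, Kaplan-Meier product-limit
curves, the log-rank test, and the minimum-log-rank-P risk-cutoff scan used
to split patients into high- and low-risk groups.

The log-rank machinery is implemented here as a vectorized many-cutoff core:
the cutoff scan evaluates the test at every admissible midpoint between
consecutive distinct prognostic indices, which would be needlessly slow as
repeated single-test calls inside the bootstrap comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateModelError, InputError

log = logging.getLogger(__name__)


@dataclass
class CoxModel:
    """Fitted Cox proportional-hazards model (no baseline hazard)."""

    params: pd.Series  # log-hazard ratio per covariate unit
    standard_errors: pd.Series
    log_likelihood: float
    converged: bool

    @property
    def covariates(self) -> list[str]:
        return list(self.params.index)


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # at-risk count at each event time
    n_events: np.ndarray
    censor_times: np.ndarray  # censoring marks


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def cox_fit(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-9,
    ties: str = "efron",
) -> CoxModel:
    """Fit a Cox model of conversion hazard on the feature columns.

    ``cohort`` must carry ``time`` and ``event`` aligned with ``features``.
    Raises on fewer than two events, constant columns, or rank-deficient
    features (naming the collinear columns); non-convergence is raised as
    :class:`DegenerateModelError`, never silent.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if ties not in ("efron", "breslow"):
        raise InputError("ties must be 'efron' or 'breslow'")
    time = cohort.loc[features.index, "time"].astype(float)
    event = cohort.loc[features.index, "event"].astype(int)
    if int(event.sum()) < 2:
        raise DegenerateModelError("need at least 2 events to fit a Cox model")
    X = features.to_numpy(dtype=float)
    constant = [c for c, v in zip(features.columns, X.std(axis=0)) if v == 0]
    if constant:
        raise InputError(f"constant feature column(s): {constant}")
    # rank check via QR on the standardized design
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    r_diag = np.abs(np.diag(np.linalg.qr(Z, mode="r")))
    collinear = [c for c, r in zip(features.columns, r_diag) if r < 1e-8]
    if collinear:
        raise InputError(f"collinear feature column(s): {collinear}")

    frame = features.copy()
    frame["__time"] = time
    frame["__event"] = event
    fitter = CoxPHFitter(penalizer=0.0)
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(
                frame,
                duration_col="__time",
                event_col="__event",
                show_progress=False,
                fit_options={"max_steps": max_iter, "precision": tol},
            )
        for w in caught:
            if "converge" in str(w.message).lower():
                converged = False
                log.warning("Cox fit convergence warning: %s", w.message)
    except ConvergenceError as exc:
        raise DegenerateModelError(f"Cox fit did not converge: {exc}") from exc
    return CoxModel(
        params=fitter.params_.copy(),
        standard_errors=fitter.standard_errors_.copy(),
        log_likelihood=float(fitter.log_likelihood_),
        converged=converged,
    )


def prognostic_index(model: CoxModel, features: pd.DataFrame) -> pd.Series:
    """PI = sum_i beta_i x_i — the exact linear combination, no centering."""
    missing = [c for c in model.covariates if c not in features.columns]
    if missing:
        raise InputError(f"features lack model covariate(s): {missing}")
    X = features.loc[:, model.covariates].to_numpy(dtype=float)
    return pd.Series(X @ model.params.to_numpy(), index=features.index, name="pi")


def concordance_index(scores, time, event) -> float:
    """Harrell's C over censoring-comparable pairs; score ties count 1/2.

    A pair (i, j) is comparable when the member with the shorter time has an
    event (or, at tied times, exactly one member has an event). Higher scores
    are expected on shorter-time members.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    # comparable[i, j]: i is the event member that defines the ordering
    shorter = (t[:, None] < t[None, :]) | (
        (t[:, None] == t[None, :]) & (e[None, :] == 0)
    )
    comparable = shorter & (e[:, None] == 1)
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise InputError("no comparable pairs under censoring")
    concordant = comparable & (s[:, None] > s[None, :])
    tied = comparable & (s[:, None] == s[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Samples censored exactly at an event time count as at risk for that event
    time (censoring happens just after events at tied times).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise InputError("empty cohort")
    event_times = np.unique(t[e == 1])
    at_risk = (t[:, None] >= event_times[None, :]).sum(axis=0)
    d = ((t[:, None] == event_times[None, :]) & (e[:, None] == 1)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=d,
        censor_times=np.sort(t[e == 0]),
    )


def _logrank_core(
    group_matrix: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistic and P of the two-group log-rank test for each row
    of ``group_matrix`` (boolean membership of 'group 1', K x n)."""
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        raise InputError("log-rank test needs at least one event")
    R = (time[:, None] >= event_times[None, :]).astype(float)  # n x d
    D = ((time[:, None] == event_times[None, :]) & (event[:, None] == 1)).astype(float)
    n_t = R.sum(axis=0)
    d_t = D.sum(axis=0)
    G = group_matrix.astype(float)
    N1 = G @ R  # K x d at-risk in group 1
    D1 = G @ D
    frac = N1 / n_t
    E1 = d_t * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        V = d_t * frac * (1.0 - frac) * (n_t - d_t) / np.maximum(n_t - 1.0, 1.0)
    U = (D1 - E1).sum(axis=1)
    Vs = V.sum(axis=1)
    chi2 = np.where(Vs > 0, U**2 / np.maximum(Vs, 1e-300), 0.0)
    p = np.where(Vs > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def logrank_test(time, event, groups) -> LogrankResult:
    """Standard two-group log-rank test (O - E over hypergeometric variance)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise InputError("exactly two non-empty groups are required")
    member = (g == levels[1])[None, :]
    chi2, p = _logrank_core(member, t, e)
    return LogrankResult(statistic=float(chi2[0]), df=1, p=float(p[0]))


def optimal_cutoff(
    scores, time, event, min_group_frac: float = 0.1
) -> tuple[float, float]:
    """Minimum-log-rank-P cutoff over midpoints of consecutive distinct scores.

    Candidates leaving either risk group below ``min_group_frac`` of the
    cohort are skipped; classification is score > cutoff => high risk. Ties in
    minimum P resolve to the smaller cutoff. Returns ``(cutoff, min_p)``.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    distinct = np.unique(s)
    if distinct.size < 2:
        raise InputError("scores are constant; no cutoff exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = s.size
    high = s[None, :] > candidates[:, None]  # K x n
    n_high = high.sum(axis=1)
    admissible = (n_high >= min_group_frac * n) & (
        (n - n_high) >= min_group_frac * n
    )
    if not admissible.any():
        raise InputError("no admissible cutoff candidates")
    cand = candidates[admissible]
    _, p = _logrank_core(high[admissible], t, e)
    best = int(np.argmin(p))  # ties -> first, i.e. the smaller cutoff
    return float(cand[best]), float(p[best])


# ---------------------------------------------------------------------------
# plotting / serialization


def plot_km(curves: dict[str, KMCurve], path=None, title: str = ""):
    """Step plot of one KM curve per labelled group; saves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        x = np.concatenate([[0.0], curve.times])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("days")
    ax.set_ylabel("conversion-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def write_model_tsv(model: CoxModel, path) -> None:
    frame = pd.DataFrame(
        {"coefficient": model.params, "se": model.standard_errors}
    )
    frame.index.name = "covariate"
    frame.to_csv(path, sep="\t")
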