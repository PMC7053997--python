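"""Two-state Markov state models of loop dynamics.

Estimates a lagged 2x2 transition matrix from discrete helical/extended state
series, with equilibrium probabilities pi, the implied relaxation timescale,
and a Bayesian uncertainty ensemble.

For a two-state chain the reversible maximum-likelihood estimate coincides
with simple row normalization of the lagged count matrix: any irreducible
2-state chain satisfies detailed balance, so no iterative reversible
estimator is needed. Equilibrium probabilities come in closed form,
``pi_h = T_eh / (T_he + T_eh)``, and the implied timescale from the second
eigenvalue ``lambda_2 = 1 - T_he - T_eh`` as ``t = -lag / ln(lambda_2)``.

The Bayesian ensemble draws each transition-matrix row independently from a
Dirichlet posterior with a Jeffreys-style prior (1/2 per cell) over the
observed row counts. This is a deliberate simplification relative to
trajectory-reweighting transition-matrix samplers; only summary statistics
(posterior means and central intervals) are meant to be compared across
implementations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError
from .states import StateSeries

__all__ = [
    "LaggedCounts",
    "Msm2Model",
    "BayesEnsemble",
    "count_transitions",
    "estimate_msm",
    "its_curve",
    "bayes_sample",
    "DEFAULT_LAG_FRAMES",
]

logger = logging.getLogger(__name__)

# 500 frames at a 0.6 ns frame interval is a 300 ns lag, where the implied
# timescale of the loop dynamics plateaus.
DEFAULT_LAG_FRAMES = 500


@dataclass
class LaggedCounts:
    """2x2 transition counts (from-state x to-state) at a fixed lag."""

    counts: np.ndarray
    lag_frames: int
    lag_ns: float
    states: tuple[str, str]
    counting_mode: str = "sliding"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise EstimationError("counts must be a non-negative 2x2 matrix")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class Msm2Model:
    """Maximum-likelihood two-state MSM at one lag."""

    T: np.ndarray
    pi: np.ndarray
    lag_ns: float
    implied_timescale_ns: float
    states: tuple[str, str] = ("helical", "extended")

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-12):
            raise EstimationError("transition matrix rows must sum to 1")
        if np.any(self.pi < 0) or not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-12):
            raise EstimationError("pi must be a probability vector")

    def detailed_balance_residual(self) -> float:
        return float(abs(self.pi[0] * self.T[0, 1] - self.pi[1] * self.T[1, 0]))

    def to_dict(self) -> dict:
        return {"states": list(self.states), "T": self.T.tolist(),
                "pi": self.pi.tolist(), "lag_ns": self.lag_ns,
                "implied_timescale_ns": self.implied_timescale_ns}


@dataclass
class BayesEnsemble:
    """Posterior transition-matrix samples plus summary statistics."""

    samples: list[Msm2Model]
    summaries: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)


def _label_array(series: StateSeries, states: tuple[str, str]) -> np.ndarray:
    lut = {s: i for i, s in enumerate(states)}
    return np.array([lut[l] for l in series.labels], dtype=int)


def count_transitions(
    series_set: list[StateSeries],
    lag_frames: int,
    frame_interval_ns: float = 1.0,
    states: tuple[str, str] = ("helical", "extended"),
    counting_mode: str = "sliding",
) -> LaggedCounts:
    """Lagged transition counts pooled over trajectories.

    Sliding-window counting uses every pair (t, t + lag) within each series;
    strided counting uses non-overlapping pairs (t = 0, lag, 2*lag, ...).
    Pairs never span a trajectory boundary. Series shorter than the lag are
    skipped with a warning; if all are skipped an :class:`EstimationError`
    is raised.
    """
    if lag_frames < 1:
        raise EstimationError("lag must be >= 1 frame")
    counts = np.zeros((2, 2))
    used = 0
    for k, series in enumerate(series_set):
        x = _label_array(series, states)
        if len(x) <= lag_frames:
            logger.warning("series %d (length %d) shorter than lag %d: skipped",
                           k, len(x), lag_frames)
            continue
        if counting_mode == "sliding":
            a, b = x[:-lag_frames], x[lag_frames:]
        elif counting_mode == "strided":
            sub = x[::lag_frames]
            a, b = sub[:-1], sub[1:]
        else:
            raise EstimationError(f"unknown counting mode {counting_mode!r}")
        np.add.at(counts, (a, b), 1)
        used += 1
    if used == 0:
        raise EstimationError("no series longer than the lag: cannot count transitions")
    return LaggedCounts(counts, lag_frames, lag_frames * frame_interval_ns,
                        states, counting_mode)


def estimate_msm(counts: LaggedCounts) -> Msm2Model:
    """Maximum-likelihood two-state MSM from lagged counts.

    Requires at least one count in each row (no absorbing/unvisited state)
    and at least one off-diagonal count overall.
    """
    c = counts.counts
    for i, s in enumerate(counts.states):
        if c[i].sum() == 0:
            raise EstimationError(f"state {s!r} has no outgoing counts")
    if c[0, 1] + c[1, 0] == 0:
        raise EstimationError("no transitions observed between the states")
    T = c / c.sum(axis=1, keepdims=True)
    pi_h = T[1, 0] / (T[0, 1] + T[1, 0])
    pi = np.array([pi_h, 1.0 - pi_h])
    lam2 = 1.0 - T[0, 1] - T[1, 0]
    if 0.0 < lam2 < 1.0:
        its = -counts.lag_ns / math.log(lam2)
    elif lam2 >= 1.0:  # pragma: no cover - excluded by the off-diagonal check
        its = math.inf
    else:
        its = math.nan  # oscillatory regime: timescale undefined at this lag
    return Msm2Model(T, pi, counts.lag_ns, its, counts.states)


def its_curve(
    series_set: list[StateSeries],
    lags: list[int],
    frame_interval_ns: float = 1.0,
    states: tuple[str, str] = ("helical", "extended"),
    plateau_rtol: float = 0.1,
) -> pd.DataFrame:
    """Implied timescale as a function of lag time.

    Returns one row per lag with columns ``lag_frames``, ``lag_ns``,
    ``implied_timescale_ns``, ``ok`` (estimable at that lag) and ``plateau``
    (relative change from the previous estimable lag below ``plateau_rtol``).
    """
    if list(lags) != sorted(lags):
        raise EstimationError("lags must be sorted ascending")
    rows = []
    prev = None
    for lag in lags:
        try:
            model = estimate_msm(count_transitions(series_set, lag, frame_interval_ns, states))
            its = model.implied_timescale_ns
            ok = math.isfinite(its)
        except EstimationError as exc:
            logger.warning("lag %d not estimable: %s", lag, exc)
            its, ok = math.nan, False
        plateau = bool(ok and prev is not None and prev > 0
                       and abs(its - prev) / prev < plateau_rtol)
        rows.append({"lag_frames": lag, "lag_ns": lag * frame_interval_ns,
                     "implied_timescale_ns": its, "ok": ok, "plateau": plateau})
        if ok:
            prev = its
    return pd.DataFrame(rows)


def bayes_sample(
    counts: LaggedCounts,
    n_samples: int = 500,
    seed: int | None = None,
    prior: float = 0.5,
    effective: bool = True,
) -> BayesEnsemble:
    """Bayesian transition-matrix ensemble by per-row Dirichlet sampling.

    Each sample's rows are drawn from Dirichlet(row counts + ``prior``);
    pi and the implied timescale are recomputed per sample. Summaries hold
    the posterior mean and central 95% interval of T_he, T_eh, pi_h, pi_e.

    With sliding-window counting the (t, t+lag) pairs overlap and are far
    from independent; treating them as such makes the posterior spuriously
    narrow. ``effective=True`` (default) therefore rescales sliding counts
    by 1/lag — the standard effective-count correction, equivalent to
    counting non-overlapping windows — before forming the Dirichlet
    parameters. Strided counts are used as-is.
    """
    estimate_msm(counts)  # validate estimability before sampling
    rng = np.random.default_rng(seed)
    c = counts.counts
    if effective and counts.counting_mode == "sliding" and counts.lag_frames > 1:
        c = c / counts.lag_frames
    alpha = c + prior
    t_he = rng.beta(alpha[0, 1], alpha[0, 0], size=n_samples)
    t_eh = rng.beta(alpha[1, 0], alpha[1, 1], size=n_samples)
    samples = []
    for phe, peh in zip(t_he, t_eh):
        T = np.array([[1.0 - phe, phe], [peh, 1.0 - peh]])
        pi_h = peh / (phe + peh)
        lam2 = 1.0 - phe - peh
        its = -counts.lag_ns / math.log(lam2) if 0.0 < lam2 < 1.0 else math.nan
        samples.append(Msm2Model(T, np.array([pi_h, 1.0 - pi_h]),
                                 counts.lag_ns, its, counts.states))
    def _summ(v):
        v = np.asarray(v)
        lo, hi = np.percentile(v, [2.5, 97.5])
        return {"mean": float(v.mean()), "ci95": (float(lo), float(hi))}
    summaries = {
        "T_he": _summ(t_he),
        "T_eh": _summ(t_eh),
        "pi_h": _summ([m.pi[0] for m in samples]),
        "pi_e": _summ([m.pi[1] for m in samples]),
    }
    return BayesEnsemble(samples, summaries)
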