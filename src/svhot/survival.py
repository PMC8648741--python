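"""Survival records and a vectorized k-group log-rank engine.

The engine exists because the iPART threshold search evaluates the log-rank
test over every combination of candidate thresholds (tens of thousands of
partitions per cohort, and once more per leave-one-out fold). Partitions by
thresholds are contiguous ranges of the value-sorted cohort, so at-risk and
death counts for any group are differences of cumulative-sum tables; the
chi-square statistic for whole batches of threshold combinations is then a
handful of array operations.

The statistic is the standard one: at each distinct event time :math:`t_j`
with :math:`d_j` events among :math:`n_j` at risk, group g contributes
observed :math:`d_{gj}` versus expected :math:`d_j n_{gj}/n_j`, with the
hypergeometric covariance; the sum over times is compared to a chi-square
with k-1 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-sample follow-up: time in years, event flag, optional treatment."""

    sample_id: str
    time: float
    event: int
    endpoint: str = "MFS"
    treatment: str | None = None

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"follow-up time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")
        if self.treatment not in (None, "yes", "no"):
            raise ValueError(f"treatment must be yes/no/None, got {self.treatment}")


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = list(records)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "time": [r.time for r in rows],
            "event": [r.event for r in rows],
            "treatment": [r.treatment for r in rows],
        }
    ).set_index("sample_id")


class LogrankResult(NamedTuple):
    statistic: float
    df: int
    p: float


def _group_tables(time: np.ndarray, event: np.ndarray, member: np.ndarray):
    """Per-group at-risk/death tables at distinct event times.

    ``member``: boolean matrix (k, n). Returns (ngj, dgj) of shape (k, J).
    """
    tau = np.unique(time[event.astype(bool)])
    risk = time[None, :] >= tau[:, None]          # (J, n)
    death = (time[None, :] == tau[:, None]) & event.astype(bool)[None, :]
    ngj = np.stack([risk[:, m].sum(axis=1) for m in member])
    dgj = np.stack([death[:, m].sum(axis=1) for m in member])
    return tau, ngj.astype(np.float64), dgj.astype(np.float64)


def logrank_test(
    time: Sequence[float],
    event: Sequence[int],
    labels: Sequence,
) -> LogrankResult:
    """Two-sided k-group log-rank test (chi-square, k-1 df).

    A group with zero members raises ``ValueError``; a cohort with zero
    events returns p = 1 with a warning.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    labels = np.asarray(labels, dtype=object)
    uniq = pd.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    member = np.stack([labels == g for g in uniq])
    if member.sum(axis=1).min() == 0:
        raise ValueError("log-rank test received an empty group")
    if event.sum() == 0:
        warnings.warn("no events in cohort; log-rank p set to 1", stacklevel=2)
        return LogrankResult(0.0, k - 1, 1.0)
    tau, ngj, dgj = _group_tables(time, event, member)
    nj = ngj.sum(axis=0)
    dj = dgj.sum(axis=0)
    corr = np.where(nj > 1, (nj - dj) / np.maximum(nj - 1, 1), 0.0)
    observed = dgj.sum(axis=1)
    expected = (dj * ngj / nj).sum(axis=1)
    frac = ngj / nj
    v = np.empty((k, k))
    for g in range(k):
        for h in range(k):
            delta = 1.0 if g == h else 0.0
            v[g, h] = np.sum(dj * corr * frac[g] * (delta - frac[h]))
    z = (observed - expected)[:-1]
    vm = v[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(vm, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(vm) @ z)
    stat = max(stat, 0.0)
    p = float(_chi2_dist.sf(stat, k - 1))
    return LogrankResult(stat, k - 1, p)


class CutEngine:
    """Batched log-rank evaluation of threshold partitions of one scalar.

    Samples are sorted by their index value once; a partition into k
    contiguous groups is a vector of k-1 cut positions (sample counts in the
    lower groups). All group tables come from cumulative sums over the
    value-sorted sample axis.
    """

    def __init__(
        self,
        values: Sequence[float],
        time: Sequence[float],
        event: Sequence[int],
    ) -> None:
        values = np.asarray(values, dtype=np.float64)
        time = np.asarray(time, dtype=np.float64)
        event = np.asarray(event, dtype=np.int64)
        if not (len(values) == len(time) == len(event)):
            raise ValueError("values/time/event length mismatch")
        order = np.argsort(values, kind="mergesort")
        self.order = order
        self.values = values[order]
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.n = len(values)
        tau = np.unique(self.time[self.event])
        self.n_events = int(self.event.sum())
        risk = (self.time[:, None] >= tau[None, :]).astype(np.float64)
        death = (
            (self.time[:, None] == tau[None, :]) & self.event[:, None]
        ).astype(np.float64)
        zero = np.zeros((1, tau.size))
        self.ncum = np.concatenate([zero, np.cumsum(risk, axis=0)])   # (n+1, J)
        self.dcum = np.concatenate([zero, np.cumsum(death, axis=0)])
        self.nj = self.ncum[-1]
        self.dj = self.dcum[-1]
        self.corr = np.where(
            self.nj > 1, (self.nj - self.dj) / np.maximum(self.nj - 1, 1), 0.0
        )

    def candidate_cuts(self) -> tuple[np.ndarray, np.ndarray]:
        """Midpoints between consecutive distinct sorted values.

        Returns (thresholds, cut_positions); cutting at position c puts the
        first c value-sorted samples in the lower group (value <= threshold).
        """
        distinct, first_idx = np.unique(self.values, return_index=True)
        if distinct.size < 2:
            return np.array([]), np.array([], dtype=np.int64)
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
        # position = count of samples with value <= threshold
        cuts = np.searchsorted(self.values, thresholds, side="right")
        return thresholds, cuts.astype(np.int64)

    def chi2_for_cuts(self, cuts: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Chi-square statistics for a batch of partitions.

        ``cuts``: (M, k-1) strictly increasing cut positions in [1, n-1].
        """
        cuts = np.atleast_2d(np.asarray(cuts, dtype=np.int64))
        m, km1 = cuts.shape
        k = km1 + 1
        out = np.empty(m)
        if self.n_events == 0:
            out.fill(0.0)
            return out
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            b = np.concatenate(
                [
                    np.zeros((hi - lo, 1), dtype=np.int64),
                    cuts[lo:hi],
                    np.full((hi - lo, 1), self.n, dtype=np.int64),
                ],
                axis=1,
            )
            ngj = [self.ncum[b[:, g + 1]] - self.ncum[b[:, g]] for g in range(k)]
            dgj = [self.dcum[b[:, g + 1]] - self.dcum[b[:, g]] for g in range(k)]
            frac = [ngj[g] / self.nj for g in range(k)]
            z = np.stack(
                [
                    dgj[g].sum(axis=1) - (self.dj * frac[g]).sum(axis=1)
                    for g in range(k - 1)
                ],
                axis=1,
            )  # (M, k-1)
            w = self.dj * self.corr
            v = np.empty((hi - lo, k - 1, k - 1))
            for g in range(k - 1):
                for h in range(g, k - 1):
                    delta = 1.0 if g == h else 0.0
                    v[:, g, h] = ((w * frac[g]) * (delta - frac[h])).sum(axis=1)
                    v[:, h, g] = v[:, g, h]
            stat = np.einsum("mi,mij,mj->m", z, np.linalg.pinv(v), z)
            out[lo:hi] = np.maximum(stat, 0.0)
        return out

    def p_for_cuts(self, cuts: np.ndarray) -> np.ndarray:
        cuts = np.atleast_2d(np.asarray(cuts, dtype=np.int64))
        if self.n_events == 0:
            return np.ones(cuts.shape[0])
        stat = self.chi2_for_cuts(cuts)
        return _chi2_dist.sf(stat, cuts.shape[1])


def permutation_logrank_p(
    time: Sequence[float],
    event: Sequence[int],
    labels: Sequence,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation estimate of the log-rank p (labels shuffled vs outcomes)."""
    rng = np.random.default_rng(seed)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    labels = np.asarray(labels, dtype=object)
    observed = logrank_test(time, event, labels).statistic
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        hits += logrank_test(time, event, perm).statistic >= observed
    return hits / n_permutations


def km_curves(
    records: Iterable[SurvivalRecord], labels: dict[str, str]
) -> pd.DataFrame:
    """Kaplan-Meier curves per labelled group (long form, via lifelines).

    Columns: group, time, survival, at_risk.
    """
    from lifelines import KaplanMeierFitter

    df = records_to_frame(records)
    df = df.loc[[s for s in df.index if s in labels]]
    df["group"] = [labels[s] for s in df.index]
    frames = []
    for group, g in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(g["time"], g["event"])
        surv = kmf.survival_function_
        times = surv.index.to_numpy()
        at_risk = np.array(
            [(g["time"].to_numpy() >= t).sum() for t in times], dtype=int
        )
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "time": times,
                    "survival": surv.iloc[:, 0].to_numpy(),
                    "at_risk": at_risk,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def km_median(time: Sequence[float], event: Sequence[int]) -> float:
    """Kaplan-Meier median survival time (inf when never reached)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    return float(kmf.median_survival_time_)
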