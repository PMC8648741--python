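"""iPART: iterative multi-threshold partitioning of a per-patient scalar
against survival.

The search is exhaustive and deterministic: candidate thresholds are the
midpoints between consecutive distinct index values; a k-group partition is
a choice of k-1 of them; the best partition minimizes the k-group log-rank
p-value subject to a minimum group size. Local minima of the single-
threshold scan (below a p cap) provide the reduced candidate sets used for
the double-threshold search, mirroring the published procedure.

Scan-minimized p-values are optimistically biased (no correction over the
search is applied); :func:`permutation_pvalue` offers an honest estimate by
permuting survival against the index.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .survival import CutEngine, LogrankResult, SurvivalRecord, logrank_test, records_to_frame

log = logging.getLogger(__name__)

#: Default minimum samples per group: Kaplan-Meier estimates on tiny groups
#: are degenerate.
MIN_GROUP_SIZE = 5

#: Default cap on local-minimum p-values fed to the double-threshold search
#: (0.10 for iTRAC in the published analysis; 0.3 for iRACIN).
DEFAULT_P_CAP = 0.10

GROUP_NAMES = {2: ("Low", "High"), 3: ("Low", "Medium", "High")}


def group_names(k: int) -> tuple[str, ...]:
    return GROUP_NAMES.get(k, tuple(f"G.{i + 1}" for i in range(k)))


def logrank_p(groups: Mapping[str, Sequence[SurvivalRecord]]) -> float:
    """Two-sided log-rank p over a partition of survival records."""
    labels: list[str] = []
    time: list[float] = []
    event: list[int] = []
    for name, records in groups.items():
        records = list(records)
        if not records:
            raise ValueError(f"group {name!r} has zero members")
        for r in records:
            labels.append(name)
            time.append(r.time)
            event.append(r.event)
    return logrank_test(time, event, labels).p


def _aligned_arrays(
    values: Mapping[str, float] | pd.Series,
    survival: Iterable[SurvivalRecord],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    vals = pd.Series(values, dtype=float)
    surv = {r.sample_id: r for r in survival}
    samples = [s for s in vals.index if s in surv]
    if len(samples) < len(vals):
        log.info("%d sample(s) lack survival records; dropped",
                 len(vals) - len(samples))
    v = vals.loc[samples].to_numpy()
    t = np.array([surv[s].time for s in samples])
    e = np.array([surv[s].event for s in samples])
    return samples, v, t, e


@dataclass
class ThresholdScan:
    """Single-threshold (two-group) scan of the log-rank p-value."""

    thresholds: np.ndarray
    p_values: np.ndarray
    min_group_size: int

    def argmin_threshold(self) -> float:
        return float(self.thresholds[int(np.argmin(self.p_values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "p": self.p_values})


def threshold_scan(
    values: Mapping[str, float] | pd.Series,
    survival: Iterable[SurvivalRecord],
    min_group_size: int = MIN_GROUP_SIZE,
) -> ThresholdScan:
    """Log-rank p at every candidate single threshold.

    Candidates are midpoints between consecutive distinct sorted values;
    those producing a group smaller than ``min_group_size`` are excluded.
    """
    samples, v, t, e = _aligned_arrays(values, survival)
    if len(samples) < 2 * min_group_size:
        raise ValueError(
            f"need at least {2 * min_group_size} samples, got {len(samples)}"
        )
    engine = CutEngine(v, t, e)
    thresholds, cuts = engine.candidate_cuts()
    keep = (cuts >= min_group_size) & (engine.n - cuts >= min_group_size)
    thresholds, cuts = thresholds[keep], cuts[keep]
    if thresholds.size == 0:
        raise ValueError("no feasible single threshold under min_group_size")
    p = engine.p_for_cuts(cuts[:, None])
    return ThresholdScan(thresholds, p, min_group_size)


def local_minima(scan: ThresholdScan, p_cap: float = DEFAULT_P_CAP) -> list[float]:
    """Thresholds at local minima of the scan curve with p below ``p_cap``.

    A plateau of equal p-values counts once, at its midpoint candidate;
    boundary candidates qualify against their single neighbour.
    """
    p = np.asarray(scan.p_values, dtype=float)
    t = np.asarray(scan.thresholds, dtype=float)
    if p.size == 0:
        return []
    minima: list[float] = []
    i = 0
    while i < p.size:
        j = i
        while j + 1 < p.size and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] > p[i]
        right_ok = j == p.size - 1 or p[j + 1] > p[i]
        if left_ok and right_ok and p[i] < p_cap:
            minima.append(float(t[(i + j) // 2]))
        i = j + 1
    return minima


@dataclass
class PartitionResult:
    """Outcome of a k-group threshold partition.

    ``thresholds`` are the k-1 cut values (tl, th for k = 3); labels follow
    Low/Medium/High for k <= 3 and G.1..G.k otherwise, ordered by value
    (value <= tl -> first group).
    """

    k: int
    thresholds: tuple[float, ...]
    labels: dict[str, str]
    logrank_p: float
    group_sizes: dict[str, int]
    statistic: float = float("nan")

    def assign(self, value: float) -> str:
        # value <= threshold goes to the lower group (left-closed groups)
        names = group_names(self.k)
        gi = int(np.sum(value > np.asarray(self.thresholds)))
        return names[gi]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "thresholds": list(self.thresholds),
            "logrank_p": self.logrank_p,
            "statistic": self.statistic,
            "group_sizes": self.group_sizes,
            "labels": self.labels,
        }


def best_partition(
    values: Mapping[str, float] | pd.Series,
    survival: Iterable[SurvivalRecord],
    k: int = 3,
    candidates: Sequence[float] | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
) -> PartitionResult:
    """Exhaustive search for the k-group partition minimizing log-rank p.

    ``candidates`` restricts the searched thresholds (e.g. to local minima
    of the single-threshold scan); by default every midpoint between
    consecutive distinct values is considered. Ties on the p-value are
    broken by the more balanced partition, then by smaller thresholds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    survival = list(survival)
    samples, v, t, e = _aligned_arrays(values, survival)
    engine = CutEngine(v, t, e)
    all_thr, all_cuts = engine.candidate_cuts()
    if candidates is None:
        thr, cuts = all_thr, all_cuts
    else:
        cand = np.asarray(sorted(set(float(c) for c in candidates)))
        cuts = np.searchsorted(engine.values, cand, side="right").astype(np.int64)
        keep = (cuts > 0) & (cuts < engine.n)
        thr, cuts = cand[keep], cuts[keep]
        # distinct cut positions only (two candidates between the same pair
        # of samples give identical partitions)
        _, first = np.unique(cuts, return_index=True)
        thr, cuts = thr[np.sort(first)], cuts[np.sort(first)]
    if thr.size < k - 1:
        raise ValueError(
            f"only {thr.size} candidate thresholds for a {k}-group partition"
        )
    if k == 2:
        combo_cuts = cuts[:, None]
        combo_thr = thr[:, None]
    elif k == 3:
        i, j = np.triu_indices(len(cuts), 1)
        combo_cuts = np.stack([cuts[i], cuts[j]], axis=1)
        combo_thr = np.stack([thr[i], thr[j]], axis=1)
    else:
        combos = list(itertools.combinations(range(len(cuts)), k - 1))
        idx = np.array(combos, dtype=np.int64)
        combo_cuts = cuts[idx]
        combo_thr = thr[idx]
    bounds = np.concatenate(
        [
            np.zeros((len(combo_cuts), 1), dtype=np.int64),
            combo_cuts,
            np.full((len(combo_cuts), 1), engine.n, dtype=np.int64),
        ],
        axis=1,
    )
    sizes = np.diff(bounds, axis=1)
    feasible = (sizes >= min_group_size).all(axis=1)
    if not feasible.any():
        raise ValueError(
            f"no feasible {k}-group partition: {len(combo_cuts)} combinations "
            f"all violate min_group_size={min_group_size} "
            f"(n={engine.n}, candidates={thr.size})"
        )
    combo_cuts, combo_thr, sizes = (
        combo_cuts[feasible], combo_thr[feasible], sizes[feasible]
    )
    stat = engine.chi2_for_cuts(combo_cuts)
    best_stat = stat.max()
    tied = np.flatnonzero(stat >= best_stat - 1e-12)
    if len(tied) > 1:
        balance = ((sizes[tied] - engine.n / k) ** 2).sum(axis=1)
        tied = tied[balance == balance.min()]
        if len(tied) > 1:
            order = np.lexsort(combo_thr[tied].T[::-1])
            tied = tied[order[:1]]
    pick = int(tied[0])
    thresholds = tuple(float(x) for x in combo_thr[pick])
    names = group_names(k)
    labels: dict[str, str] = {}
    value_map = pd.Series(values, dtype=float)
    for s in samples:
        x = value_map[s]
        gi = int(np.sum(x > np.asarray(thresholds)))
        labels[s] = names[gi]
    p = float(_chi2_dist.sf(stat[pick], k - 1))
    group_sizes = {names[g]: int(sizes[pick, g]) for g in range(k)}
    return PartitionResult(k, thresholds, labels, p, group_sizes,
                           statistic=float(stat[pick]))


@dataclass(frozen=True)
class HazardEstimate:
    """Cox proportional-hazards estimate for one group vs the reference."""

    group: str
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n: int
    n_events: int
    infinite_ci: bool = False


def hazard_ratios(
    partition: PartitionResult | Mapping[str, str],
    survival: Iterable[SurvivalRecord],
    reference_group: str | None = None,
) -> list[HazardEstimate]:
    """Per-group hazard ratios vs a reference from a Cox PH fit (lifelines).

    A group with no events yields a degenerate estimate flagged with an
    infinite confidence interval.
    """
    from lifelines import CoxPHFitter

    labels = partition.labels if isinstance(partition, PartitionResult) else dict(partition)
    df = records_to_frame(survival)
    df = df.loc[[s for s in df.index if s in labels]].copy()
    df["group"] = [labels[s] for s in df.index]
    groups = list(pd.unique(df["group"]))
    if isinstance(partition, PartitionResult):
        groups = [g for g in group_names(partition.k) if g in groups]
    if reference_group is None:
        reference_group = groups[0]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref = df[df["group"] == reference_group]
    if len(ref) == 0 or ref["event"].sum() < 1:
        raise ValueError("reference group must be non-empty with >= 1 event")
    out: list[HazardEstimate] = []
    for g in groups:
        if g == reference_group:
            continue
        sub = df[df["group"].isin([reference_group, g])].copy()
        sub["x"] = (sub["group"] == g).astype(float)
        n = int((sub["x"] == 1).sum())
        n_ev = int(sub.loc[sub["x"] == 1, "event"].sum())
        if n_ev == 0:
            out.append(HazardEstimate(g, float("nan"), 0.0, float("inf"),
                                      1.0, n, 0, infinite_ci=True))
            continue
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub[["time", "event", "x"]], duration_col="time",
                    event_col="event")
        s = cph.summary.loc["x"]
        with np.errstate(over="ignore"):  # huge CI bounds -> inf is fine
            out.append(
            HazardEstimate(
                g,
                float(np.exp(s["coef"])),
                float(np.exp(s["coef lower 95%"])),
                float(np.exp(s["coef upper 95%"])),
                float(s["p"]),
                n,
                n_ev,
            )
        )
    return out


def hazard_table(estimates: Iterable[HazardEstimate]) -> pd.DataFrame:
    rows = list(estimates)
    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "hr": [r.hr for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "wald_p": [r.wald_p for r in rows],
            "n": [r.n for r in rows],
            "n_events": [r.n_events for r in rows],
            "infinite_ci": [r.infinite_ci for r in rows],
        }
    )


@dataclass
class LoocvResult:
    """Held-out labels from leave-one-out cross-validation."""

    labels: dict[str, str | None]
    logrank_p: float
    n_failed: int


def loocv(
    values: Mapping[str, float] | pd.Series,
    survival: Iterable[SurvivalRecord],
    k: int = 3,
    candidates: Sequence[float] | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
) -> LoocvResult:
    """Leave-one-out validation of the threshold partition.

    Each fold recomputes the best k-group partition on n-1 samples and
    labels the held-out sample by the resulting thresholds. Returns the n
    held-out labels and the log-rank p of the held-out labelling.
    Deterministic: two runs with the same inputs agree exactly.
    """
    vals = pd.Series(values, dtype=float)
    survival = list(survival)
    surv_by_id = {r.sample_id: r for r in survival}
    samples = [s for s in vals.index if s in surv_by_id]
    held_out: dict[str, str | None] = {}
    n_failed = 0
    for s in samples:
        rest = vals.drop(s)
        try:
            part = best_partition(
                rest,
                [surv_by_id[x] for x in rest.index],
                k=k,
                candidates=candidates,
                min_group_size=min_group_size,
            )
            held_out[s] = part.assign(float(vals[s]))
        except ValueError:
            log.warning("LOOCV fold for sample %s infeasible; labelled NA", s)
            held_out[s] = None
            n_failed += 1
    labelled = [s for s in samples if held_out[s] is not None]
    if len(set(held_out[s] for s in labelled)) >= 2:
        res = logrank_test(
            [surv_by_id[s].time for s in labelled],
            [surv_by_id[s].event for s in labelled],
            [held_out[s] for s in labelled],
        )
        p = res.p
    else:
        p = float("nan")
    return LoocvResult(held_out, p, n_failed)


def multi_k_report(
    values: Mapping[str, float] | pd.Series,
    survival: Iterable[SurvivalRecord],
    k_max: int = 8,
    candidates: Sequence[float] | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Best partition per k in 2..k_max with its p and maximal hazard ratio.

    No automatic winner is declared: the cross-k choice is left to the
    analyst. For k > 3 the search space is the given candidate set (supply
    local-minima thresholds to keep the combinatorics tractable).
    """
    survival = list(survival)
    rows = []
    for k in range(2, k_max + 1):
        try:
            part = best_partition(values, survival, k=k, candidates=candidates,
                                  min_group_size=min_group_size)
        except ValueError as exc:
            log.warning("k=%d infeasible: %s", k, exc)
            continue
        try:
            hrs = hazard_ratios(part, survival)
            max_hr = max((h.hr for h in hrs if np.isfinite(h.hr)), default=float("nan"))
        except ValueError:
            max_hr = float("nan")
        rows.append(
            {
                "k": k,
                "logrank_p": part.logrank_p,
                "max_hr": max_hr,
                "thresholds": ",".join(f"{t:.6g}" for t in part.thresholds),
            }
        )
    return pd.DataFrame(rows)


def permutation_pvalue(
    values: Mapping[str, float] | pd.Series,
    survival: Iterable[SurvivalRecord],
    k: int = 3,
    n_permutations: int = 200,
    min_group_size: int = MIN_GROUP_SIZE,
    seed: int = 0,
) -> float:
    """Honest p-value for the scan-minimized statistic, by permutation.

    Survival records are permuted against the index values; each permuted
    cohort is re-searched, and the fraction of permutations whose best
    statistic reaches the observed one is returned.
    """
    rng = np.random.default_rng(seed)
    vals = pd.Series(values, dtype=float)
    survival = list(survival)
    observed = best_partition(vals, survival, k=k,
                              min_group_size=min_group_size).statistic
    surv_by_id = {r.sample_id: r for r in survival}
    samples = [s for s in vals.index if s in surv_by_id]
    times = np.array([surv_by_id[s].time for s in samples])
    events = np.array([surv_by_id[s].event for s in samples])
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(samples))
        permuted = [
            SurvivalRecord(s, float(times[j]), int(events[j]))
            for s, j in zip(samples, perm)
        ]
        stat = best_partition(vals.loc[samples], permuted, k=k,
                              min_group_size=min_group_size).statistic
        hits += stat >= observed
    return hits / n_permutations
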