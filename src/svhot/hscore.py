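"""The random-breakage-model binomial statistic (Hscore).

Under the random breakage model (RBM) every readable base pair is equally
likely to carry a breakpoint, with probability ``Pu = n / L`` where n is the
total breakpoint count of the set under study and L the readable genome
size. For a merged element track of cumulative length Li containing ni
breakpoints, the number of breakpoints it would harbour by chance is
``X ~ Binomial(Li, Pu)`` and

    Hscore = -log10 P(X > ni)

(strict inequality). The higher the Hscore, the less plausible it is that
the observed concentration of breakpoints in the track is random.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .core import (
    BreakpointCatalog,
    Genome,
    IntervalTrack,
    count_breakpoints_in_track,
    total_breakpoints,
)

#: Finite stand-in for an infinite Hscore in matrix/plot exports.
HSCORE_CAP = 350.0

#: Hscore at/above which an element class counts as significantly broken.
HOTSPOT_THRESHOLD = 3.0

#: A hotspot must exceed its flanks by this Hscore ratio when both are hot.
FLANK_RATIO = 1.5


@dataclass(frozen=True)
class HscoreResult:
    """Hscore of one track against one breakpoint set.

    ``hscore`` is ``math.inf`` when the tail probability underflows to zero
    (the statistic "tends to infinity"); ``adjusted`` marks Holm-corrected
    tail probabilities.
    """

    element_class: str
    ni: int
    li: int
    pu: float
    p_tail: float
    hscore: float
    adjusted: bool = False

    @property
    def infinite(self) -> bool:
        return math.isinf(self.hscore)

    def capped_hscore(self, cap: float = HSCORE_CAP) -> float:
        return min(self.hscore, cap)


def uniform_break_probability(n_total: int, genome: Genome) -> float:
    """Pu = n / L, the per-base breakage probability under the RBM."""
    if n_total < 1:
        raise ValueError("Hscore is undefined for an empty breakpoint set")
    size = genome.readable_size
    if size <= 0:
        raise ValueError("readable genome size must be positive")
    pu = n_total / size
    if pu > 1.0:
        raise ValueError(f"more breakpoints ({n_total}) than readable bases ({size})")
    return pu


def _log10_tail_by_summation(ni: int, li: int, pu: float) -> float:
    """log10 P(X > ni) via log-space pmf summation over the upper tail.

    Accurate deep in the tail where the survival function underflows;
    terms beyond the point where they stop contributing are skipped.
    """
    logs: list[np.ndarray] = []
    x = ni + 1
    block = 1024
    best = -np.inf
    while x <= li:
        xs = np.arange(x, min(x + block, li + 1))
        lp = binom.logpmf(xs, li, pu)
        logs.append(lp)
        best = max(best, float(lp.max()))
        # mean < ni in the regimes that reach here, so terms decay;
        # stop once the block is negligible against the running maximum
        if lp[-1] < best - 46:  # e^-46 ~ 1e-20 relative
            break
        x += block
    total = logsumexp(np.concatenate(logs))
    return float(total) / math.log(10)


def log10_binomial_tail(ni: int, li: int, pu: float) -> tuple[float, float]:
    """(p_tail, hscore) with ``p_tail = P(X > ni)`` for X ~ Binomial(li, pu).

    Computed through the regularized-incomplete-beta survival function, with
    a log-space pmf summation once the tail approaches the floating-point
    floor; ``hscore`` is infinite exactly when p_tail underflows to 0.
    """
    ni, li = int(ni), int(li)
    if not 0 <= ni <= li:
        raise ValueError(f"require 0 <= ni <= Li, got ni={ni}, Li={li}")
    if not 0.0 <= pu <= 1.0:
        raise ValueError(f"Pu must be a probability, got {pu}")
    if ni == li or pu == 0.0:
        return 0.0, math.inf
    if pu == 1.0:
        return 1.0, 0.0
    p_tail = float(binom.sf(ni, li, pu))
    if p_tail >= 1e-250:
        return p_tail, -math.log10(p_tail) if p_tail < 1.0 else 0.0
    log10_p = _log10_tail_by_summation(ni, li, pu)
    p_tail = float(10.0 ** log10_p)
    if p_tail == 0.0:
        return 0.0, math.inf
    return p_tail, -log10_p


def hscore_for_track(
    catalogs: BreakpointCatalog | Iterable[BreakpointCatalog],
    track: IntervalTrack,
    genome: Genome,
    n_total: int | None = None,
) -> HscoreResult:
    """Hscore of one element track for a breakpoint set (cohort or patient).

    ``n_total`` defaults to the total breakpoint count of ``catalogs`` and
    sets Pu; pass it explicitly when scoring a sub-track under the Pu of a
    larger set.
    """
    if isinstance(catalogs, BreakpointCatalog):
        catalogs = [catalogs]
    else:
        catalogs = list(catalogs)
    if n_total is None:
        n_total = total_breakpoints(catalogs)
    merged = track.merge()
    li = merged.cumulative_length()
    ni = count_breakpoints_in_track(catalogs, merged, genome)
    pu = uniform_break_probability(n_total, genome)
    p_tail, hscore = log10_binomial_tail(ni, li, pu)
    return HscoreResult(track.element_class, ni, li, pu, p_tail, hscore)


@dataclass(frozen=True)
class StructureCall:
    """Hotspot / hot-region verdict for one element class.

    A class is a *hotspot* when it is significantly more broken than chance
    (Hscore >= 3) while its immediate flanks are not, or when all three are
    significant but the centre exceeds 1.5x both flanks. When centre and
    flanks are all significant without that margin the whole neighbourhood
    is a *hot region*. ``mixed_flanks`` flags the configuration (one flank
    significant, one not) that the two published rules do not cover; it is
    resolved by the 1.5x-margin rule against the larger flank.
    """

    verdict: str
    center_hscore: float
    flank_minus: float
    flank_plus: float
    mixed_flanks: bool = False


def classify_structure(
    center: float, flank_minus: float, flank_plus: float
) -> StructureCall:
    """Apply the hotspot / hot-region rules to a centre and its +-1 flanks."""
    for name, h in (("center", center), ("flank_minus", flank_minus),
                    ("flank_plus", flank_plus)):
        if h < 0 or math.isnan(h):
            raise ValueError(f"{name} hscore must be >= 0, got {h}")
    t = HOTSPOT_THRESHOLD
    fmax = max(flank_minus, flank_plus)
    if center < t:
        return StructureCall("not_significant", center, flank_minus, flank_plus)
    if fmax < t:
        return StructureCall("hotspot", center, flank_minus, flank_plus)
    mixed = min(flank_minus, flank_plus) < t
    if math.isinf(center) and math.isinf(fmax):
        # indeterminate ratio: both saturate the scale
        verdict = "hot_region"
    elif center >= FLANK_RATIO * fmax:
        verdict = "hotspot"
    else:
        verdict = "hot_region" if not mixed else "not_significant"
    return StructureCall(verdict, center, flank_minus, flank_plus, mixed)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class HscoreMatrix:
    """Per-sample x per-class Hscore grid with the underlying results."""

    hscores: pd.DataFrame             # samples x classes, float (inf allowed)
    results: dict[tuple[str, str], HscoreResult]
    adjust: str = "none"

    def to_tsv(
        self,
        path,
        cap: float = HSCORE_CAP,
        rescale_outliers: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        """Export for downstream clustering tools.

        Infinite scores are capped. ``rescale_outliers`` maps sample ids to
        (divisor, multiplier) pairs — a presentation-only shrink of extreme
        rows; it never alters stored results.
        """
        out = self.hscores.clip(upper=cap)
        if rescale_outliers:
            out = out.copy()
            for sample, (div, mul) in rescale_outliers.items():
                out.loc[sample] = out.loc[sample] / div * mul
        out.to_csv(path, sep="\t", float_format="%.6g")


def hscore_matrix(
    cohort: Sequence[BreakpointCatalog],
    tracks: Sequence[IntervalTrack] | Mapping[str, IntervalTrack],
    genome: Genome,
    adjust: str = "holm",
) -> HscoreMatrix:
    """Per-patient Hscores across element classes.

    Each sample's Pu uses its own total breakpoint count. With
    ``adjust="holm"`` the tail probabilities within each sample (family =
    all element classes) undergo Holm step-down before the -log10; adjusted
    Hscores are never larger than raw ones.
    """
    if adjust not in ("none", "holm"):
        raise ValueError(f"adjust must be 'none' or 'holm', got {adjust!r}")
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if isinstance(tracks, Mapping):
        tracks = list(tracks.values())
    merged = [t.merge() for t in tracks]
    classes = [t.element_class for t in merged]
    results: dict[tuple[str, str], HscoreResult] = {}
    rows = []
    for cat in cohort:
        if cat.tbpc == 0:
            warnings.warn(
                f"sample {cat.sample_id} has no breakpoints; skipped", stacklevel=2
            )
            continue
        sample_results = [
            hscore_for_track(cat, t, genome, n_total=cat.tbpc) for t in merged
        ]
        if adjust == "holm":
            adj_p = holm_adjust([r.p_tail for r in sample_results])
            sample_results = [
                replace(
                    r,
                    p_tail=float(pa),
                    hscore=(-math.log10(pa) if pa > 0 else math.inf),
                    adjusted=True,
                )
                for r, pa in zip(sample_results, adj_p)
            ]
        for r in sample_results:
            results[(cat.sample_id, r.element_class)] = r
        rows.append(
            pd.Series(
                [r.hscore for r in sample_results], index=classes, name=cat.sample_id
            )
        )
    if not rows:
        raise ValueError("no sample with breakpoints in cohort")
    grid = pd.DataFrame(rows)
    grid.index.name = "sample_id"
    return HscoreMatrix(grid, results, adjust)


def results_table(results: Iterable[HscoreResult]) -> pd.DataFrame:
    """Flat results table (one row per track)."""
    rows = list(results)
    return pd.DataFrame(
        {
            "element_class": [r.element_class for r in rows],
            "ni": [r.ni for r in rows],
            "Li": [r.li for r in rows],
            "Pu": [r.pu for r in rows],
            "p_tail": [r.p_tail for r in rows],
            "hscore": [r.capped_hscore() for r in rows],
            "adjusted": [r.adjusted for r in rows],
            "infinite": [r.infinite for r in rows],
        }
    )
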