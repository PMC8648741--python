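"""Gene-context split: inside-gene vs outside-gene element sub-tracks.

An element is *inside* a gene when it overlaps the TSS-TES interval of any
gene by at least one base pair; otherwise it is *outside*. Elements are
assigned wholly (never split), so element counts are conserved. The two
sub-tracks are scored under the same RBM (same n and L) and compared by the
ratio of their Hscores, RHscore i/o.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import BreakpointCatalog, GeneModel, Genome, IntervalTrack
from .hscore import HscoreResult, hscore_for_track


class UndefinedRatioError(ValueError):
    """RHscore i/o is undefined when the outside-gene Hscore is zero."""


def split_track_by_genes(
    track: IntervalTrack,
    genes: GeneModel | IntervalTrack,
    expressed_only: bool = False,
) -> tuple[IntervalTrack, IntervalTrack]:
    """Partition a track's elements into (inside, outside) gene sub-tracks.

    Overlapping genes are merged before the test so assignment is
    deterministic; the split operates on the original (unmerged) elements.
    """
    gene_track = (
        genes.gene_track(expressed_only) if isinstance(genes, GeneModel) else genes
    )
    merged_genes = gene_track.merge().per_chrom()
    inside = np.zeros(len(track), dtype=bool)
    for chrom in np.unique(track.chroms):
        mask = track.chroms == chrom
        if str(chrom) not in merged_genes:
            continue
        gs, ge = merged_genes[str(chrom)]
        s, e = track.starts[mask], track.ends[mask]
        # merged genes are disjoint and sorted, so the only candidate for
        # overlap with [s, e) is the last gene starting before e
        idx = np.searchsorted(gs, e, side="left") - 1
        hit = (idx >= 0) & (ge[np.clip(idx, 0, None)] > s)
        inside[np.flatnonzero(mask)[hit]] = True
    def _subset(mask: np.ndarray, suffix: str) -> IntervalTrack:
        return IntervalTrack(
            track.element_class,
            track.chroms[mask],
            track.starts[mask],
            track.ends[mask],
        )

    return _subset(inside, "ingene"), _subset(~inside, "outgene")


def rhscore_io(h_inside: float, h_outside: float) -> float:
    """RHscore i/o = inside-gene Hscore / outside-gene Hscore.

    Raises :class:`UndefinedRatioError` for a zero denominator; an infinite
    numerator gives inf, an infinite denominator gives 0.0, and both
    infinite give nan (indeterminate).
    """
    if h_inside < 0 or h_outside < 0:
        raise ValueError("Hscores must be non-negative")
    if h_outside == 0.0:
        raise UndefinedRatioError("outside-gene Hscore is 0; ratio undefined")
    if math.isinf(h_inside) and math.isinf(h_outside):
        return math.nan
    return h_inside / h_outside


@dataclass(frozen=True)
class GeneContextResult:
    element_class: str
    inside: HscoreResult
    outside: HscoreResult

    @property
    def rhscore(self) -> float:
        try:
            return rhscore_io(self.inside.hscore, self.outside.hscore)
        except UndefinedRatioError:
            return math.nan


def ingene_outgene_hscores(
    catalogs: BreakpointCatalog | Iterable[BreakpointCatalog],
    track: IntervalTrack,
    genes: GeneModel | IntervalTrack,
    genome: Genome,
    n_total: int | None = None,
    expressed_only: bool = False,
) -> GeneContextResult:
    """Split a track by gene context and score both halves under one RBM.

    Both sub-tracks use the full-set Pu (same n_total, same L): the split
    compares territories under a single null, not two separate nulls.
    """
    if isinstance(catalogs, BreakpointCatalog):
        catalogs = [catalogs]
    else:
        catalogs = list(catalogs)
    if n_total is None:
        from .core import total_breakpoints

        n_total = total_breakpoints(catalogs)
    ins, out = split_track_by_genes(track, genes, expressed_only)
    return GeneContextResult(
        track.element_class,
        inside=hscore_for_track(catalogs, ins, genome, n_total),
        outside=hscore_for_track(catalogs, out, genome, n_total),
    )


def gene_context_table(results: Iterable[GeneContextResult]) -> pd.DataFrame:
    rows = list(results)
    return pd.DataFrame(
        {
            "element_class": [r.element_class for r in rows],
            "h_in": [r.inside.capped_hscore() for r in rows],
            "h_out": [r.outside.capped_hscore() for r in rows],
            "rhscore_io": [r.rhscore for r in rows],
        }
    )
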