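"""Genomic coordinate types, interval algebra and breakpoint bookkeeping.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
A breakpoint (BP) is a single base position where one side of a structural
variant (SV) junction maps; every SV contributes exactly two breakpoints.
A track is the set of intervals of one DNA-element class (CpG islands,
G-quadruplex motifs, R-loop forming sequences, ...); after merging, its
cumulative length ``Li`` is the number of covered bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Total ungapped length of the hg38 assembly, used as the readable genome
#: size L when real-genome coordinates are analysed.
HG38_READABLE_SIZE = 2_948_611_470


class CoordinateError(ValueError):
    """Invalid genomic coordinates (negative, empty, or off-chromosome)."""


class StructuralError(ValueError):
    """Malformed SV bookkeeping (e.g. an sv_id without exactly two sides)."""


@dataclass(frozen=True)
class Genome:
    """A genome as an ordered set of chromosomes plus a readable size L.

    ``readable_size`` is the number of base pairs that can carry a
    breakpoint (the ungapped genome length). For synthetic genomes with no
    gaps it defaults to the sum of chromosome lengths.
    """

    chromosomes: tuple[tuple[str, int], ...]
    readable_size: int = 0

    def __post_init__(self) -> None:
        chroms = tuple((str(c), int(n)) for c, n in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise CoordinateError("duplicate chromosome names")
        if any(n <= 0 for _, n in chroms):
            raise CoordinateError("chromosome lengths must be positive")
        total = sum(n for _, n in chroms)
        if self.readable_size == 0:
            object.__setattr__(self, "readable_size", total)
        if not 0 < self.readable_size <= total:
            raise CoordinateError(
                f"readable_size must be in (0, {total}], got {self.readable_size}"
            )

    @classmethod
    def from_sizes(cls, sizes: Mapping[str, int], readable_size: int = 0) -> "Genome":
        return cls(tuple(sizes.items()), readable_size)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalTrack:
    """A named class of genomic intervals, stored as parallel numpy arrays.

    ``merged`` is True when the intervals are sorted and pairwise
    non-overlapping, so ``cumulative_length`` equals the covered-base count.
    """

    def __init__(
        self,
        element_class: str,
        chroms: Sequence[str] | np.ndarray,
        starts: Sequence[int] | np.ndarray,
        ends: Sequence[int] | np.ndarray,
        merged: bool = False,
        genome: Genome | None = None,
    ) -> None:
        self.element_class = element_class
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise CoordinateError("chroms/starts/ends length mismatch")
        if np.any(self.starts < 0) or np.any(self.starts >= self.ends):
            raise CoordinateError(
                f"track {element_class!r} has an interval with start >= end or start < 0"
            )
        if genome is not None:
            lengths = genome.lengths
            for c in np.unique(self.chroms):
                if c not in lengths:
                    raise CoordinateError(f"unknown chromosome {c!r}")
            caps = np.array([lengths[c] for c in self.chroms], dtype=np.int64)
            if np.any(self.ends > caps):
                raise CoordinateError(
                    f"track {element_class!r} has intervals beyond chromosome ends"
                )
        self.merged = merged

    @classmethod
    def from_intervals(
        cls,
        element_class: str,
        intervals: Iterable[GenomicInterval | tuple[str, int, int]],
        merged: bool = False,
    ) -> "IntervalTrack":
        rows = [
            (iv.chrom, iv.start, iv.end)
            if isinstance(iv, GenomicInterval)
            else (iv[0], int(iv[1]), int(iv[2]))
            for iv in intervals
        ]
        if not rows:
            return cls(element_class, [], [], [], merged=True)
        c, s, e = zip(*rows)
        return cls(element_class, list(c), list(s), list(e), merged=merged)

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield GenomicInterval(c, int(s), int(e))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted (starts, ends) arrays per chromosome."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in np.unique(self.chroms):
            mask = self.chroms == c
            s, e = self.starts[mask], self.ends[mask]
            order = np.argsort(s, kind="mergesort")
            out[str(c)] = (s[order], e[order])
        return out

    def merge(self) -> "IntervalTrack":
        """bedtools-style merge: sort and fuse overlapping or bookended
        intervals. The set of covered bases is preserved."""
        if self.merged:
            return self
        chroms: list[str] = []
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        for c in sorted({str(x) for x in self.chroms}):
            s, e = self.per_chrom()[c]
            cummax = np.maximum.accumulate(e)
            # new block where start exceeds every previous end (strictly:
            # bookended intervals [a,b) + [b,c) fuse, as bedtools does)
            new = np.empty(len(s), dtype=bool)
            new[0] = True
            new[1:] = s[1:] > cummax[:-1]
            idx = np.flatnonzero(new)
            ms = s[idx]
            me = np.maximum.reduceat(e, idx)
            chroms.extend([c] * len(idx))
            starts.append(ms)
            ends.append(me)
        if not chroms:
            return IntervalTrack(self.element_class, [], [], [], merged=True)
        return IntervalTrack(
            self.element_class,
            chroms,
            np.concatenate(starts),
            np.concatenate(ends),
            merged=True,
        )

    def cumulative_length(self) -> int:
        """Li: total covered bases (merges first when needed)."""
        t = self.merge()
        return int(np.sum(t.ends - t.starts))


def merge_track(track: IntervalTrack) -> IntervalTrack:
    """Sort and fuse overlapping intervals; idempotent."""
    return track.merge()


def cumulative_length(track: IntervalTrack) -> int:
    """Sum of merged interval sizes (symbol Li). Empty track -> 0."""
    return track.cumulative_length()


@dataclass(frozen=True)
class Breakpoint:
    """One side of an SV junction at a single base position."""

    sample_id: str
    chrom: str
    pos: int
    sv_id: str
    side: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise CoordinateError(f"negative breakpoint position {self.pos}")
        if self.side not in (1, 2):
            raise StructuralError(f"side must be 1 or 2, got {self.side}")


class BreakpointCatalog:
    """All breakpoints of one tumour sample, with SV pairing.

    ``tbpc`` (total breakpoint count) is the number of rows. A breakpoint is
    *intra*-chromosomal when both sides of its SV map to the same chromosome.
    """

    COLUMNS = ("chrom", "pos", "sv_id", "side")

    def __init__(self, sample_id: str, frame: pd.DataFrame) -> None:
        self.sample_id = sample_id
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise StructuralError(f"breakpoint frame missing columns {sorted(missing)}")
        df = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        df["side"] = df["side"].astype(np.int64)
        if (df["pos"] < 0).any():
            raise CoordinateError("negative breakpoint position")
        self.frame = df

    @classmethod
    def from_breakpoints(
        cls, sample_id: str, breakpoints: Iterable[Breakpoint]
    ) -> "BreakpointCatalog":
        rows = [(b.chrom, b.pos, b.sv_id, b.side) for b in breakpoints]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(sample_id, df)

    @property
    def tbpc(self) -> int:
        return len(self.frame)

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        return {
            str(c): g["pos"].to_numpy()
            for c, g in self.frame.groupby("chrom", sort=False)
        }

    def validate_against(self, genome: Genome) -> None:
        lengths = genome.lengths
        for c, pos in self.positions_by_chrom().items():
            if c not in lengths:
                raise CoordinateError(
                    f"sample {self.sample_id}: breakpoint on unknown chromosome {c!r}"
                )
            if pos.max(initial=-1) >= lengths[c]:
                raise CoordinateError(
                    f"sample {self.sample_id}: breakpoint beyond end of {c}"
                )

    def sv_side_counts(self) -> tuple[int, int]:
        return classify_sv_sides(self)

    @property
    def n_bpsv_intra(self) -> int:
        return self.sv_side_counts()[0]

    @property
    def n_bpsv_inter(self) -> int:
        return self.sv_side_counts()[1]


def classify_sv_sides(catalog: BreakpointCatalog) -> tuple[int, int]:
    """(n_bpsv_intra, n_bpsv_inter): BP counts by SV chromosomal span.

    Both sides of an SV count; the two numbers sum to ``tbpc``. Raises
    :class:`StructuralError` if any sv_id has a side count other than two.
    """
    df = catalog.frame
    if df.empty:
        return (0, 0)
    sizes = df.groupby("sv_id")["chrom"].agg(["size", "nunique"])
    bad = sizes.index[sizes["size"] != 2]
    if len(bad):
        raise StructuralError(
            f"sample {catalog.sample_id}: sv_ids without exactly 2 sides: "
            f"{list(bad[:5])}"
        )
    n_intra = int(2 * (sizes["nunique"] == 1).sum())
    return (n_intra, catalog.tbpc - n_intra)


def count_breakpoints_in_track(
    catalogs: BreakpointCatalog | Iterable[BreakpointCatalog],
    track: IntervalTrack,
    genome: Genome | None = None,
) -> int:
    """ni: number of breakpoints inside the merged track.

    Membership is the half-open test ``start <= pos < end``. With a genome
    given, breakpoints on chromosomes absent from it raise
    :class:`CoordinateError`.
    """
    if isinstance(catalogs, BreakpointCatalog):
        catalogs = [catalogs]
    merged = track.merge()
    by_chrom = merged.per_chrom()
    known = genome.lengths if genome is not None else None
    total = 0
    for cat in catalogs:
        for chrom, pos in cat.positions_by_chrom().items():
            if known is not None and chrom not in known:
                raise CoordinateError(
                    f"sample {cat.sample_id}: breakpoint on unknown chromosome {chrom!r}"
                )
            if chrom not in by_chrom:
                continue
            s, e = by_chrom[chrom]
            idx = np.searchsorted(s, pos, side="right") - 1
            inside = (idx >= 0) & (pos < e[np.clip(idx, 0, None)])
            total += int(np.count_nonzero(inside))
    return total


def total_breakpoints(catalogs: Iterable[BreakpointCatalog]) -> int:
    return sum(c.tbpc for c in catalogs)


@dataclass
class GeneModel:
    """Gene intervals spanning TSS to TES, with an expression-evidence flag.

    The gene-context split can be restricted to genes with expression
    evidence; synthetic gene models mark all genes expressed by default.
    """

    track: IntervalTrack
    expressed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.expressed is None:
            self.expressed = np.ones(len(self.track), dtype=bool)
        self.expressed = np.asarray(self.expressed, dtype=bool)
        if len(self.expressed) != len(self.track):
            raise CoordinateError("expressed flags do not match gene count")

    def gene_track(self, expressed_only: bool = False) -> IntervalTrack:
        if not expressed_only or self.expressed.all():
            return self.track
        mask = self.expressed
        return IntervalTrack(
            self.track.element_class,
            self.track.chroms[mask],
            self.track.starts[mask],
            self.track.ends[mask],
        )
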