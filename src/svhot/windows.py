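"""Shifted-track Hscore profiles and profile-based hotspot calling.

Each element is shifted by k x 100% of its own length (k = -max_k .. +max_k,
positive = rightward in genome coordinates), the shifted track is merged and
re-scored, and the centre (offset 0) is classified against its immediate
flanks (offsets -1 and +1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import BreakpointCatalog, Genome, IntervalTrack
from .hscore import HscoreResult, StructureCall, classify_structure, hscore_for_track

log = logging.getLogger(__name__)


def shift_track(track: IntervalTrack, k: int, genome: Genome) -> IntervalTrack:
    """Shift every interval by k times its own length; clip at chromosome
    bounds; intervals pushed entirely off-chromosome are dropped (logged).

    The result is merged, so its cumulative length reflects the countable
    territory at that offset.
    """
    if k == 0:
        raise ValueError("k must be non-zero; offset 0 is the unshifted track")
    lengths = genome.lengths
    widths = track.ends - track.starts
    starts = track.starts + k * widths
    ends = track.ends + k * widths
    caps = np.array([lengths[c] for c in track.chroms], dtype=np.int64)
    starts = np.clip(starts, 0, caps)
    ends = np.clip(ends, 0, caps)
    keep = starts < ends
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        log.info(
            "shift_track(%s, k=%+d): %d interval(s) off-chromosome, dropped",
            track.element_class, k, dropped,
        )
    shifted = IntervalTrack(
        track.element_class, track.chroms[keep], starts[keep], ends[keep]
    )
    return shifted.merge()


@dataclass
class HscoreProfile:
    """Hscore per window offset for one element class (offset 0 = elements)."""

    element_class: str
    results: dict[int, HscoreResult]

    def classify(self) -> StructureCall:
        """Hotspot call from the centre and its immediate (+-1) flanks."""
        return classify_structure(
            self.results[0].hscore,
            self.results[-1].hscore,
            self.results[+1].hscore,
        )

    def to_frame(self) -> pd.DataFrame:
        offsets = sorted(self.results)
        rows = [self.results[k] for k in offsets]
        return pd.DataFrame(
            {
                "element_class": self.element_class,
                "offset": offsets,
                "ni": [r.ni for r in rows],
                "Li": [r.li for r in rows],
                "hscore": [r.capped_hscore() for r in rows],
            }
        )


def build_profile(
    catalogs: BreakpointCatalog | Iterable[BreakpointCatalog],
    track: IntervalTrack,
    genome: Genome,
    n_total: int | None = None,
    max_k: int = 8,
) -> HscoreProfile:
    """Hscore at offsets -max_k..+max_k; offset 0 is the unshifted track."""
    if isinstance(catalogs, BreakpointCatalog):
        catalogs = [catalogs]
    else:
        catalogs = list(catalogs)
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    results: dict[int, HscoreResult] = {
        0: hscore_for_track(catalogs, track, genome, n_total)
    }
    for k in range(1, max_k + 1):
        for sk in (-k, +k):
            shifted = shift_track(track, sk, genome)
            results[sk] = hscore_for_track(catalogs, shifted, genome, n_total)
    return HscoreProfile(track.element_class, results)


def profile_plot(profile: HscoreProfile, path) -> None:
    """hscore vs offset with the hotspotness threshold line at 3."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["offset"], df["hscore"], marker="o", color="black")
    ax.axhline(3.0, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("window offset (x element length)")
    ax.set_ylabel("Hscore")
    ax.set_title(profile.element_class)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
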