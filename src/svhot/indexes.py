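"""Pooled instability index tracks and per-patient iTRAC / iRACIN values.

TRACe (transcription-associated chromosomal instability elements) are the
classes broken preferentially inside genes; RACINe (replication-associated)
are broken irrespective of gene context. Each index pools its member BED
tracks into one merged territory; a patient's index value is the Hscore of
that territory for the patient's own breakpoints (per-patient Pu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BreakpointCatalog, Genome, IntervalTrack
from .hscore import hscore_for_track

#: Default TRACe membership; "DHS" unqualified covers all four sub-classes.
TRACE_CLASSES = (
    "RLFS", "GQ", "CpGi", "CRM", "SCS-S",
    "DHS_prom", "DHS_enh", "DHS_dyadic", "DHS_rest",
)

#: Default RACINe membership.
RACIN_CLASSES = ("DR", "STR", "MR", "IR", "Z", "SR", "MS", "LC")


class ConfigurationError(ValueError):
    """An index definition references element classes that are absent."""


@dataclass(frozen=True)
class IndexDefinition:
    """A named instability index and its member element classes."""

    name: str
    member_classes: tuple[str, ...]


def trace_definition(include_dhs_rest: bool = True) -> IndexDefinition:
    """iTRAC membership. ``include_dhs_rest=False`` drops the DHS sub-class
    without attributable regulatory function (not significantly broken)."""
    members = tuple(
        c for c in TRACE_CLASSES if include_dhs_rest or c != "DHS_rest"
    )
    return IndexDefinition("iTRAC", members)


def racin_definition() -> IndexDefinition:
    return IndexDefinition("iRACIN", RACIN_CLASSES)


def build_index_track(
    tracks: Sequence[IntervalTrack] | Mapping[str, IntervalTrack],
    definition: IndexDefinition,
) -> IntervalTrack:
    """Pool the member class tracks into one sorted, merged index track."""
    if isinstance(tracks, Mapping):
        by_class = {str(k): v for k, v in tracks.items()}
    else:
        by_class = {t.element_class: t for t in tracks}
    missing = [c for c in definition.member_classes if c not in by_class]
    if missing:
        raise ConfigurationError(
            f"index {definition.name}: missing member classes {missing}"
        )
    members = [by_class[c] for c in definition.member_classes]
    chroms = np.concatenate([t.chroms for t in members]) if members else np.array([])
    starts = np.concatenate([t.starts for t in members]) if members else np.array([])
    ends = np.concatenate([t.ends for t in members]) if members else np.array([])
    pooled = IntervalTrack(definition.name, chroms, starts, ends)
    return pooled.merge()


def patient_index_values(
    cohort: Iterable[BreakpointCatalog],
    index_track: IntervalTrack,
    genome: Genome,
) -> pd.Series:
    """One index Hscore per sample (per-patient Pu from the sample's TBPc).

    Per-patient index values use raw (unadjusted) tail probabilities: each
    index is a single test per patient. Samples with no breakpoints are
    excluded with a warning. Returns a float Series indexed by sample_id.
    """
    merged = index_track.merge()
    values: dict[str, float] = {}
    for cat in cohort:
        if cat.tbpc == 0:
            warnings.warn(
                f"sample {cat.sample_id} has TBPc = 0; excluded from "
                f"{index_track.element_class}", stacklevel=2,
            )
            continue
        res = hscore_for_track(cat, merged, genome, n_total=cat.tbpc)
        values[cat.sample_id] = res.hscore
    return pd.Series(values, name=index_track.element_class, dtype=float)
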