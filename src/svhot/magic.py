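"""MAGIC: the mixed transcription-/replication-associated risk classifier.

Metastatic risk follows a lambda shape in both instability indexes: the
*medium* groups carry the worst outcome. MAGIC therefore calls a patient
High-risk exactly when either the iTRAC or the iRACIN three-group label is
Medium, and Low-risk otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ipart import HazardEstimate, PartitionResult, hazard_ratios
from .survival import SurvivalRecord

log = logging.getLogger(__name__)

GROUPS_3 = ("Low", "Medium", "High")


@dataclass(frozen=True)
class MagicLabel:
    sample_id: str
    risk: str | None              # "High" / "Low"; None when a group is missing
    itrac_group: str | None
    iracin_group: str | None


def magic_label(
    itrac_group: str | None, iracin_group: str | None, sample_id: str = ""
) -> MagicLabel:
    """Risk = High iff either index group is Medium; missing group -> NA."""
    if itrac_group is None or iracin_group is None:
        warnings.warn(
            f"sample {sample_id or '?'}: missing index group; MAGIC risk NA",
            stacklevel=2,
        )
        return MagicLabel(sample_id, None, itrac_group, iracin_group)
    for name, g in (("iTRAC", itrac_group), ("iRACIN", iracin_group)):
        if g not in GROUPS_3:
            raise ValueError(f"{name} group must be one of {GROUPS_3}, got {g!r}")
    risk = "High" if "Medium" in (itrac_group, iracin_group) else "Low"
    return MagicLabel(sample_id, risk, itrac_group, iracin_group)


def magic_classify(
    itrac: PartitionResult | Mapping[str, str],
    iracin: PartitionResult | Mapping[str, str],
) -> pd.DataFrame:
    """Combine two three-group labelings into MAGIC risk calls.

    Samples lacking either index label are excluded (logged count).
    Columns: itrac_group, iracin_group, magic_risk; index = sample_id.
    """
    lab_t = itrac.labels if isinstance(itrac, PartitionResult) else dict(itrac)
    lab_r = iracin.labels if isinstance(iracin, PartitionResult) else dict(iracin)
    common = [s for s in lab_t if s in lab_r]
    skipped = len(set(lab_t) | set(lab_r)) - len(common)
    if skipped:
        log.info("MAGIC: %d sample(s) lack one of the two index labels; excluded",
                 skipped)
    rows = [magic_label(lab_t[s], lab_r[s], s) for s in common]
    return pd.DataFrame(
        {
            "itrac_group": [r.itrac_group for r in rows],
            "iracin_group": [r.iracin_group for r in rows],
            "magic_risk": [r.risk for r in rows],
        },
        index=pd.Index(common, name="sample_id"),
    )


def treatment_stratified_survival(
    labels: Mapping[str, str],
    survival: Iterable[SurvivalRecord],
    reference: str = "no",
) -> pd.DataFrame:
    """Treated-vs-untreated hazard ratio within each risk/index group.

    Treatment flags come from the survival records; samples with NA
    treatment are excluded. A stratum with fewer than 2 samples per arm or
    zero events is flagged and gets no estimate.
    """
    survival = [r for r in survival if r.sample_id in labels]
    rows = []
    for group in sorted(set(labels.values()), key=str):
        members = [r for r in survival if labels[r.sample_id] == group
                   and r.treatment is not None]
        n_treated = sum(1 for r in members if r.treatment == "yes")
        n_untreated = len(members) - n_treated
        n_events = sum(r.event for r in members)
        base = {
            "group": group,
            "n_treated": n_treated,
            "n_untreated": n_untreated,
            "n_events": n_events,
        }
        if n_treated < 2 or n_untreated < 2 or n_events == 0:
            rows.append({**base, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "wald_p": np.nan,
                         "flagged": True})
            continue
        treatment_labels = {r.sample_id: r.treatment for r in members}
        try:
            est = hazard_ratios(treatment_labels, members,
                                reference_group=reference)[0]
            rows.append({**base, "hr": est.hr, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "wald_p": est.wald_p,
                         "flagged": est.infinite_ci})
        except (ValueError, IndexError) as exc:
            log.warning("group %s: treated-vs-untreated fit failed (%s)",
                        group, exc)
            rows.append({**base, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "wald_p": np.nan,
                         "flagged": True})
    return pd.DataFrame(rows)
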