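"""Readers and writers for the plain-text formats the toolkit exchanges.

* BED3(+name), tab-separated, 0-based half-open; either one file per
  element class or a 4-column multi-class file (column 4 = class label).
* Breakpoint TSV: sample_id, chrom, pos, sv_id, side, partner_chrom,
  partner_pos (header required).
* Clinical CSV: sample_id, time_years, event, treatment (yes/no/NA).
* Genome TSV: chrom, length (+ optional '#readable_size=' header line).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import BreakpointCatalog, GeneModel, Genome, IntervalTrack
from .survival import SurvivalRecord


def read_bed(path: str | Path, element_class: str | None = None) -> IntervalTrack:
    """Read a single-class BED3(+) file into an IntervalTrack."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    name = element_class or Path(path).stem
    return IntervalTrack(name, df["chrom"].to_numpy(object),
                         df["start"].to_numpy(), df["end"].to_numpy())


def read_multiclass_bed(path: str | Path) -> dict[str, IntervalTrack]:
    """Read a 4-column BED whose name column is the element class."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    return {
        str(cls): IntervalTrack(str(cls), g["chrom"].to_numpy(object),
                                g["start"].to_numpy(), g["end"].to_numpy())
        for cls, g in df.groupby("name", sort=True)
    }


def write_bed(track: IntervalTrack, path: str | Path,
              with_name: bool = False) -> None:
    df = track.to_dataframe()
    if with_name:
        df["name"] = track.element_class
    df.to_csv(path, sep="\t", header=False, index=False)


def read_breakpoints(path: str | Path) -> list[BreakpointCatalog]:
    """Read a cohort breakpoint TSV into per-sample catalogs."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str,
                                            "sv_id": str,
                                            "partner_chrom": str})
    required = {"sample_id", "chrom", "pos", "sv_id", "side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"breakpoint TSV missing columns {sorted(missing)}")
    return [
        BreakpointCatalog(str(sid), g.reset_index(drop=True))
        for sid, g in df.groupby("sample_id", sort=True)
    ]


def write_breakpoints(catalogs: Iterable[BreakpointCatalog],
                      path: str | Path) -> None:
    frames = []
    for cat in catalogs:
        df = cat.frame.copy()
        df.insert(0, "sample_id", cat.sample_id)
        # partner coordinates derived from the paired side of each sv_id
        partner = df.set_index(["sv_id", "side"])[["chrom", "pos"]]
        other = df["side"].map({1: 2, 2: 1})
        keys = pd.MultiIndex.from_arrays([df["sv_id"], other])
        df["partner_chrom"] = partner["chrom"].reindex(keys).to_numpy()
        df["partner_pos"] = partner["pos"].reindex(keys).to_numpy()
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "chrom", "pos", "sv_id", "side",
                 "partner_chrom", "partner_pos"])
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical CSV into survival records (treatment NA -> None)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "time_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        treatment = getattr(row, "treatment", None)
        if isinstance(treatment, float) and np.isnan(treatment):
            treatment = None
        if treatment in ("NA", "", None):
            treatment = None
        records.append(
            SurvivalRecord(
                sample_id=str(row.sample_id),
                time=float(row.time_years),
                event=int(row.event),
                treatment=treatment,
                endpoint=str(getattr(row, "endpoint", "MFS")),
            )
        )
    return records


def write_clinical(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    rows = list(records)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "time_years": [r.time for r in rows],
            "event": [r.event for r in rows],
            "treatment": [r.treatment if r.treatment is not None else "NA"
                          for r in rows],
            "endpoint": [r.endpoint for r in rows],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_genome(path: str | Path) -> Genome:
    readable = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#readable_size="):
        readable = int(first.strip().split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    return Genome(tuple(zip(df["chrom"], df["length"])), readable)


def write_genome(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#readable_size={genome.readable_size}\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")


def read_gene_model(path: str | Path) -> GeneModel:
    """BED3(+2) gene file; optional columns 4/5 = name, expressed (0/1)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    track = IntervalTrack("genes", df[0].to_numpy(object),
                          df[1].to_numpy(), df[2].to_numpy())
    expressed = (df[4].to_numpy().astype(int).astype(bool)
                 if df.shape[1] >= 5 else None)
    return GeneModel(track, expressed)


def write_gene_model(genes: GeneModel, path: str | Path) -> None:
    df = genes.track.to_dataframe()
    df["name"] = [f"gene{i}" for i in range(len(df))]
    df["expressed"] = genes.expressed.astype(int)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_patient_values(path: str | Path,
                        value_column: str | None = None) -> pd.Series:
    """Per-patient scalar TSV (sample_id + one or more value columns).

    Returns a Series indexed by sample_id; use ``value_column`` to pick a
    column (e.g. an externally supplied CNV-abundance proxy).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("patient value TSV needs a sample_id column")
    cols = [c for c in df.columns if c != "sample_id"]
    col = value_column or cols[0]
    return df.set_index("sample_id")[col].astype(float)


def write_patient_values(values: Mapping[str, float] | pd.Series,
                         path: str | Path, name: str = "value") -> None:
    s = pd.Series(values, name=name)
    s.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6g")
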