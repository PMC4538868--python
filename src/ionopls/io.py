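"""Plain-text file formats: long-form CSV peak tables, GMT pathways, JSON truth.

All formats are diffable text. The ion table is stored as four CSVs in one
directory: ``intensities.csv`` (long form: sample_id, ion_id, intensity —
robust to ragged ion counts per analyte), ``ion_meta.csv``,
``sample_meta.csv`` and ``analyte_meta.csv``. Pathway annotations use the
GMT dialect (pathway, description, tab-separated members). Ground truth
from the synthetic generator round-trips through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ions import (
    ANALYTE_META_COLUMNS,
    ION_META_COLUMNS,
    SAMPLE_META_COLUMNS,
    AlkaneLadder,
    IonPeakTable,
    MetaboliteTable,
)
from .sus_enrichment import PathwayAnnotation

__all__ = [
    "write_ion_table",
    "read_ion_table",
    "write_gmt",
    "read_gmt",
    "write_ground_truth",
    "read_ground_truth",
    "write_alkane_ladder",
    "read_alkane_ladder",
    "write_metabolite_table",
    "read_metabolite_table",
]

_FLOAT = "%.10g"


def write_ion_table(table: IonPeakTable, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    long = table.intensities.stack().rename("intensity").reset_index()
    long.columns = ["sample_id", "ion_id", "intensity"]
    long.to_csv(directory / "intensities.csv", index=False, float_format=_FLOAT)
    table.ion_meta.to_csv(directory / "ion_meta.csv", index_label="ion_id", float_format=_FLOAT)
    table.sample_meta.to_csv(directory / "sample_meta.csv", index_label="sample_id")
    table.analyte_meta.to_csv(directory / "analyte_meta.csv", index_label="analyte", float_format=_FLOAT)
    return directory


def read_ion_table(directory) -> IonPeakTable:
    """Load and cross-validate an ion table written by :func:`write_ion_table`.

    Unknown sample or ion ids, duplicate ids and negative intensities are
    rejected with the offending identifiers named in the error.
    """
    directory = Path(directory)
    long = pd.read_csv(directory / "intensities.csv")
    ion_meta = pd.read_csv(directory / "ion_meta.csv", index_col="ion_id")[ION_META_COLUMNS]
    sample_meta = pd.read_csv(directory / "sample_meta.csv", index_col="sample_id")[SAMPLE_META_COLUMNS]
    analyte_meta = pd.read_csv(directory / "analyte_meta.csv", index_col="analyte")[ANALYTE_META_COLUMNS]
    extra_samples = set(long["sample_id"]) - set(sample_meta.index)
    if extra_samples:
        raise ValueError(f"unknown sample ids in intensities: {sorted(extra_samples)}")
    extra_ions = set(long["ion_id"]) - set(ion_meta.index)
    if extra_ions:
        raise ValueError(f"unknown ion ids in intensities: {sorted(extra_ions)}")
    dup = long.duplicated(["sample_id", "ion_id"])
    if dup.any():
        pairs = long.loc[dup, ["sample_id", "ion_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, ion) entries, first: {pairs}")
    wide = long.pivot(index="sample_id", columns="ion_id", values="intensity")
    if wide.isna().any().any():
        raise ValueError("intensity table is ragged: missing (sample, ion) entries")
    # preserve metadata ordering
    wide = wide.reindex(index=[s for s in sample_meta.index if s in wide.index],
                        columns=[i for i in ion_meta.index if i in wide.columns])
    return IonPeakTable(wide, ion_meta, sample_meta, analyte_meta)


def write_metabolite_table(table: MetaboliteTable, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.abundances.to_csv(directory / "abundances.csv", index_label="sample_id", float_format=_FLOAT)
    table.sample_meta.to_csv(directory / "sample_meta.csv", index_label="sample_id")
    meta = pd.DataFrame({"identified": table.identity})
    if table.ri is not None:
        meta["ri"] = table.ri
    meta.to_csv(directory / "metabolite_meta.csv", index_label="metabolite", float_format=_FLOAT)
    return directory


def read_metabolite_table(directory) -> MetaboliteTable:
    directory = Path(directory)
    ab = pd.read_csv(directory / "abundances.csv", index_col="sample_id")
    sm = pd.read_csv(directory / "sample_meta.csv", index_col="sample_id")
    meta = pd.read_csv(directory / "metabolite_meta.csv", index_col="metabolite")
    ri = meta["ri"] if "ri" in meta else None
    return MetaboliteTable(ab, sm.loc[ab.index], meta["identified"].astype(bool), ri)


def write_gmt(annotation: PathwayAnnotation, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for pw in sorted(annotation.pathways):
            desc = annotation.descriptions.get(pw, "")
            members = "\t".join(sorted(annotation.pathways[pw]))
            fh.write(f"{pw}\t{desc}\t{members}\n")
    return path


def read_gmt(path, universe=None) -> PathwayAnnotation:
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pw, desc, members = parts[0], parts[1], parts[2:]
            pathways[pw] = set(m for m in members if m)
            descriptions[pw] = desc
    return PathwayAnnotation(
        pathways=pathways,
        universe=set(universe) if universe is not None else set(),
        descriptions=descriptions,
    )


def write_ground_truth(truth, path) -> Path:
    from .synthetic import GroundTruth  # noqa: F401  (type reference only)

    payload = {
        "affected": {
            "|".join(pair): [[m, d, e] for m, d, e in entries]
            for pair, entries in truth.affected.items()
        },
        "corrupted_ions": sorted(truth.corrupted_ions),
        "artifact_analytes": sorted(truth.artifact_analytes),
        "dilution": {k: float(v) for k, v in truth.dilution.items()},
        "enriched_pathway": truth.enriched_pathway,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in vars(truth.config).items()},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_ground_truth(path):
    from .synthetic import GroundTruth, TruthConfig

    payload = json.loads(Path(path).read_text())
    cfg_raw = payload["config"]
    cfg = TruthConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg_raw.items()})
    affected = {
        tuple(key.split("|")): [(m, d, float(e)) for m, d, e in entries]
        for key, entries in payload["affected"].items()
    }
    return GroundTruth(
        affected=affected,
        corrupted_ions=set(payload["corrupted_ions"]),
        artifact_analytes=set(payload["artifact_analytes"]),
        dilution=payload["dilution"],
        config=cfg,
        enriched_pathway=payload.get("enriched_pathway"),
    )


def write_alkane_ladder(ladder: AlkaneLadder, path) -> Path:
    df = pd.DataFrame({"carbon": ladder.carbons, "rt": ladder.retention_times})
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT)
    return path


def read_alkane_ladder(path) -> AlkaneLadder:
    df = pd.read_csv(path)
    return AlkaneLadder(df["carbon"].to_numpy(), df["rt"].to_numpy())
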