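"""Plain-text readers and writers for every pipeline artefact.

All tabular formats are CSV/TSV with headers; readers validate schemas
(naming missing columns) and restore the canonical atlas region ordering
regardless of on-disk row/column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .expression import DonorSampleSet, ExpressionMatrix
from .synthetic import SubjectTable

SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex", "tiv")
ATLAS_COLUMNS = ("region_id", "label", "lobe_class", "x", "y", "z")


class SchemaError(ValueError):
    """A file is missing required columns or is otherwise malformed."""


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# -- atlas ------------------------------------------------------------------

def write_atlas_tsv(atlas: RegionAtlas, path) -> None:
    frame = pd.DataFrame(
        {
            "region_id": list(atlas.region_ids),
            "label": list(atlas.labels),
            "lobe_class": list(atlas.lobe_classes),
            "x": atlas.centroids[:, 0],
            "y": atlas.centroids[:, 1],
            "z": atlas.centroids[:, 2],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path) -> RegionAtlas:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ATLAS_COLUMNS, path)
    return RegionAtlas(
        tuple(frame["region_id"].astype(str)),
        tuple(frame["label"].astype(str)),
        tuple(frame["lobe_class"].astype(str)),
        frame[["x", "y", "z"]].to_numpy(dtype=float),
    )


# -- subjects ---------------------------------------------------------------

def write_subjects_csv(subjects: SubjectTable, path) -> None:
    out = subjects.covariates.reset_index()
    out = pd.concat([out, subjects.volumes.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


def read_subjects_csv(path, atlas: RegionAtlas) -> SubjectTable:
    frame = pd.read_csv(path)
    _require_columns(frame, SUBJECT_COLUMNS, path)
    missing_regions = [r for r in atlas.region_ids if r not in frame.columns]
    if missing_regions:
        raise SchemaError(f"{path}: missing region column(s) {missing_regions[:5]}")
    frame = frame.set_index("subject_id")
    covariates = frame[["group", "age", "sex", "tiv"]].copy()
    volumes = frame[list(atlas.region_ids)].astype(float)  # canonical order
    return SubjectTable(covariates, volumes, atlas)


# -- expression -------------------------------------------------------------

def write_expression_csv(expression: ExpressionMatrix, path) -> None:
    expression.to_frame().rename_axis("region_id").to_csv(path)


def read_expression_csv(path, atlas: RegionAtlas) -> ExpressionMatrix:
    frame = pd.read_csv(path, index_col=0)
    missing = [r for r in atlas.region_ids if r not in frame.index]
    if missing:
        raise SchemaError(f"{path}: missing region row(s) {missing[:5]}")
    frame = frame.loc[list(atlas.region_ids)]  # restore canonical order
    return ExpressionMatrix(
        atlas, tuple(frame.columns), frame.to_numpy(dtype=float)
    )


# -- donor bundles ----------------------------------------------------------

def write_donor_bundle(donors: Sequence[DonorSampleSet], directory) -> None:
    """One sub-directory per donor: samples.csv, probes.csv, intensities.csv,
    background.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for d in donors:
        ddir = directory / d.donor_id
        ddir.mkdir(exist_ok=True)
        pd.DataFrame(
            d.sample_coords, columns=["x", "y", "z"]
        ).rename_axis("sample").to_csv(ddir / "samples.csv")
        pd.DataFrame(
            {"probe_id": list(d.probe_ids), "gene": [d.probe_map[p] for p in d.probe_ids]}
        ).to_csv(ddir / "probes.csv", index=False)
        pd.DataFrame(d.intensities, index=list(d.probe_ids)).rename_axis(
            "probe_id"
        ).to_csv(ddir / "intensities.csv")
        pd.DataFrame(d.background, index=list(d.probe_ids)).rename_axis(
            "probe_id"
        ).to_csv(ddir / "background.csv")


def read_donor_bundle(directory) -> list[DonorSampleSet]:
    directory = Path(directory)
    donors = []
    for ddir in sorted(p for p in directory.iterdir() if p.is_dir()):
        samples = pd.read_csv(ddir / "samples.csv", index_col=0)
        _require_columns(samples, ("x", "y", "z"), ddir / "samples.csv")
        probes = pd.read_csv(ddir / "probes.csv")
        _require_columns(probes, ("probe_id", "gene"), ddir / "probes.csv")
        intens = pd.read_csv(ddir / "intensities.csv", index_col=0)
        bg = pd.read_csv(ddir / "background.csv", index_col=0)
        probe_ids = tuple(probes["probe_id"].astype(str))
        donors.append(
            DonorSampleSet(
                donor_id=ddir.name,
                sample_coords=samples[["x", "y", "z"]].to_numpy(dtype=float),
                probe_ids=probe_ids,
                intensities=intens.loc[list(probe_ids)].to_numpy(dtype=float),
                background=bg.loc[list(probe_ids)].to_numpy(dtype=float),
                probe_map=dict(zip(probe_ids, probes["gene"].astype(str))),
            )
        )
    if not donors:
        raise SchemaError(f"{directory}: no donor sub-directories found")
    return donors


# -- results ----------------------------------------------------------------

def write_results_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
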