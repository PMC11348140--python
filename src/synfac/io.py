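"""Tab-separated readers/writers for the pipeline's on-disk interchange.

All tables are TSV with headers; matrices carry region ids as both header
and index so shape and ordering mismatches are detectable on load.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .infodynamics import RegionalTimeSeries
from .synthdata import Parcellation, PlantedTruth


def write_timeseries(directory, series: list[RegionalTimeSeries]):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ts in series:
        pd.DataFrame(ts.data).to_csv(
            directory / f"{ts.subject_id}_ts.tsv", sep="\t", index=False
        )


def read_timeseries(directory, dt: float = 2.0) -> list[RegionalTimeSeries]:
    directory = Path(directory)
    out = []
    for path in sorted(directory.glob("sub-*_ts.tsv")):
        sid = path.name.replace("_ts.tsv", "")
        data = pd.read_csv(path, sep="\t").to_numpy(float)
        out.append(RegionalTimeSeries(subject_id=sid, data=data, dt=dt))
    return out


def write_parcellation(path, parc: Parcellation):
    parc.to_frame().to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path, sep="\t"))


def write_matrix(path, mat: np.ndarray, ids=None):
    n = mat.shape[0]
    ids = list(range(n)) if ids is None else list(ids)
    pd.DataFrame(mat, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SchemaError(f"{path}: matrix is not square ({df.shape})")
    return df.to_numpy(float)


def write_truth(path, truth: PlantedTruth):
    payload = {
        "factor_patterns": truth.factor_patterns.tolist(),
        "loadings": truth.loadings.tolist(),
        "clinical_weights": truth.clinical_weights.tolist(),
        "risk_gene_index": truth.risk_gene_index,
        "factor_blocks": truth.factor_blocks,
        "attenuation_weights": (
            truth.attenuation_weights.tolist()
            if truth.attenuation_weights is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        factor_patterns=np.asarray(payload["factor_patterns"]),
        loadings=np.asarray(payload["loadings"]),
        clinical_weights=np.asarray(payload["clinical_weights"]),
        risk_gene_index={int(k): v for k, v in payload["risk_gene_index"].items()},
        factor_blocks=payload["factor_blocks"],
        attenuation_weights=(
            np.asarray(payload["attenuation_weights"])
            if payload["attenuation_weights"] is not None
            else None
        ),
    )


def write_dataset(directory, cohort, series, parc, expression=None, sc=None,
                  myelin=None, gradient=None, truth=None):
    """Write a full synthetic bundle in the documented layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(directory / "participants.tsv", sep="\t", index=False)
    write_parcellation(directory / "parcellation.tsv", parc)
    write_timeseries(directory / "timeseries", series)
    if expression is not None:
        expression.to_csv(directory / "expression.tsv", sep="\t")
    if sc is not None:
        write_matrix(directory / "sc.tsv", sc, parc.region_id)
    if myelin is not None:
        pd.DataFrame({"region_id": parc.region_id, "myelin": myelin}).to_csv(
            directory / "myelin.tsv", sep="\t", index=False
        )
    if gradient is not None:
        pd.DataFrame({"region_id": parc.region_id, "gradient": gradient}).to_csv(
            directory / "gradient.tsv", sep="\t", index=False
        )
    if truth is not None:
        write_truth(directory / "truth.json", truth)
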