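"""Plain-text serialization dialects for every pipeline artifact.

All formats are tab-delimited text (with ``#``-prefixed metadata headers
where needed) so any stage can be run independently on files: spectra,
spectral-model fits, electrode tables, geometry (points + distance
matrix), parcel maps, null-map ensembles (matrix + JSON sidecar),
expression matrices, ontology annotations, and long-format epoch tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AgingMatrix, EpochRecord
from .projection import ElectrodeSet, ParcelMap, SurfaceGeometry
from .spatial import NullMapEnsemble
from .spectra import PowerSpectrum, TimeSeries
from .specparam import SpectralFitResult
from .transcriptomics import ExpressionMatrix, GeneAnnotation

SEP = "\t"


# -- time series -----------------------------------------------------------

def write_timeseries(ts: TimeSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs = {ts.fs}\n")
        fh.write("value\n")
        for v in ts.samples:
            fh.write(f"{v:.9g}\n")


def read_timeseries(path) -> TimeSeries:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError("time-series file must start with a '# fs = ...' line")
    fs = float(header.partition("=")[2])
    df = pd.read_csv(path, sep=SEP, skiprows=1)
    return TimeSeries(df["value"].to_numpy(), fs)


# -- spectra ---------------------------------------------------------------

def write_spectrum(psd: PowerSpectrum, path) -> None:
    with open(path, "w") as fh:
        for key, val in {"n_segments": psd.n_segments, **psd.meta}.items():
            fh.write(f"# {key} = {val}\n")
        fh.write(f"frequency_hz{SEP}power\n")
        for f, p in zip(psd.freqs, psd.power):
            fh.write(f"{f:.12g}{SEP}{p:.12g}\n")


def read_spectrum(path) -> PowerSpectrum:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(path, sep=SEP, skiprows=body_start)
    n_segments = int(meta.pop("n_segments", 1))
    return PowerSpectrum(df["frequency_hz"].to_numpy(), df["power"].to_numpy(),
                         n_segments=n_segments, meta=meta)


def write_fit_result(res: SpectralFitResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("[aperiodic]\n")
        fh.write(f"offset{SEP}knee{SEP}exponent\n")
        ap = res.aperiodic
        fh.write(f"{ap.offset:.12g}{SEP}{ap.knee:.12g}{SEP}{ap.exponent:.12g}\n")
        fh.write("[peaks]\n")
        fh.write(f"center{SEP}height{SEP}bandwidth\n")
        for p in res.peaks:
            fh.write(f"{p.center:.12g}{SEP}{p.height:.12g}{SEP}{p.bandwidth:.12g}\n")
        fh.write("[goodness]\n")
        fh.write(f"rmse{SEP}r_squared{SEP}converged{SEP}fk_hz{SEP}tau_s\n")
        fh.write(
            f"{res.rmse:.12g}{SEP}{res.r_squared:.12g}{SEP}{int(res.converged)}"
            f"{SEP}{res.knee_frequency:.12g}{SEP}{res.tau:.12g}\n"
        )


# -- electrodes & geometry -------------------------------------------------

def write_electrodes(sets: list[ElectrodeSet], path) -> None:
    rows = []
    for es in sets:
        for pos, val in zip(es.positions, es.values):
            rows.append({"subject_id": es.subject_id, "x_mm": pos[0],
                         "y_mm": pos[1], "z_mm": pos[2], "value": val})
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_electrodes(path) -> list[ElectrodeSet]:
    df = pd.read_csv(path, sep=SEP)
    required = {"subject_id", "x_mm", "y_mm", "z_mm", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"electrode table missing columns: {sorted(missing)}")
    out = []
    for sid, sub in df.groupby("subject_id", sort=True):
        out.append(ElectrodeSet(str(sid), sub[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                                sub["value"].to_numpy()))
    return out


def write_geometry(geom: SurfaceGeometry, points_path, dist_path) -> None:
    pts = pd.DataFrame(geom.points, columns=["x", "y", "z"])
    pts.insert(0, "point_id", [f"pt{i}" for i in range(len(pts))])
    pts["parcel_id"] = np.asarray(geom.parcel_ids)[geom.point_parcels]
    pts.to_csv(points_path, sep=SEP, index=False)
    dm = pd.DataFrame(geom.parcel_distance, index=geom.parcel_ids,
                      columns=geom.parcel_ids)
    dm.to_csv(dist_path, sep=SEP, index_label="parcel_id")


def read_geometry(points_path, dist_path) -> SurfaceGeometry:
    pts = pd.read_csv(points_path, sep=SEP)
    dm = pd.read_csv(dist_path, sep=SEP, index_col=0)
    parcel_ids = dm.index.to_numpy()
    lookup = {pid: i for i, pid in enumerate(parcel_ids)}
    point_parcels = pts["parcel_id"].map(lookup)
    if point_parcels.isna().any():
        raise ValueError("points reference parcels absent from the distance matrix")
    return SurfaceGeometry(parcel_ids, pts[["x", "y", "z"]].to_numpy(),
                           point_parcels.to_numpy(int), dm.to_numpy())


# -- parcel maps & nulls ---------------------------------------------------

def write_parcel_map(m: ParcelMap, path) -> None:
    pd.DataFrame(
        {"parcel_id": m.parcel_ids, "value": m.values,
         "confidence": m.confidence, "valid": m.valid_mask.astype(int)}
    ).to_csv(path, sep=SEP, index=False)


def read_parcel_map(path, confidence_floor: float = 0.5) -> ParcelMap:
    df = pd.read_csv(path, sep=SEP)
    return ParcelMap(df["parcel_id"].to_numpy(), df["value"].to_numpy(),
                     df["confidence"].to_numpy(), confidence_floor=confidence_floor)


def write_null_ensemble(ens: NullMapEnsemble, matrix_path, sidecar_path) -> None:
    np.savetxt(matrix_path, ens.nulls, delimiter=SEP)
    with open(sidecar_path, "w") as fh:
        json.dump({"source_map_id": ens.source_map_id, "seed": int(ens.seed),
                   "method": ens.method, "n_null": int(ens.n_null)}, fh, indent=1)


def read_null_ensemble(matrix_path, sidecar_path) -> NullMapEnsemble:
    nulls = np.atleast_2d(np.loadtxt(matrix_path, delimiter=SEP))
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return NullMapEnsemble(nulls=nulls, source_map_id=meta["source_map_id"],
                           seed=meta["seed"], method=meta["method"])


# -- expression & annotation ----------------------------------------------

def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.X, columns=[f"parcel{i}" for i in range(expr.n_parcels)])
    df.insert(0, "gene_id", expr.gene_ids)
    df.to_csv(path, sep=SEP, index=False)


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=SEP)
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicated gene id in expression table")
    return ExpressionMatrix(df.drop(columns="gene_id").to_numpy(),
                            df["gene_id"].to_numpy())


def write_annotation(ann: GeneAnnotation, pairs_path, meta_path) -> None:
    rows = [{"term_id": t, "gene_id": g}
            for t, genes in sorted(ann.term_genes.items()) for g in sorted(genes)]
    pd.DataFrame(rows).to_csv(pairs_path, sep=SEP, index=False)
    meta = [{"term_id": t, "name": nm, "namespace": ns}
            for t, (nm, ns) in sorted(ann.term_meta.items())]
    pd.DataFrame(meta).to_csv(meta_path, sep=SEP, index=False)


def read_annotation(pairs_path, meta_path) -> GeneAnnotation:
    pairs = pd.read_csv(pairs_path, sep=SEP)
    meta = pd.read_csv(meta_path, sep=SEP)
    term_genes: dict = {}
    for t, g in zip(pairs["term_id"], pairs["gene_id"]):
        term_genes.setdefault(t, set()).add(g)
    term_meta = {t: (nm, ns) for t, nm, ns in
                 zip(meta["term_id"], meta["name"], meta["namespace"])}
    return GeneAnnotation(term_genes, term_meta)


# -- epochs ----------------------------------------------------------------

def write_epochs(records: list[EpochRecord], path) -> None:
    """Long-format epoch table: one row per sample with fs in a header line."""
    with open(path, "w") as fh:
        fs = records[0].ts.fs if records else 0
        fh.write(f"# fs = {fs}\n")
        fh.write(SEP.join(["subject_id", "region", "channel_id", "period",
                           "trial_id", "sample_index", "value"]) + "\n")
        for r in records:
            for i, v in enumerate(r.ts.samples):
                fh.write(f"{r.subject_id}{SEP}{r.region}{SEP}{r.channel_id}{SEP}"
                         f"{r.period}{SEP}{r.trial_id}{SEP}{i}{SEP}{v:.9g}\n")


def read_epochs(path) -> list[EpochRecord]:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError("epoch table must start with a '# fs = ...' line")
    fs = float(header.partition("=")[2])
    df = pd.read_csv(path, sep=SEP, skiprows=1)
    out = []
    keys = ["subject_id", "region", "channel_id", "period", "trial_id"]
    for key, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("sample_index")
        out.append(EpochRecord(str(key[0]), key[1], str(key[2]), key[3],
                               int(key[4]), TimeSeries(sub["value"].to_numpy(), fs)))
    return out


def write_aging_matrix(matrix: AgingMatrix, values_path, ages_path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.subject_ids,
                      columns=matrix.parcel_ids)
    df.to_csv(values_path, sep=SEP, index_label="subject_id")
    pd.DataFrame({"subject_id": matrix.subject_ids, "age": matrix.ages}).to_csv(
        ages_path, sep=SEP, index=False)


def read_aging_matrix(values_path, ages_path) -> AgingMatrix:
    df = pd.read_csv(values_path, sep=SEP, index_col=0)
    ages = pd.read_csv(ages_path, sep=SEP).set_index("subject_id")["age"]
    ages = ages.reindex(df.index)
    if ages.isna().any():
        raise ValueError("ages missing for some subjects")
    return AgingMatrix(df.to_numpy(), ages.to_numpy(),
                       subject_ids=df.index.to_numpy(),
                       parcel_ids=df.columns.to_numpy())
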