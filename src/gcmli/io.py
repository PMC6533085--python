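"""Readers/writers for sweep containers, rasters, feature tables and reports.

Formats
-------
* Sweep container: HDF5, one group per synapse holding ``time_base`` (ms),
  ``currents`` (n_trains x n_samples, pA), ``stimulus_times`` (ms) and
  metadata attributes; plus an equivalent delimited-text export (one time
  column, one column per train).
* Ground-truth manifest: CSV (synapse_id, class_label, genotype, every
  synapse parameter, seed).
* Rasters: plain text, one whitespace-separated line of spike times (ms) per
  repeat; empty lines are empty repeats.
* Morphometry: long CSV (synapse_id, genotype, az_length_nm, distance_nm),
  one row per vesicle.
* Reports: JSON with sorted keys (byte-reproducible given equal inputs).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .classify import ProfileMatrix
from .features import EPSCTrainFeatures
from .morphometry import SynapseProfile
from .synth import (GroundTruthCohort, QuantalSynapseParams, SimulatedSweep,
                    StimulusProtocol, SynapseRecord)

__all__ = [
    "write_sweep_container",
    "read_sweep_container",
    "export_sweeps_tsv",
    "write_manifest_csv",
    "read_manifest_csv",
    "features_to_frame",
    "write_features_csv",
    "read_profile_matrix_csv",
    "write_profile_matrix_csv",
    "write_rasters",
    "read_rasters",
    "write_morphometry_csv",
    "read_morphometry_csv",
    "write_json_report",
]


def write_sweep_container(path, cohort: GroundTruthCohort) -> None:
    """Write a cohort's sweeps to an HDF5 container (deterministic bytes)."""
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["protocol"] = json.dumps(asdict(cohort.protocol), sort_keys=True)
        for rec in cohort.synapses:
            g = f.create_group(rec.synapse_id)
            g.attrs["class_label"] = rec.class_label
            g.attrs["genotype"] = rec.genotype
            g.attrs["params"] = rec.params.to_json()
            sw0 = rec.sweeps[0]
            g.create_dataset("time_base", data=sw0.time_base,
                             track_times=False)
            g.create_dataset("stimulus_times", data=sw0.stimulus_times,
                             track_times=False)
            currents = np.stack([s.current for s in rec.sweeps])
            g.create_dataset("currents", data=currents, track_times=False)
            quanta = np.stack([s.truth_quanta for s in rec.sweeps])
            g.create_dataset("truth_quanta", data=quanta, track_times=False)
            g.attrs["sampling_rate"] = sw0.sampling_rate


def read_sweep_container(path) -> GroundTruthCohort:
    """Read a cohort back from an HDF5 sweep container."""
    path = Path(path)
    synapses: list[SynapseRecord] = []
    with h5py.File(path, "r") as f:
        protocol = StimulusProtocol(**json.loads(f.attrs["protocol"]))
        seed = int(f.attrs["seed"])
        for sid in f:
            g = f[sid]
            for key in ("time_base", "currents", "stimulus_times"):
                if key not in g:
                    raise ValueError(f"synapse {sid!r}: missing field {key!r}")
            params = QuantalSynapseParams.from_json(g.attrs["params"])
            time_base = g["time_base"][()]
            stim = g["stimulus_times"][()]
            currents = g["currents"][()]
            quanta = g["truth_quanta"][()]
            fs = float(g.attrs["sampling_rate"])
            sweeps = [SimulatedSweep(time_base=time_base, current=currents[i],
                                     stimulus_times=stim,
                                     truth_quanta=quanta[i],
                                     sampling_rate=fs, params_id=sid)
                      for i in range(currents.shape[0])]
            synapses.append(SynapseRecord(sid, params,
                                          str(g.attrs["class_label"]),
                                          str(g.attrs["genotype"]), sweeps))
    return GroundTruthCohort(synapses=synapses, protocol=protocol, seed=seed)


def export_sweeps_tsv(record: SynapseRecord, path) -> None:
    """Delimited-text export: a time column plus one current column per train."""
    cols = {"time_ms": record.sweeps[0].time_base}
    for i, sw in enumerate(record.sweeps):
        cols[f"train_{i:02d}_pA"] = sw.current
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_manifest_csv(cohort: GroundTruthCohort, path) -> None:
    rows = []
    for rec in cohort.synapses:
        row = {"synapse_id": rec.synapse_id, "class_label": rec.class_label,
               "genotype": rec.genotype, "seed": cohort.seed}
        row.update(asdict(rec.params))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"synapse_id", "class_label", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing fields: {sorted(missing)}")
    return df


def features_to_frame(features_by_id: dict[str, EPSCTrainFeatures],
                      qc_codes: dict[str, tuple[str, ...]] | None = None
                      ) -> pd.DataFrame:
    """Long per-synapse feature table (one row per stimulus index)."""
    qc_codes = qc_codes or {}
    rows = []
    for sid, feats in features_by_id.items():
        codes = ";".join(qc_codes.get(sid, ()))
        for j in range(feats.n_stimuli):
            rows.append({
                "synapse_id": sid,
                "stimulus_index": j + 1,
                "mean_charge_fC": feats.mean_charges[j],
                "median_charge_fC": feats.median_charges[j],
                "failure_rate": feats.failure_rate[j],
                "ppr": feats.ppr,
                "success_rate_1": feats.success_rate_1,
                "qc_codes": codes,
            })
    return pd.DataFrame(rows)


def write_features_csv(features_by_id, path, qc_codes=None) -> None:
    features_to_frame(features_by_id, qc_codes).to_csv(
        path, index=False, float_format="%.8g")


def write_profile_matrix_csv(matrix: ProfileMatrix, path) -> None:
    n = matrix.values.shape[1]
    df = pd.DataFrame(matrix.values,
                      columns=[f"charge_{j + 1:02d}" for j in range(n)])
    df.insert(0, "synapse_id", matrix.ids)
    df.insert(1, "cohort", matrix.cohort)
    df.to_csv(path, index=False, float_format="%.8g")


def read_profile_matrix_csv(path) -> ProfileMatrix:
    df = pd.read_csv(path)
    if "synapse_id" not in df.columns:
        raise ValueError("profile CSV missing field 'synapse_id'")
    charge_cols = [c for c in df.columns if c.startswith("charge_")]
    if not charge_cols:
        raise ValueError("profile CSV has no charge_* columns")
    cohort = str(df["cohort"].iloc[0]) if "cohort" in df.columns else "reference"
    return ProfileMatrix(df[charge_cols].to_numpy(float),
                         ids=[str(s) for s in df["synapse_id"]],
                         cohort=cohort)


def write_rasters(rasters: list[np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for spikes in rasters:
            fh.write(" ".join(f"{t:.4f}" for t in np.asarray(spikes)) + "\n")


def read_rasters(path) -> list[np.ndarray]:
    rasters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            try:
                rasters.append(np.array([float(x) for x in line.split()])
                               if line else np.empty(0))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return rasters


def write_morphometry_csv(profiles: list[SynapseProfile], path) -> None:
    rows = []
    for p in profiles:
        if p.vesicle_distances.size == 0:
            rows.append({"synapse_id": p.synapse_id, "genotype": p.genotype,
                         "az_length_nm": p.az_length, "distance_nm": np.nan})
        for d in p.vesicle_distances:
            rows.append({"synapse_id": p.synapse_id, "genotype": p.genotype,
                         "az_length_nm": p.az_length, "distance_nm": d})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_morphometry_csv(path) -> list[SynapseProfile]:
    df = pd.read_csv(path)
    required = {"synapse_id", "genotype", "az_length_nm", "distance_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphometry CSV missing fields: {sorted(missing)}")
    profiles = []
    for sid, grp in df.groupby("synapse_id", sort=False):
        dist = grp["distance_nm"].dropna().to_numpy(float)
        profiles.append(SynapseProfile(
            synapse_id=str(sid), az_length=float(grp["az_length_nm"].iloc[0]),
            vesicle_distances=dist, genotype=str(grp["genotype"].iloc[0])))
    return profiles


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
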