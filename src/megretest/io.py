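"""Delimited-text and JSON artifact round-trips.

Connectivity matrices are tab-separated with an ROI-label header row and
column and a NaN sentinel on the diagonal; spectra are two-column
(freq_hz, normalized_power); the consistency table is tidy TSV; run reports
are JSON with a per-file sha256 manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .spectral import PowerSpectrum


class ParseError(ValueError):
    pass


def write_matrix(path, mat: ConnectivityMatrix, labels: list[str]) -> None:
    n = len(mat.values)
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# band=%g-%g Hz n_epochs=%d unit=AEC-c\n"
                 % (mat.band[0], mat.band[1], mat.n_epochs))
        fh.write("roi\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, mat.values):
            fh.write(lab + "\t" + "\t".join("%.17g" % v for v in row) + "\n")


def read_matrix(path) -> tuple[ConnectivityMatrix, list[str]]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# band="):
        raise ParseError(f"{path}:1: missing band header")
    meta = lines[0][2:].split()
    lo, hi = (float(v) for v in meta[0].split("=")[1].split("-"))
    n_epochs = int(meta[2].split("=")[1])
    if len(lines) < 2 or not lines[1].startswith("roi\t"):
        raise ParseError(f"{path}:2: missing ROI header row")
    labels = lines[1].rstrip("\n").split("\t")[1:]
    values = np.empty((len(labels), len(labels)))
    for i, line in enumerate(lines[2:]):
        parts = line.split("\t")
        if len(parts) != len(labels) + 1:
            raise ParseError(f"{path}:{i + 3}: expected {len(labels) + 1} "
                             f"columns, got {len(parts)}")
        values[i] = [float(v) for v in parts[1:]]
    mat = ConnectivityMatrix(values=values, band=(lo, hi), n_epochs=n_epochs)
    return mat, labels


def write_spectrum(path, spec: PowerSpectrum) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# band=%g-%g Hz n_epochs=%d n_rois=%d\n"
                 % (spec.band[0], spec.band[1], spec.n_epochs, spec.n_rois))
        fh.write("freq_hz\tnormalized_power\n")
        for f, p in zip(spec.freqs, spec.power):
            fh.write("%.17g\t%.17g\n" % (f, p))


def read_spectrum(path) -> PowerSpectrum:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# band="):
        raise ParseError(f"{path}:1: missing band header")
    meta = lines[0][2:].split()
    lo, hi = (float(v) for v in meta[0].split("=")[1].split("-"))
    n_epochs = int(meta[2].split("=")[1])
    n_rois = int(meta[3].split("=")[1])
    if len(lines) < 2 or lines[1] != "freq_hz\tnormalized_power":
        raise ParseError(f"{path}:2: missing column header row")
    rows = [tuple(float(v) for v in ln.split("\t")) for ln in lines[2:]]
    arr = np.array(rows)
    return PowerSpectrum(freqs=arr[:, 0], power=arr[:, 1], band=(lo, hi),
                         n_epochs=n_epochs, n_rois=n_rois)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_session_dir(outdir, rec, fingerprint_meta: dict) -> None:
    """Cohort external format: sensor data as .npy (channels x samples),
    geometry as TSV, head model + provenance as a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "sensors.npy", rec.data)
    arr = rec.array
    with (outdir / "geometry.tsv").open("w") as fh:
        fh.write("channel\tkind\tbaseline_m\t"
                 "c1x\tc1y\tc1z\tn1x\tn1y\tn1z\t"
                 "c2x\tc2y\tc2z\tn2x\tn2y\tn2z\n")
        for ch in range(arr.n_channels):
            p, o = arr.coil_positions[ch], arr.coil_orientations[ch]
            vals = [*p[0], *o[0], *p[1], *o[1]]
            fh.write(arr.channel_id[ch] + "\t" + str(arr.kind[ch]) + "\t"
                     + "%.6g" % arr.baseline[ch] + "\t"
                     + "\t".join("%.9g" % v for v in vals) + "\n")
    sidecar = dict(rate_hz=rec.rate, system=rec.system,
                   sphere_center=rec.head.sphere_center.tolist(),
                   sphere_radius=rec.head.sphere_radius,
                   **fingerprint_meta)
    write_report(outdir / "session.json", sidecar)
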