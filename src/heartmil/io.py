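"""WAV and cohort-layout I/O.

Recordings are stored in the CirCor DigiScope convention: one 16-bit PCM WAV
per auscultation location (``<patient>_<LOC>.wav``), a matching three-column
segmentation TSV (``<patient>_<LOC>.tsv``) and one ``<patient>.txt`` carrying
demographics and patient-level labels.
"""

from __future__ import annotations

import os

import numpy as np
from scipy.io import wavfile

from .segmentation import PhaseSegmentation, read_segmentation_tsv, write_segmentation_tsv

_PCM16 = 32767


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV as float samples in [-1, 1] plus the sampling rate."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = max(abs(info.min), info.max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return samples, float(rate)


def write_wav(path, samples: np.ndarray, rate: float) -> None:
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, int(rate), (x * _PCM16).astype(np.int16))


def write_patient(outdir, patient) -> None:
    """Write one patient in the CirCor-style layout."""
    os.makedirs(outdir, exist_ok=True)
    pid = patient.patient_id
    locs = []
    for rec in patient.recordings:
        locs.append(rec.location)
        base = os.path.join(outdir, f"{pid}_{rec.location}")
        write_wav(base + ".wav", rec.samples, rec.sampling_rate)
        write_segmentation_tsv(base + ".tsv", rec.segmentation, rec.sampling_rate)
    demo = patient.demographics
    lines = [
        f"#{pid} {len(patient.recordings)} {int(patient.recordings[0].sampling_rate)}",
        f"Locations: {' '.join(locs)}",
        f"Age: {'' if demo.age_months is None else demo.age_months}",
        f"Sex: {'' if demo.sex is None else demo.sex}",
        f"Weight: {'' if demo.weight_kg is None else demo.weight_kg}",
        f"Height: {'' if demo.height_cm is None else demo.height_cm}",
        f"Murmur: {patient.murmur_label}",
        f"Outcome: {patient.outcome_label}",
    ]
    with open(os.path.join(outdir, f"{pid}.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_cohort(outdir, patients) -> None:
    for patient in patients:
        write_patient(outdir, patient)


def read_patient_metadata(path) -> dict:
    """Parse a ``<patient>.txt`` metadata file into a plain dict."""
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                pid, n_loc, rate = line[1:].split()
                meta.update(patient_id=pid, n_locations=int(n_loc),
                            sampling_rate=float(rate))
            else:
                key, _, value = line.partition(":")
                meta[key.strip().lower()] = value.strip() or None
    if "locations" in meta and meta["locations"]:
        meta["locations"] = meta["locations"].split()
    return meta


def read_recording(base_path) -> tuple[np.ndarray, float, PhaseSegmentation | None]:
    """Read ``<base>.wav`` and, when present, its ``<base>.tsv`` segmentation."""
    samples, rate = read_wav(str(base_path) + ".wav")
    tsv = str(base_path) + ".tsv"
    seg = read_segmentation_tsv(tsv, rate) if os.path.exists(tsv) else None
    return samples, rate, seg
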