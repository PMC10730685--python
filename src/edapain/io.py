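"""Reading and writing delimited skin-conductance recordings.

One subject's recording is a comma-delimited text file with a header row and
two columns: ``time`` (seconds from stream start, strictly increasing) and
``gsr`` (conductance in microsiemens).  A cohort archive is a directory of
such per-subject files plus one ``metadata.csv`` table listing every stimulus
(subject_id, label, onset, file) and a ``protocol.json`` snapshot, so an
archive can be segmented back into the exact training tensor it came from.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig, compute_temperature_stages
from .simulate import (
    Cohort,
    SubjectProfile,
    SubjectStream,
    generate_profiles,
    generate_subject_stream,
    segment_stream,
)

TIME_COLUMN = "time"
SIGNAL_COLUMN = "gsr"
FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """A signal file does not conform to the declared dialect."""


def write_signal_file(path: str | Path, t: np.ndarray, gsr: np.ndarray) -> None:
    """Write one recording as ``time,gsr`` delimited text (6-decimal precision)."""
    t = np.asarray(t, dtype=float)
    gsr = np.asarray(gsr, dtype=float)
    if t.shape != gsr.shape or t.ndim != 1:
        raise FormatError("time and gsr must be equal-length 1-D vectors")
    pd.DataFrame({TIME_COLUMN: t, SIGNAL_COLUMN: gsr}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_signal_file(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one recording; returns (time, gsr).

    Raises FormatError on a missing/empty file body, missing columns, or a
    non-monotone time axis.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty signal file") from exc
    missing = {TIME_COLUMN, SIGNAL_COLUMN} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    gsr = df[SIGNAL_COLUMN].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    return t, gsr


def infer_sampling_rate(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise FormatError("cannot infer sampling rate from a single sample")
    # atol covers the declared 6-decimal write precision of the time column
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=2e-6):
        raise FormatError("time axis is not uniformly sampled")
    # full-span estimate: per-sample write truncation cancels out
    return (len(t) - 1) / float(t[-1] - t[0])


def write_cohort_archive(
    out_dir: str | Path,
    protocol: ProtocolConfig | None = None,
    separation: float = 1.0,
    seed: int = 0,
    n_subjects: int | None = None,
) -> Path:
    """Simulate a cohort and write it as a signal-file archive.

    Streams are written one subject at a time (nothing is held in memory),
    which makes this the natural backend for the ``simulate`` command.
    """
    protocol = protocol or ProtocolConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    profile_ss, subject_root = ss.spawn(2)
    profiles = generate_profiles(protocol, profile_ss)
    if n_subjects is not None:
        profiles = profiles[:n_subjects]
    child_seeds = subject_root.spawn(len(profiles))
    rows = []
    for prof, child in zip(profiles, child_seeds):
        stream = generate_subject_stream(prof, protocol, child, separation)
        fname = f"{prof.subject_id}.csv"
        write_signal_file(out / fname, stream.t, stream.gsr)
        for onset, lab in zip(stream.onsets, stream.labels):
            rows.append(
                {
                    "subject_id": prof.subject_id,
                    "label": int(lab),
                    "onset": float(onset),
                    "file": fname,
                }
            )
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    with open(out / "protocol.json", "w") as fh:
        json.dump(dataclasses.asdict(protocol), fh, indent=2)
    return out


def load_cohort_archive(archive_dir: str | Path, window: float = 5.5) -> Cohort:
    """Segment an on-disk archive back into a Cohort."""
    archive = Path(archive_dir)
    meta_path = archive / "metadata.csv"
    if not meta_path.exists():
        raise FormatError(f"{archive}: missing metadata.csv")
    meta = pd.read_csv(meta_path)
    required = {"subject_id", "label", "onset", "file"}
    if required - set(meta.columns):
        raise FormatError(f"metadata.csv missing columns {sorted(required - set(meta.columns))}")
    proto_path = archive / "protocol.json"
    if proto_path.exists():
        with open(proto_path) as fh:
            raw = json.load(fh)
        raw["interval_range"] = tuple(raw["interval_range"])
        protocol = ProtocolConfig(**raw)
    else:
        protocol = ProtocolConfig()

    segments = []
    subject_ids = list(dict.fromkeys(meta["subject_id"]))
    for sid in subject_ids:
        rows = meta[meta["subject_id"] == sid]
        fname = rows["file"].iloc[0]
        t, gsr = read_signal_file(archive / fname)
        stream = SubjectStream(
            subject_id=sid,
            t=t,
            gsr=gsr,
            onsets=rows["onset"].to_numpy(dtype=float),
            labels=rows["label"].to_numpy(dtype=int),
            sampling_rate=infer_sampling_rate(t),
        )
        segments.extend(segment_stream(stream, window=window))
    # Generator profiles are not recoverable from disk; carry placeholder
    # profiles so the cohort still knows its roster of subject ids.
    placeholder_cal = compute_temperature_stages(42.0, 46.0, protocol.baseline_temp)
    profiles = [
        SubjectProfile(
            subject_id=sid,
            tonic_level=0.0,
            tonic_drift_rate=0.0,
            scr_gain=1.0,
            latency=0.0,
            noise_sd=0.0,
            calibration=placeholder_cal,
        )
        for sid in subject_ids
    ]
    return Cohort(subjects=profiles, segments=segments, protocol=protocol, seed=-1)
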