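"""Reading and writing the columnar recording format.

Recordings travel as CSV with header ``time_s,ca3_mv,ca1_mv`` and an
optional ``i_pa`` column for a companion intracellular current trace.
Writing uses 17 significant digits so a write/read round trip reproduces
the samples bit-exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import IntracellularTrace, Recording

RECORDING_COLUMNS = ["time_s", "ca3_mv", "ca1_mv"]


class SchemaError(ValueError):
    """Malformed recording file (header, ragged rows, bad time axis)."""


def write_recording(recording: Recording, path,
                    intracellular: IntracellularTrace | None = None) -> None:
    n = len(recording.ca3)
    t = np.arange(n) / recording.sampling_rate
    data = {"time_s": t, "ca3_mv": recording.ca3, "ca1_mv": recording.ca1}
    if intracellular is not None:
        if len(intracellular.current) != n:
            raise ValueError("intracellular trace length does not match recording")
        data["i_pa"] = intracellular.current
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_recording(path) -> Recording:
    """Read a recording CSV; validates schema and time axis."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    for col in df.columns:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"{path}: missing value in '{col}' at row {row}")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise SchemaError(
            f"{path}: time column not strictly increasing at row {int(bad[0]) + 1}")
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least 2 samples")
    fs = 1.0 / float(np.median(dt))
    rec = Recording(sampling_rate=fs, duration=len(t) / fs,
                    ca3=df["ca3_mv"].to_numpy(float),
                    ca1=df["ca1_mv"].to_numpy(float),
                    condition=str(path), seed=None)
    if "i_pa" in df.columns:
        rec.metadata["i_pa"] = df["i_pa"].to_numpy(float)
    return rec
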