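"""Reading and writing ECG records, beat segmentation and ensemble averaging.

Records are exchanged either as WFDB-style format-16 records (text ``.hea``
header + little-endian int16 ``.dat`` signal, amplitudes restored to mV with
the per-signal gain/baseline) or as plain CSV with a time column and one
column per lead.  Beat labels travel in a plain-text annotation sidecar
(``.ann``: one ``sample<TAB>label`` line per beat).

Segmentation cuts a fixed physical window around each R peak and linearly
resamples every lead to a common length, which makes cycles commensurable
across heart rates; the per-recording ensemble cycle is the pointwise mean of
all segmented cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ECGRecord",
    "ECGCycle",
    "FormatError",
    "read_record",
    "write_csv",
    "write_wfdb",
    "read_annotations",
    "write_annotations",
    "detect_r_peaks",
    "segment_cycles",
    "ensemble_cycle",
]


class FormatError(ValueError):
    """A record file could not be parsed; the message names the file (and line)."""


@dataclass
class ECGRecord:
    """A raw multi-lead recording in millivolts."""

    record_id: str
    sample_rate: float
    leads: list[str]
    samples: np.ndarray  # (n_leads, n_samples), mV
    annotations: list[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.leads):
            raise ValueError("samples must be (n_leads, n_samples) matching leads")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class ECGCycle:
    """One segmented beat: equal-length windows from every lead."""

    record_id: str
    cycle_index: int
    leads: list[str]
    samples: np.ndarray  # (n_leads, M), mV
    label: str | None = None

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] < 8:
            raise ValueError("cycle must be (n_leads, M) with M >= 8")

    @property
    def length(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# CSV round-trip

def write_csv(record: ECGRecord, path: str | Path) -> None:
    t = np.arange(record.n_samples) / record.sample_rate
    df = pd.DataFrame({"time": t})
    for name, sig in zip(record.leads, record.samples):
        df[name] = sig
    df.to_csv(path, index=False, float_format="%.6f")


def _read_csv(path: Path) -> ECGRecord:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one lead")
    time_col, lead_cols = df.columns[0], list(df.columns[1:])
    for col in lead_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: non-numeric value in column {col!r}, line {line}")
        df[col] = vals
    t = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    if np.isnan(t).any() or len(t) < 2:
        raise FormatError(f"{path}: time column is non-numeric or too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(
        record_id=path.stem,
        sample_rate=fs,
        leads=lead_cols,
        samples=df[lead_cols].to_numpy().T.astype(float),
    )


# ---------------------------------------------------------------------------
# WFDB format 16 (text header + interleaved little-endian int16 signal)

_DEFAULT_GAIN = 1000.0  # ADC units per mV; 16-bit range then spans ±32 mV


def write_wfdb(record: ECGRecord, directory: str | Path, gain: float = _DEFAULT_GAIN) -> Path:
    """Write ``record`` as ``<record_id>.hea`` / ``.dat`` (+ ``.ann`` if annotated).

    Returns the header path.  Amplitudes are quantized to ``round(gain * mV)``
    ADC units, so the round-trip error is at most half a quantization step.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    adc = np.round(record.samples * gain).astype(np.int64)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds the int16 range at this gain")
    adc = adc.astype("<i2")
    interleaved = adc.T.reshape(-1)
    (directory / f"{name}.dat").write_bytes(interleaved.tobytes())

    lines = [f"{name} {len(record.leads)} {record.sample_rate:g} {record.n_samples}"]
    for li, lead in enumerate(record.leads):
        first = int(adc[li, 0])
        checksum = int(np.sum(adc[li], dtype=np.int64) % 65536)
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 {lead}")
    header = directory / f"{name}.hea"
    header.write_text("\n".join(lines) + "\n")
    if record.annotations:
        write_annotations(directory / f"{name}.ann", record.annotations)
    return header


def _read_wfdb(header_path: Path) -> ECGRecord:
    if not header_path.exists():
        raise FormatError(f"{header_path}: header file not found")
    lines = [ln for ln in header_path.read_text().splitlines() if ln and not ln.startswith("#")]
    try:
        rec_name, n_sig, fs, n_samples = lines[0].split()[:4]
        n_sig, fs, n_samples = int(n_sig), float(fs), int(n_samples)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{header_path}: malformed record line 1") from exc
    gains, baselines, leads, dat_files = [], [], [], []
    for i, ln in enumerate(lines[1 : 1 + n_sig], start=2):
        fields = ln.split()
        try:
            dat_files.append(fields[0])
            if fields[1] != "16":
                raise FormatError(f"{header_path}: unsupported signal format {fields[1]} (line {i})")
            gain_field = fields[2].split("/")[0]
            if "(" in gain_field:
                g, b = gain_field.rstrip(")").split("(")
            else:
                g, b = gain_field, "0"
            gains.append(float(g) if float(g) != 0 else _DEFAULT_GAIN)
            baselines.append(float(b))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{header_path}: malformed signal line {i}") from exc
        leads.append(fields[-1] if len(fields) >= 9 else f"lead_{i - 1}")
    dat_path = header_path.parent / dat_files[0]
    if not dat_path.exists():
        raise FormatError(f"{dat_path}: signal file not found")
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise FormatError(
            f"{dat_path}: signal length {raw.size} != header {n_sig}x{n_samples}"
        )
    adc = raw.reshape(n_samples, n_sig).T.astype(float)
    mv = (adc - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    ann_path = header_path.with_suffix(".ann")
    annotations = read_annotations(ann_path) if ann_path.exists() else None
    return ECGRecord(rec_name, fs, leads, mv, annotations)


def write_annotations(path: str | Path, annotations: Sequence[tuple[int, str]]) -> None:
    Path(path).write_text("".join(f"{int(s)}\t{lab}\n" for s, lab in annotations))


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    path = Path(path)
    out = []
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        try:
            s, lab = ln.split("\t")
            out.append((int(s), lab))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed annotation line {i}") from exc
    return out


def read_record(path: str | Path, format: str | None = None) -> ECGRecord:
    """Read a record from a CSV file or a WFDB header path.

    ``format`` is ``"csv"`` or ``"wfdb"``; when omitted it is inferred from
    the file extension (``.csv`` vs ``.hea``).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        if not path.exists():
            raise FormatError(f"{path}: file not found")
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path if path.suffix == ".hea" else path.with_suffix(".hea"))
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Beat detection and segmentation

def detect_r_peaks(
    record: ECGRecord,
    lead: str | int = 0,
    refractory_s: float = 0.3,
    mad_k: float = 6.0,
) -> np.ndarray:
    """Locate R peaks on one lead with a squared-derivative envelope detector.

    The envelope is the moving average (80 ms) of the squared first difference;
    candidate peaks are envelope local maxima above an adaptive threshold —
    ``median + mad_k * MAD`` of the envelope, floored at 10% of the envelope
    maximum so that the gentle P/T-wave lobes never qualify — separated by at
    least ``refractory_s``.  Each candidate is then snapped to the extremum of
    the absolute signal deviation within ±40 ms, which centres the index on
    the R apex.  The threshold is scale-free: rescaling the lead by any
    positive gain leaves the output unchanged.  A flat lead yields an empty
    array.
    """
    if refractory_s <= 0:
        raise ValueError("refractory_s must be positive")
    li = lead if isinstance(lead, int) else record.leads.index(lead)
    x = record.samples[li]
    fs = record.sample_rate
    env = np.zeros_like(x)
    env[1:] = np.diff(x) ** 2
    env = uniform_filter1d(env, size=max(int(0.08 * fs), 1))
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    thr = max(med + mad_k * mad, 0.1 * float(env.max()))
    above = env > thr
    if not above.any():
        return np.array([], dtype=int)

    refr = max(int(refractory_s * fs), 1)
    # envelope local maxima above threshold
    interior = np.nonzero(above[1:-1] & (env[1:-1] >= env[:-2]) & (env[1:-1] >= env[2:]))[0] + 1
    peaks: list[int] = []
    for idx in interior:
        if peaks and idx - peaks[-1] < refr:
            if env[idx] > env[peaks[-1]]:
                peaks[-1] = idx
            continue
        peaks.append(int(idx))

    # snap to the apex of the deviation from the running baseline
    half = max(int(0.04 * fs), 1)
    base = np.median(x)
    snapped = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        snapped.append(lo + int(np.argmax(np.abs(x[lo:hi] - base))))
    snapped = sorted(set(snapped))
    # enforce the refractory period again after snapping
    out: list[int] = []
    for idx in snapped:
        if out and idx - out[-1] < refr:
            if np.abs(x[idx] - base) > np.abs(x[out[-1]] - base):
                out[-1] = idx
            continue
        out.append(idx)
    return np.asarray(out, dtype=int)


def segment_cycles(
    record: ECGRecord,
    r_peaks: Sequence[int],
    pre_s: float = 0.25,
    post_s: float = 0.45,
    out_len: int = 128,
    labels: Sequence[str] | None = None,
) -> list[ECGCycle]:
    """Cut the half-open window ``[r - pre_s, r + post_s)`` around each R peak.

    Windows that cross a record edge are dropped; every lead of a kept window
    is linearly resampled to ``out_len`` samples (identity when the native
    window already has ``out_len`` samples).  ``labels`` optionally attaches
    one label per peak (peaks whose windows are dropped lose their label).
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be positive")
    if out_len < 8:
        raise ValueError("out_len must be >= 8")
    fs = record.sample_rate
    pre, post = int(round(pre_s * fs)), int(round(post_s * fs))
    native = pre + post
    cycles: list[ECGCycle] = []
    src = np.arange(native, dtype=float)
    dst = np.linspace(0.0, native - 1.0, out_len)
    for k, r in enumerate(r_peaks):
        start, stop = int(r) - pre, int(r) + post
        if start < 0 or stop > record.n_samples:
            continue
        win = record.samples[:, start:stop]
        if out_len == native:
            resampled = win.astype(float).copy()
        else:
            resampled = np.vstack([np.interp(dst, src, lead) for lead in win])
        cycles.append(
            ECGCycle(
                record_id=record.record_id,
                cycle_index=len(cycles),
                leads=list(record.leads),
                samples=resampled,
                label=labels[k] if labels is not None else None,
            )
        )
    return cycles


def ensemble_cycle(cycles: Sequence[ECGCycle], label: str | None = None) -> ECGCycle:
    """Pointwise per-lead mean of equal-length cycles (one sample per recording)."""
    if not cycles:
        raise ValueError("cannot average an empty list of cycles")
    lengths = {c.length for c in cycles}
    if len(lengths) != 1:
        raise ValueError(f"cycles have differing lengths: {sorted(lengths)}")
    stacked = np.stack([c.samples for c in cycles])
    return ECGCycle(
        record_id=cycles[0].record_id,
        cycle_index=0,
        leads=list(cycles[0].leads),
        samples=stacked.mean(axis=0),
        label=label if label is not None else cycles[0].label,
    )
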