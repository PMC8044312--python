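"""Reading and writing ECG records, annotations and TWAC tables.

Two record formats are supported:

* **WFDB** (PhysioNet) — a text ``.hea`` header plus a binary ``.dat`` signal
  file.  Only the ubiquitous format ``16`` (interleaved little-endian 16-bit
  integers, single multiplexed signal file) is handled; amplitudes are
  converted to mV with each signal's stored gain and baseline.  Annotation
  files use the standard MIT byte-pair encoding, which is what the QT
  database's ``.q1c`` delineation files are stored in.
* **delimited text** — UTF-8 CSV with a ``# fs=<Hz>`` first line, a header
  row of lead names, then one row per sample ("." decimal point).

All amplitudes are mV once in memory.  The missing-value token in delimited
output is ``NA``.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .curve import TwacSeries
from .errors import EmptyOutputError, FormatError, RangeError, UnitError
from .records import BeatAnnotations, EcgRecord

logger = logging.getLogger("twac")

MISSING_TOKEN = "NA"

# MIT annotation type codes (subset used for delineation marks).
_CODE_NORMAL = 1       # 'N' — beat (R peak)
_CODE_TWAVE = 27       # 't' — T-wave peak
_CODE_WFON = 39        # '(' — waveform onset
_CODE_WFOFF = 40       # ')' — waveform offset
_CODE_SUB = 61
_CODE_CHN = 62
_CODE_NUM = 60
_CODE_AUX = 63
_CODE_SKIP = 59

_SYMBOL_TO_CODE = {"N": _CODE_NORMAL, "t": _CODE_TWAVE, "(": _CODE_WFON, ")": _CODE_WFOFF}
_CODE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_CODE.items()}


# ---------------------------------------------------------------------------
# WFDB records
# ---------------------------------------------------------------------------

def _parse_gain(field: str, lead: str) -> tuple[float, int, str]:
    """Parse a WFDB ``gain(baseline)/units`` specification."""
    units = "mV"
    baseline = 0
    spec = field
    if "/" in spec:
        spec, units = spec.split("/", 1)
    if "(" in spec:
        spec, rest = spec.split("(", 1)
        if not rest.endswith(")"):
            raise UnitError(f"malformed baseline in gain spec {field!r} for lead {lead}")
        baseline = int(rest[:-1])
    try:
        gain = float(spec)
    except ValueError as exc:
        raise UnitError(f"unreadable gain {field!r} for lead {lead}") from exc
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline, units


def read_wfdb_record(path: str | Path) -> EcgRecord:
    """Read a WFDB record (``.hea`` + format-16 ``.dat``) into mV.

    ``path`` may be the record stem or the path to the ``.hea`` file.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header file {hea}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"header line too short in {hea}")
    record_name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samples = int(head[3])
    except ValueError as exc:
        raise FormatError(f"unparseable header fields in {hea}") from exc
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError(f"header declares {n_sig} signals but lists {len(sig_lines)}")

    filenames, gains, baselines, names = [], [], [], []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"signal line {i} too short in {hea}")
        filenames.append(parts[0])
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(f"unsupported WFDB signal format {parts[1]!r} (only 16)")
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"ch{i}"
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain, baseline, units = _parse_gain(gain_field, desc)
        if units.lower() not in ("mv", "millivolt", "millivolts"):
            raise UnitError(f"lead {desc}: unsupported amplitude units {units!r}")
        gains.append(gain)
        baselines.append(baseline)
        names.append(desc)

    if len(set(filenames)) != 1:
        raise FormatError("only single (multiplexed) signal files are supported")
    dat = hea.parent / filenames[0]
    if not dat.exists():
        raise FormatError(f"missing signal file {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise FormatError(
            f"signal file holds {raw.size} samples, header declares {n_sig}x{n_samples}"
        )
    adc = raw.reshape(n_samples, n_sig).astype(float)
    signal = (adc - np.asarray(baselines)) / np.asarray(gains)
    return EcgRecord(signal, fs, tuple(names), record_id=record_name)


def write_wfdb_record(record: EcgRecord, path: str | Path, gain: float = 2000.0) -> None:
    """Write a record as a WFDB format-16 pair (``.hea`` + ``.dat``)."""
    path = Path(path)
    stem = path.with_suffix("")
    name = stem.name
    adc = np.round(record.signal * gain).astype(np.int64)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds 16-bit ADC range at this gain")
    adc16 = adc.astype("<i2")
    lines = [f"{name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for lead in record.lead_names:
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    stem.with_suffix(".dat").write_bytes(adc16.reshape(-1).tobytes())


# ---------------------------------------------------------------------------
# MIT annotations
# ---------------------------------------------------------------------------

def read_mit_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file into ``(sample, symbol)`` pairs.

    Only the annotation codes used for delineation marks are mapped to
    symbols; bookkeeping pseudo-annotations (SUB/CHN/NUM/AUX/SKIP) are
    consumed but not returned.
    """
    data = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _CODE_SKIP:
            if i + 3 >= len(data):
                raise FormatError("truncated SKIP annotation")
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            time += struct.unpack("<i", struct.pack("<I", (hi << 16) | lo))[0]
            continue
        if code in (_CODE_SUB, _CODE_CHN, _CODE_NUM):
            continue
        if code == _CODE_AUX:
            i += interval + (interval & 1)
            continue
        time += interval
        symbol = _CODE_TO_SYMBOL.get(code, "?")
        out.append((time, symbol))
    return out


def write_mit_annotations(marks: list[tuple[int, str]], path: str | Path) -> None:
    """Encode ``(sample, symbol)`` pairs as an MIT-format annotation file."""
    buf = bytearray()
    prev = 0
    for sample, symbol in sorted(marks):
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"unsupported annotation symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta > 1023:
            buf += struct.pack("<H", _CODE_SKIP << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
    buf += struct.pack("<H", 0)  # end of file
    Path(path).write_bytes(bytes(buf))


def read_delineation_annotations(path: str | Path, record: EcgRecord) -> BeatAnnotations:
    """Turn QT-database-style delineation marks into :class:`BeatAnnotations`.

    Understands the MIT binary encoding (``.q1c``/``.atr``-style) and, for
    ``.csv``/``.txt`` paths, a two-column ``sample,symbol`` table.  R peaks
    come from beat marks (``N``); a ``(`` directly preceding a ``t`` mark is
    the T onset and a ``)`` directly following it is the T offset.  Beats
    lacking a boundary are left missing, never fabricated.  Boundaries are
    shared across all leads (QT-style marks are record-wide).
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, comment="#")
        marks = [(int(s), str(sym)) for s, sym in zip(df.iloc[:, 0], df.iloc[:, 1])]
    else:
        marks = read_mit_annotations(path)

    for sample, _ in marks:
        if sample < 0 or sample >= record.n_samples:
            raise RangeError(
                f"annotation at sample {sample} outside record of {record.n_samples} samples"
            )

    r_peaks = [s for s, sym in marks if sym == "N"]
    n_beats = len(r_peaks)
    on = np.full(n_beats, np.nan)
    off = np.full(n_beats, np.nan)
    r_arr = np.asarray(r_peaks)
    for i, (sample, sym) in enumerate(marks):
        if sym != "t":
            continue
        beat = int(np.searchsorted(r_arr, sample, side="right")) - 1
        if beat < 0:
            continue
        if i > 0 and marks[i - 1][1] == "(" and np.isnan(on[beat]):
            on[beat] = marks[i - 1][0]
        # a biphasic T may carry two 't' marks before the closing ')'
        j = i + 1
        while j < len(marks) and marks[j][1] == "t":
            j += 1
        if j < len(marks) and marks[j][1] == ")":
            off[beat] = marks[j][0]
    onsets = {lead: on.copy() for lead in record.lead_names}
    offsets = {lead: off.copy() for lead in record.lead_names}
    ann = BeatAnnotations(r_arr, record.fs, onsets, offsets)
    ann.validate_against(record)
    return ann


# ---------------------------------------------------------------------------
# Delimited-text records
# ---------------------------------------------------------------------------

def write_text_record(record: EcgRecord, path: str | Path) -> None:
    """Write a record as CSV: ``# fs=<Hz>`` line, lead-name header, samples."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        pd.DataFrame(record.signal, columns=list(record.lead_names)).to_csv(fh, index=False)


def read_text_record(path: str | Path) -> EcgRecord:
    """Read a CSV record written by :func:`write_text_record`."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs=" not in first:
            raise FormatError(f"{path}: first line must declare '# fs=<Hz>'")
        try:
            fs = float(first.split("fs=")[1].split()[0])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: unparseable sampling rate") from exc
        df = pd.read_csv(fh)
    if df.empty:
        raise FormatError(f"{path}: no samples")
    return EcgRecord(df.to_numpy(dtype=float), fs, tuple(map(str, df.columns)), path.stem)


def read_record(path: str | Path) -> EcgRecord:
    """Dispatch on extension: ``.csv``/``.txt`` text dialect, else WFDB."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt"):
        return read_text_record(path)
    return read_wfdb_record(path)


# ---------------------------------------------------------------------------
# TWAC tables and annotation tables
# ---------------------------------------------------------------------------

def write_twac_table(series: TwacSeries, path: str | Path) -> None:
    """Persist a TWAC series as CSV (header of lead names, one row per beat)."""
    if series.n_beats == 0:
        raise EmptyOutputError("refusing to write a TWAC table with zero beats")
    series.to_frame().to_csv(path, na_rep=MISSING_TOKEN)


def read_twac_table(path: str | Path) -> TwacSeries:
    """Read back a TWAC table written by :func:`write_twac_table`."""
    df = pd.read_csv(path, index_col=0, na_values=[MISSING_TOKEN])
    return TwacSeries(
        df.to_numpy(dtype=float),
        tuple(map(str, df.columns)),
        fs=float("nan"),
        record_id=Path(path).stem,
        beat_indices=df.index.to_numpy(),
    )


def write_annotation_table(ann: BeatAnnotations, record_id: str, path: str | Path) -> None:
    """Write delineation results as a long-format CSV.

    Columns: record, lead, beat, R, T_on, T_off, flags.  Missing boundaries
    use the ``NA`` token; ``flags`` marks beats with no usable T wave.
    """
    rows = []
    for lead in ann.t_onsets:
        on, off = ann.t_onsets[lead], ann.t_offsets[lead]
        for i in range(ann.n_beats):
            missing = np.isnan(on[i]) or np.isnan(off[i])
            rows.append(
                {
                    "record": record_id,
                    "lead": lead,
                    "beat": i,
                    "R": int(ann.r_peaks[i]),
                    "T_on": None if np.isnan(on[i]) else int(on[i]),
                    "T_off": None if np.isnan(off[i]) else int(off[i]),
                    "flags": "no_t" if missing else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep=MISSING_TOKEN)
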