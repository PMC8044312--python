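"""Core in-memory containers for multi-lead ECG records and beat annotations.

Conventions used throughout the package:

* sample indexing is 0-based and windows are half-open ``[t1, t2)`` unless a
  closed interval is explicitly part of a formula (the T-wave area sum);
* amplitudes are millivolts everywhere in memory — gain conversion happens at
  the file-reader boundary;
* a missing per-beat boundary is ``NaN`` in a float array, never a sentinel
  index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("twac")

#: Canonical 12-lead names in conventional order.
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_CANONICAL = {name.lower(): name for name in STANDARD_LEADS}


def normalize_lead_name(name: str) -> str:
    """Map a lead label onto the canonical 12-lead spelling, case-insensitively.

    Unknown labels are returned verbatim (and logged), so records with
    auxiliary channels still round-trip.
    """
    canonical = _CANONICAL.get(name.strip().lower())
    if canonical is None:
        logger.info("lead name %r is not in the standard 12-lead set; kept verbatim", name)
        return name.strip()
    return canonical


@dataclass
class EcgRecord:
    """A uniformly sampled multi-lead ECG segment.

    Parameters
    ----------
    signal
        Array of shape ``(n_samples, n_leads)`` holding amplitudes in mV.
    fs
        Sampling rate in Hz.
    lead_names
        Ordered channel labels matching the signal columns.
    record_id
        Free-text identifier (file stem for records read from disk).
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...]
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (n_samples, n_leads) array")
        self.lead_names = tuple(normalize_lead_name(n) for n in self.lead_names)
        if len(self.lead_names) != self.signal.shape[1]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for {self.signal.shape[1]} signal columns"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (a view) by canonical name."""
        target = normalize_lead_name(name)
        try:
            idx = self.lead_names.index(target)
        except ValueError as exc:
            raise KeyError(f"record has no lead {name!r}") from exc
        return self.signal[:, idx]

    def slice(self, start: int, stop: int) -> "EcgRecord":
        """Sub-record over sample range ``[start, stop)``."""
        if not 0 <= start < stop <= self.n_samples:
            raise ValueError("slice bounds outside record")
        return EcgRecord(
            self.signal[start:stop].copy(), self.fs, self.lead_names, self.record_id
        )


@dataclass
class BeatAnnotations:
    """Per-beat fiducial points: R peaks plus per-lead T-wave boundaries.

    ``t_onsets[lead]`` and ``t_offsets[lead]`` are float arrays aligned with
    ``r_peaks``; ``NaN`` marks a beat where the boundary could not be (or was
    deliberately not) determined.
    """

    r_peaks: np.ndarray
    fs: float
    t_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    t_offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        for table in (self.t_onsets, self.t_offsets):
            for lead, arr in table.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.r_peaks.shape:
                    raise ValueError(f"boundary array for lead {lead} misaligned with r_peaks")
                table[lead] = arr

    @property
    def n_beats(self) -> int:
        return int(self.r_peaks.size)

    def validate_against(self, record: EcgRecord) -> None:
        """Check indices lie inside the record and R < T_on < T_off per beat."""
        n = record.n_samples
        if self.r_peaks.size and (self.r_peaks.min() < 0 or self.r_peaks.max() >= n):
            raise ValueError("R-peak index outside record")
        for lead in self.t_onsets:
            on, off = self.t_onsets[lead], self.t_offsets.get(lead)
            if off is None:
                raise ValueError(f"lead {lead} has onsets but no offsets")
            both = ~np.isnan(on) & ~np.isnan(off)
            if np.any(on[both] >= off[both]):
                raise ValueError(f"T_on >= T_off on lead {lead}")
            if np.any(on[both] <= self.r_peaks[both]):
                raise ValueError(f"T_on not after R on lead {lead}")
            for arr in (on, off):
                vals = arr[~np.isnan(arr)]
                if vals.size and (vals.min() < 0 or vals.max() >= n):
                    raise ValueError(f"T boundary outside record on lead {lead}")
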