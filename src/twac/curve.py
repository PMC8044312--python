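"""Per-beat baseline-corrected T-wave areas and the T-wave area curve (TWAC).

For each delineated beat the T-wave area is the signed sum of
baseline-subtracted amplitudes over the closed interval from T-wave onset to
offset,

    A = sum_{t = T_on}^{T_off} (s_t - s_bar),

where ``s_bar`` is a local estimate of the isoelectric level: the mean of a
short window (``2*round(p*fs)+1`` samples, default ``p = 0.016`` s) ending at
the T-wave onset, i.e. a pre-T isoelectric estimate.  Anchoring the baseline
at the onset makes the area invariant to any constant offset added to the
lead, and robust to slow baseline wander.

Plotting one lead's areas against cardiac-cycle number gives the T-wave area
curve; beat-to-beat fluctuation of that curve is the screening statistic
(see :mod:`twac.screening`).  Areas are kept signed — an inverted T wave
(e.g. lead aVR) has a negative area, and sign crossings of the curve are
themselves diagnostically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyOutputError, RangeError
from .records import BeatAnnotations, EcgRecord


@dataclass
class BaselineConfig:
    """Local-baseline estimation settings.

    Parameters
    ----------
    p
        Smoothing half-window in seconds; the averaging window spans
        ``2*round(p*fs) + 1`` samples (33 samples at 1000 Hz for the default
        ``p = 0.016``).
    anchor
        Which boundary the window is attached to: ``"t_on"`` (default, pre-T
        isoelectric estimate) or ``"t_off"`` — exposed for sensitivity
        analysis.
    placement
        ``"preceding"`` (default): the window *ends* at the anchor, so the
        baseline is estimated from the isoelectric stretch before the T wave
        and is untouched by the T upslope.  ``"centered"``: the window is
        centred on the anchor; with a T wave that rises quickly after its
        onset the right half of a centred window overlaps the T itself, which
        couples the baseline estimate to small delineation jitter.
    normalize
        If true, areas are reported in mV·s (divided by ``fs``) instead of the
        raw mV·samples of the plain sum.
    """

    p: float = 0.016
    anchor: str = "t_on"
    placement: str = "preceding"
    normalize: bool = False

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError("p must be positive")
        if self.anchor not in ("t_on", "t_off"):
            raise ValueError("anchor must be 't_on' or 't_off'")
        if self.placement not in ("preceding", "centered"):
            raise ValueError("placement must be 'preceding' or 'centered'")

    def half_width_samples(self, fs: float) -> int:
        h = int(round(self.p * fs))
        if 2 * h + 1 < 3:
            raise ValueError(f"baseline window shorter than 3 samples at fs={fs}")
        return h


@dataclass
class TwacSeries:
    """Per-lead ordered sequence of per-beat T-wave areas.

    ``areas`` has shape ``(n_beats, n_leads)``; NaN marks beats where
    delineation flagged no usable T wave on that lead.  Beat order matches the
    R-peak order of the source annotations.
    """

    areas: np.ndarray
    lead_names: tuple[str, ...]
    fs: float
    record_id: str = ""
    beat_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 2 or self.areas.shape[1] != len(self.lead_names):
            raise ValueError("areas must be (n_beats, n_leads) matching lead_names")
        self.lead_names = tuple(self.lead_names)
        if self.beat_indices is None:
            self.beat_indices = np.arange(self.areas.shape[0])
        self.beat_indices = np.asarray(self.beat_indices, dtype=int)

    @property
    def n_beats(self) -> int:
        return self.areas.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.areas)

    def lead(self, name: str) -> np.ndarray:
        return self.areas[:, self.lead_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.areas, columns=list(self.lead_names), index=pd.Index(self.beat_indices, name="beat")
        )


def local_baseline(signal: np.ndarray, anchor_index: int, cfg: BaselineConfig, fs: float) -> float:
    """Mean amplitude of the ``2*round(p*fs)+1``-sample window at the anchor.

    The window either ends at the anchor (``placement="preceding"``) or is
    centred on it (``placement="centered"``).
    """
    signal = np.asarray(signal, dtype=float)
    h = cfg.half_width_samples(fs)
    if cfg.placement == "preceding":
        lo, hi = anchor_index - 2 * h, anchor_index + 1
    else:
        lo, hi = anchor_index - h, anchor_index + h + 1
    if lo < 0 or hi > signal.size:
        raise RangeError(
            f"baseline window [{lo}, {hi}) outside signal of length {signal.size}"
        )
    return float(signal[lo:hi].mean())


def t_wave_area(signal: np.ndarray, t_on: int, t_off: int, baseline: float) -> float:
    """Signed T-wave area over the closed interval ``[t_on, t_off]``.

    The sign is preserved: inverted T waves yield negative areas.
    """
    signal = np.asarray(signal, dtype=float)
    if not t_on < t_off:
        raise ValueError(f"t_on ({t_on}) must precede t_off ({t_off})")
    if t_on < 0 or t_off >= signal.size:
        raise RangeError("T boundaries outside signal")
    return float(np.sum(signal[t_on : t_off + 1] - baseline))


def build_twac(
    record: EcgRecord, ann: BeatAnnotations, cfg: BaselineConfig | None = None
) -> TwacSeries:
    """Assemble the per-lead T-wave area curve from a delineated record.

    One area per (lead, beat); NaN where the beat lacks T boundaries on that
    lead or the baseline window would leave the record.
    """
    cfg = cfg or BaselineConfig()
    ann.validate_against(record)
    if ann.n_beats == 0:
        raise EmptyOutputError("no annotated beats — cannot build a TWAC series")
    areas = np.full((ann.n_beats, record.n_leads), np.nan)
    any_value = False
    for j, lead in enumerate(record.lead_names):
        if lead not in ann.t_onsets:
            continue
        sig = record.signal[:, j]
        on, off = ann.t_onsets[lead], ann.t_offsets[lead]
        for i in range(ann.n_beats):
            if np.isnan(on[i]) or np.isnan(off[i]):
                continue
            t_on, t_off = int(on[i]), int(off[i])
            anchor = t_on if cfg.anchor == "t_on" else t_off
            try:
                s_bar = local_baseline(sig, anchor, cfg, record.fs)
                areas[i, j] = t_wave_area(sig, t_on, t_off, s_bar)
            except RangeError:
                continue
            any_value = True
    if not any_value:
        raise EmptyOutputError("no (lead, beat) pair produced an area")
    if cfg.normalize:
        areas = areas / record.fs
    return TwacSeries(areas, record.lead_names, record.fs, record.record_id)


def plot_twac(series: TwacSeries, path: str) -> None:
    """Render per-lead area curves (cardiac cycle number on the abscissa)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(series.lead_names)
    ncols = 3
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 1.9 * nrows), sharex=True)
    axes = np.atleast_1d(axes).ravel()
    for j, lead in enumerate(series.lead_names):
        ax = axes[j]
        y = series.areas[:, j]
        ax.plot(series.beat_indices, y, marker="o", ms=2.5, lw=1)
        ax.axhline(0.0, color="0.7", lw=0.6)
        ax.set_title(lead, fontsize=8)
    for ax in axes[n:]:
        ax.axis("off")
    fig.suptitle(f"T-wave area curve — {series.record_id}", fontsize=10)
    fig.supxlabel("cardiac cycle")
    fig.supylabel("T-wave area (mV·samples)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
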