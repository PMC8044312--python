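"""T-wave delineation: RR-adaptive search windows and the sliding-area indicator.

The delineator locates T-wave onsets and offsets in three steps:

1. **R peaks** anchor each beat (band-pass energy detector, lead II by
   default, one R train shared across leads).
2. **Search windows.**  For beat *i* with preceding RR interval ``RR_i`` the
   window ``[t1, t2)`` is a piecewise function of RR with three cases
   (short / intermediate / long RR).  Each bound is
   ``R_i + round_mode(coeff * RR_i) + fixed``, where the coefficient term is
   evaluated in *samples* (ceil in cases 1 and 3, floor in case 2) and the
   fixed term is a constant converted from seconds.  The shipped case
   thresholds, coefficients and fixed offsets are the published calibrated
   values; :func:`fit_search_boundaries` (k-means on (RR, RT) scatter) and
   :func:`tune_window_params` (cross-validated grid search) re-derive them
   from annotated data.
3. **Area indicator.**  At candidate ``t`` the indicator is the summed area
   between the signal over a short window and the horizontal line through
   ``s_t``:  ``A(t) = sum_{k=t-W+1}^{t} (s_k - s_t)`` (trailing window, used
   for offsets) or its time-mirrored leading form (onsets).  The boundary is
   the argmax of ``|A|`` over the search window, ties to the earliest sample.
   Subtracting ``s_t`` makes the indicator exactly invariant to constant
   offsets and robust to slow baseline wander and to T polarity.

Note on the published coefficients: with sample-domain rounding the onset
case-3 window is degenerate (``t1 >= t2`` for every RR in the case); such
windows raise :class:`~twac.errors.WindowError` and the beat is skipped with
a log entry rather than silently mislocated.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import InsufficientDataError, RangeError, TwacError, WindowError
from .records import BeatAnnotations, EcgRecord

logger = logging.getLogger("twac")

ONSET = "onset"
OFFSET = "offset"


@dataclass
class SearchWindowParams:
    """RR-case thresholds and window coefficients for both T boundaries.

    ``*_coeffs`` hold the six per-case coefficients ``(a, b, c, d, e, f)``:
    ``(a, b)`` bound case 1, ``(c, d)`` case 2, ``(e, f)`` case 3.
    ``*_fixed`` are the per-case additive offsets in seconds, and
    ``*_rt_range`` the admissible R-to-boundary interval per case (used only
    for diagnostics: a window leaving its range is logged, not clipped).
    """

    rr_thresholds_onset: tuple[float, float] = (0.67, 1.23)
    rr_thresholds_offset: tuple[float, float] = (0.71, 1.10)
    onset_coeffs: tuple[float, ...] = (0.4, 0.2, 0.4, 0.4, 0.3, 0.0)
    offset_coeffs: tuple[float, ...] = (0.2, 0.1, 0.2, 0.0, 0.0, 0.1)
    onset_fixed: tuple[tuple[float, float], ...] = ((0.02, 0.16), (0.04, 0.24), (0.04, 0.40))
    offset_fixed: tuple[tuple[float, float], ...] = ((0.18, 0.30), (0.18, 0.40), (0.18, 0.48))
    onset_rt_range: tuple[tuple[float, float], ...] = ((0.05, 0.25), (0.05, 0.35), (0.05, 0.45))
    offset_rt_range: tuple[tuple[float, float], ...] = ((0.20, 0.45), (0.20, 0.60), (0.20, 0.45))

    def __post_init__(self) -> None:
        for th in (self.rr_thresholds_onset, self.rr_thresholds_offset):
            if not th[0] < th[1]:
                raise ValueError("RR thresholds must be strictly increasing")
        for coeffs in (self.onset_coeffs, self.offset_coeffs):
            if len(coeffs) != 6 or any(not 0.0 <= c <= 1.0 for c in coeffs):
                raise ValueError("coefficients must be six values in [0, 1]")

    def thresholds(self, target: str) -> tuple[float, float]:
        return self.rr_thresholds_onset if target == ONSET else self.rr_thresholds_offset

    def coeffs(self, target: str, case: int) -> tuple[float, float]:
        c = self.onset_coeffs if target == ONSET else self.offset_coeffs
        return c[2 * (case - 1)], c[2 * (case - 1) + 1]

    def fixed(self, target: str, case: int) -> tuple[float, float]:
        f = self.onset_fixed if target == ONSET else self.offset_fixed
        return f[case - 1]

    def rt_range(self, target: str, case: int) -> tuple[float, float]:
        r = self.onset_rt_range if target == ONSET else self.offset_rt_range
        return r[case - 1]

    def with_coefficients(self, updates: dict[str, float]) -> "SearchWindowParams":
        """Copy with named coefficients replaced, e.g. ``{"onset_a": 0.3}``."""
        letters = "abcdef"
        onset = list(self.onset_coeffs)
        offset = list(self.offset_coeffs)
        for key, value in updates.items():
            target, letter = key.split("_")
            pos = letters.index(letter)
            (onset if target == ONSET else offset)[pos] = value
        return replace(self, onset_coeffs=tuple(onset), offset_coeffs=tuple(offset))


@dataclass
class IndicatorConfig:
    """Sliding-area indicator settings.

    ``window_w`` is the indicator window length in seconds for the trailing
    (offset) search; ``window_w_onset`` for the leading (onset) search.  Both
    must stay below the shortest admissible R-to-onset interval (0.05 s).
    They differ because the two searches face different geometry: the offset
    search window never starts near the T apex, so its indicator may span the
    whole T wave — the |A| maximum then sits exactly where the wave has fully
    entered the window, i.e. at the offset.  The onset search window can
    reach the apex, where a long window lets ``W * s_t`` dominate and capture
    the |A| maximum away from the boundary, so the onset indicator is kept
    short (about a T up-slope).
    """

    window_w: float = 0.040
    window_w_onset: float = 0.020

    def __post_init__(self) -> None:
        for w in (self.window_w, self.window_w_onset):
            if not 0 < w < 0.05:
                raise ValueError("indicator windows must lie in (0, 0.05) s")

    def window_for(self, mode: str) -> float:
        return self.window_w if mode == "trailing" else self.window_w_onset

    def samples(self, fs: float, mode: str = "trailing") -> int:
        w = int(round(self.window_for(mode) * fs))
        if w < 2:
            raise ValueError(f"indicator window shorter than 2 samples at fs={fs}")
        return w


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(record: EcgRecord, lead: str = "II") -> np.ndarray:
    """Detect R peaks on one lead (band-pass energy + local refinement).

    Falls back to the lead with the largest peak-to-peak amplitude when the
    requested lead is absent.  Returns an empty array (with a warning logged)
    if no plausible peaks are found; RR intervals outside 0.3-2 s are logged.
    """
    if record.duration_s < 2.0:
        raise ValueError("need at least 2 s of signal for R-peak detection")
    try:
        sig = record.lead(lead)
    except KeyError:
        amplitudes = record.signal.max(axis=0) - record.signal.min(axis=0)
        j = int(np.argmax(amplitudes))
        logger.info("lead %s absent; using %s for R detection", lead, record.lead_names[j])
        sig = record.signal[:, j]
    fs = record.fs
    if np.ptp(sig) < 0.05:
        logger.warning("signal nearly flat; no R peaks detected")
        return np.array([], dtype=int)
    sos = butter(3, [5.0, 18.0], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, sig)
    energy = filtered**2
    win = max(int(round(0.12 * fs)), 1)
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")
    peaks, _ = find_peaks(
        integrated, height=0.2 * integrated.max(), distance=int(0.3 * fs)
    )
    if peaks.size == 0:
        logger.warning("no R peaks found")
        return np.array([], dtype=int)
    # refine each detection to the raw-signal extremum nearby
    half = int(round(0.06 * fs))
    refined = []
    center = float(np.median(sig))
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, sig.size)
        refined.append(lo + int(np.argmax(np.abs(sig[lo:hi] - center))))
    r = np.unique(np.asarray(refined, dtype=int))
    rr = np.diff(r) / fs
    bad = (rr < 0.3) | (rr > 2.0)
    if np.any(bad):
        logger.warning("%d RR intervals outside the plausible 0.3-2 s range", int(bad.sum()))
    return r


# ---------------------------------------------------------------------------
# Search windows
# ---------------------------------------------------------------------------

def classify_rr_case(rr: float, target: str, params: SearchWindowParams) -> int:
    """Assign an RR interval to window case 1, 2 or 3 (boundaries to the upper case)."""
    if not rr > 0:
        raise ValueError("RR must be positive")
    lo, hi = params.thresholds(target)
    if rr < lo:
        return 1
    if rr < hi:
        return 2
    return 3


def search_window(
    r_i: int, rr_i: float, fs: float, target: str, params: SearchWindowParams
) -> tuple[int, int]:
    """Half-open search window ``[t1, t2)`` for one beat's T boundary.

    The coefficient term is rounded on the RR interval expressed in samples
    (ceil for cases 1 and 3, floor for case 2); the fixed term is converted
    from seconds.  Raises :class:`WindowError` when the published
    coefficients give a degenerate window (``t2 <= t1``).
    """
    case = classify_rr_case(rr_i, target, params)
    lo_c, hi_c = params.coeffs(target, case)
    f1, f2 = params.fixed(target, case)
    rr_samples = rr_i * fs
    rnd = math.floor if case == 2 else math.ceil
    t1 = r_i + rnd(lo_c * rr_samples) + int(round(f1 * fs))
    t2 = r_i + rnd(hi_c * rr_samples) + int(round(f2 * fs))
    if t2 <= t1:
        raise WindowError(
            f"{target} case {case}: degenerate window [{t1}, {t2}) for RR={rr_i:.3f}s"
        )
    rt_lo, rt_hi = params.rt_range(target, case)
    if (t1 - r_i) / fs > rt_hi or (t2 - r_i) / fs < rt_lo:
        logger.info(
            "%s case %d window [%.3f, %.3f]s after R leaves its admissible "
            "RT range (%.2f, %.2f)s",
            target, case, (t1 - r_i) / fs, (t2 - r_i) / fs, rt_lo, rt_hi,
        )
    return t1, t2


# ---------------------------------------------------------------------------
# Area indicator and boundary localization
# ---------------------------------------------------------------------------

def area_indicator(
    signal: np.ndarray,
    t: int,
    cfg: IndicatorConfig,
    fs: float,
    mode: str = "trailing",
) -> float:
    """Indicator value at one candidate sample.

    Trailing mode sums ``s_k - s_t`` over ``[t-W+1, t]``; leading mode over
    ``[t, t+W-1]``.  Units are mV·samples.
    """
    signal = np.asarray(signal, dtype=float)
    w = cfg.samples(fs, mode)
    if mode == "trailing":
        lo, hi = t - w + 1, t + 1
    elif mode == "leading":
        lo, hi = t, t + w
    else:
        raise ValueError("mode must be 'trailing' or 'leading'")
    if lo < 0 or hi > signal.size:
        raise RangeError(f"indicator window [{lo}, {hi}) outside signal")
    return float(np.sum(signal[lo:hi] - signal[t]))


def _indicator_profile(
    signal: np.ndarray, t1: int, t2: int, w: int, mode: str
) -> np.ndarray:
    """Vectorized indicator values for every candidate in ``[t1, t2)``."""
    n = signal.size
    if mode == "trailing":
        if t1 - w + 1 < 0 or t2 > n:
            raise RangeError("indicator window leaves the signal")
    else:
        if t1 < 0 or t2 + w - 1 > n:
            raise RangeError("indicator window leaves the signal")
    c = np.concatenate(([0.0], np.cumsum(signal)))
    t = np.arange(t1, t2)
    if mode == "trailing":
        sums = c[t + 1] - c[t - w + 1]
    else:
        sums = c[t + w] - c[t]
    return sums - w * signal[t]


def _locate(
    signal: np.ndarray, window: tuple[int, int], cfg: IndicatorConfig, fs: float, mode: str
) -> int | None:
    t1, t2 = window
    if not t1 < t2:
        raise WindowError(f"invalid search window [{t1}, {t2})")
    values = _indicator_profile(
        np.asarray(signal, dtype=float), t1, t2, cfg.samples(fs, mode), mode
    )
    magnitude = np.abs(values)
    if np.all(magnitude == 0.0):
        return None  # no T wave in this window
    return t1 + int(np.argmax(magnitude))


def locate_t_offset(
    signal: np.ndarray, window: tuple[int, int], cfg: IndicatorConfig, fs: float
) -> int | None:
    """T-wave offset: argmax of |A| (trailing window) over ``[t1, t2)``.

    Returns ``None`` when the indicator is identically zero (no T wave).
    """
    return _locate(signal, window, cfg, fs, "trailing")


def locate_t_onset(
    signal: np.ndarray, window: tuple[int, int], cfg: IndicatorConfig, fs: float
) -> int | None:
    """T-wave onset: argmax of |A| with the time-mirrored (leading) window."""
    return _locate(signal, window, cfg, fs, "leading")


# ---------------------------------------------------------------------------
# Record-level delineation
# ---------------------------------------------------------------------------

def delineate_record(
    record: EcgRecord,
    r_peaks: np.ndarray,
    params: SearchWindowParams | None = None,
    cfg: IndicatorConfig | None = None,
) -> BeatAnnotations:
    """Locate T onsets/offsets for every beat on every lead.

    One R train is shared across leads.  The first beat has no preceding RR
    interval and uses the record's median RR.  Beats whose window leaves the
    record, is degenerate, or yields ``T_on >= T_off`` are flagged missing
    with a log entry.
    """
    params = params or SearchWindowParams()
    cfg = cfg or IndicatorConfig()
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise InsufficientDataError("need at least 2 R peaks to form RR intervals")
    fs = record.fs
    rr = np.diff(r_peaks) / fs
    rr_per_beat = np.concatenate(([float(np.median(rr))], rr))

    windows: dict[str, list[tuple[int, int] | None]] = {ONSET: [], OFFSET: []}
    for target in (ONSET, OFFSET):
        for r, rr_i in zip(r_peaks, rr_per_beat):
            try:
                windows[target].append(search_window(int(r), float(rr_i), fs, target, params))
            except WindowError as exc:
                logger.info("beat at %d skipped for %s: %s", r, target, exc)
                windows[target].append(None)

    n_beats = r_peaks.size
    onsets = {lead: np.full(n_beats, np.nan) for lead in record.lead_names}
    offsets = {lead: np.full(n_beats, np.nan) for lead in record.lead_names}
    for j, lead in enumerate(record.lead_names):
        sig = record.signal[:, j]
        for i in range(n_beats):
            won, woff = windows[ONSET][i], windows[OFFSET][i]
            if won is None or woff is None:
                continue
            try:
                t_on = locate_t_onset(sig, won, cfg, fs)
                t_off = locate_t_offset(sig, woff, cfg, fs)
            except RangeError:
                logger.info("beat %d on %s: window outside record; skipped", i, lead)
                continue
            if t_on is None or t_off is None:
                logger.info("beat %d on %s: no T wave found", i, lead)
                continue
            if not r_peaks[i] < t_on < t_off:
                logger.info("beat %d on %s: violates R < T_on < T_off; dropped", i, lead)
                continue
            onsets[lead][i] = t_on
            offsets[lead][i] = t_off
    return BeatAnnotations(r_peaks, fs, onsets, offsets)


# ---------------------------------------------------------------------------
# Calibration: k-means case boundaries
# ---------------------------------------------------------------------------

@dataclass
class FittedBoundaries:
    """Result of the k-means boundary derivation."""

    rr_thresholds: tuple[float, ...]
    rt_ranges: tuple[tuple[float, float], ...]


def fit_search_boundaries(
    rr: np.ndarray,
    rt: np.ndarray,
    k: int = 3,
    *,
    seed: int = 0,
    standardize: bool = False,
) -> FittedBoundaries:
    """Derive piecewise RR thresholds from k-means clusters of (RR, RT) pairs.

    Clusters are ordered by their RR centres; each threshold is the midpoint
    between the RR extent of adjacent clusters, and each case's RT range is
    the cluster's RT min/max.  ``standardize`` optionally z-scores both
    coordinates before clustering.
    """
    from sklearn.cluster import KMeans

    rr = np.asarray(rr, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if rr.shape != rt.shape or rr.ndim != 1:
        raise ValueError("rr and rt must be 1-D arrays of equal length")
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = np.column_stack([rr, rt])
    n_distinct = np.unique(pts, axis=0).shape[0]
    if n_distinct < k:
        raise InsufficientDataError(f"{n_distinct} distinct points for k={k} clusters")
    if k == 1:
        return FittedBoundaries((), ((float(rt.min()), float(rt.max())),))
    x = pts
    if standardize:
        x = (pts - pts.mean(axis=0)) / pts.std(axis=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    labels = km.labels_
    order = np.argsort([rr[labels == c].mean() for c in range(k)])
    thresholds = []
    ranges = []
    for rank, c in enumerate(order):
        sel = labels == c
        ranges.append((float(rt[sel].min()), float(rt[sel].max())))
        if rank < k - 1:
            nxt = order[rank + 1]
            thresholds.append((float(rr[sel].max()) + float(rr[labels == nxt].min())) / 2.0)
    return FittedBoundaries(tuple(thresholds), tuple(ranges))


# ---------------------------------------------------------------------------
# Calibration: cross-validated grid search over window coefficients
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    """Outcome of the coefficient grid search."""

    best: dict[str, float]
    params: SearchWindowParams
    mean_sensitivity: float
    per_fold_sensitivity: tuple[float, ...]


def _boundary_sensitivity(
    records: list[tuple[EcgRecord, BeatAnnotations]],
    params: SearchWindowParams,
    cfg: IndicatorConfig,
    tolerance: float,
    lead: str,
) -> tuple[int, int]:
    """(hits, total) reference boundaries recovered within the tolerance."""
    hits = total = 0
    for record, ref in records:
        tol = int(round(tolerance * record.fs))
        try:
            det = delineate_record(record, ref.r_peaks, params, cfg)
        except TwacError:
            det = None
        for table_name in ("t_onsets", "t_offsets"):
            ref_arr = getattr(ref, table_name).get(lead)
            if ref_arr is None:
                continue
            det_arr = getattr(det, table_name)[lead] if det is not None else None
            for i, r in enumerate(ref_arr):
                if np.isnan(r):
                    continue
                total += 1
                if det_arr is not None and not np.isnan(det_arr[i]):
                    if abs(det_arr[i] - r) <= tol:
                        hits += 1
    return hits, total


def tune_window_params(
    records: list[tuple[EcgRecord, BeatAnnotations]],
    grid: dict[str, list[float]],
    folds: int = 5,
    tolerance: float = 0.020,
    *,
    base: SearchWindowParams | None = None,
    cfg: IndicatorConfig | None = None,
    lead: str = "II",
    seed: int = 0,
) -> TuningResult:
    """Exhaustive grid search over window coefficients with k-fold CV.

    ``grid`` maps coefficient names (``onset_a`` ... ``offset_f``) to
    candidate values.  For each combination the boundary sensitivity — the
    fraction of reference boundaries whose detected location falls within
    ``+/- tolerance`` seconds — is measured per fold and averaged; the
    combination with the highest mean sensitivity wins, ties broken by the
    first combination in lexicographic grid order.  The fold partition is
    seeded and shared across combinations.
    """
    if not grid:
        raise ValueError("empty coefficient grid")
    if len(records) < folds:
        raise InsufficientDataError(f"{len(records)} records for {folds} folds")
    base = base or SearchWindowParams()
    cfg = cfg or IndicatorConfig()
    keys = sorted(grid)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    fold_members = [perm[i::folds] for i in range(folds)]

    best: tuple[float, ...] | None = None
    best_score = -1.0
    best_folds: tuple[float, ...] = ()
    best_params = base
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = base.with_coefficients(dict(zip(keys, combo)))
        fold_sens = []
        for members in fold_members:
            hits, total = _boundary_sensitivity(
                [records[m] for m in members], params, cfg, tolerance, lead
            )
            fold_sens.append(hits / total if total else 0.0)
        score = float(np.mean(fold_sens))
        if score > best_score:
            best, best_score, best_folds, best_params = (
                combo, score, tuple(fold_sens), params
            )
    assert best is not None
    return TuningResult(dict(zip(keys, best)), best_params, best_score, best_folds)
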