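"""Positive/negative ischemia screen from TWAC fluctuation.

A healthy subject's T-wave area curve is flat; ischemic repolarization makes
it jagged.  Jaggedness is quantified per lead as the normalized median
absolute successive difference of the beat-area sequence,

    score = median(|A_{i+1} - A_i|) / (median(|A_i|) + eps),

a dimensionless, gain-invariant statistic robust to single outlier beats.
A lead is positive when its score exceeds the threshold, and the subject is
positive when *any* lead is positive.  The count of sign flips of the area
sequence is reported alongside (sign crossings of the curve — e.g. an aVR
curve repeatedly crossing zero — are clinically noteworthy).

The shipped default threshold was calibrated by Youden-index maximization on
the packaged synthetic cohort (seed 0, n = 100, prevalence 0.5); it is a
property of that synthetic cohort, and real-data users should recalibrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curve import TwacSeries
from .errors import CalibrationError, InsufficientDataError

EPSILON = 1e-9

#: Minimum number of usable beats per lead for a fluctuation score.  A 15 s
#: record at the 50 bpm bradycardia floor still yields >= 12 beats.
MIN_BEATS = 8

#: Default decision threshold; see module docstring for provenance.
DEFAULT_THRESHOLD = 0.1706

#: Advisory lead-set -> coronary-artery correspondence used for localization.
ARTERY_MAP: tuple[tuple[frozenset[str], str], ...] = (
    (frozenset({"V3", "V4", "aVL"}), "left anterior descending (suggestive)"),
    (frozenset({"aVR"}), "left main / circumflex (suggestive)"),
)


@dataclass
class ScreenResult:
    """Per-lead fluctuation scores and the overall screening decision."""

    scores: dict[str, float]
    sign_flips: dict[str, int]
    lead_positive: dict[str, bool]
    positive: bool
    threshold: float
    n_beats: dict[str, int]
    localization: list[tuple[tuple[str, ...], str]] = field(default_factory=list)
    record_id: str = ""

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "decision": "positive" if self.positive else "negative",
            "threshold": self.threshold,
            "leads": {
                lead: {
                    "score": self.scores[lead],
                    "sign_flips": self.sign_flips[lead],
                    "positive": self.lead_positive[lead],
                    "n_beats": self.n_beats[lead],
                }
                for lead in sorted(self.scores)
            },
            "localization": [
                {"leads": list(leads), "artery": artery} for leads, artery in self.localization
            ],
        }


def fluctuation_score(areas: np.ndarray, min_beats: int = MIN_BEATS) -> tuple[float, int]:
    """Fluctuation score and sign-flip count for one lead's area sequence.

    Missing beats (NaN) are excluded pairwise: a successive difference is
    used only when both neighbours are present; nothing is interpolated.
    """
    areas = np.asarray(areas, dtype=float)
    present = ~np.isnan(areas)
    if present.sum() < min_beats:
        raise InsufficientDataError(
            f"{int(present.sum())} usable beats; need at least {min_beats}"
        )
    pair = present[:-1] & present[1:]
    diffs = np.abs(areas[1:][pair] - areas[:-1][pair])
    if diffs.size == 0:
        raise InsufficientDataError("no adjacent beat pairs without missing values")
    score = float(np.median(diffs) / (np.median(np.abs(areas[present])) + EPSILON))
    signs = np.sign(areas[present])
    nz = signs[signs != 0]
    flips = int(np.sum(nz[1:] != nz[:-1]))
    return score, flips


def classify_twac(
    series: TwacSeries,
    threshold: float = DEFAULT_THRESHOLD,
    min_beats: int = MIN_BEATS,
    localize: bool = True,
) -> ScreenResult:
    """Screen one subject: any lead whose score exceeds the threshold → positive."""
    scores: dict[str, float] = {}
    flips: dict[str, int] = {}
    n_beats: dict[str, int] = {}
    for j, lead in enumerate(series.lead_names):
        areas = series.areas[:, j]
        try:
            s, f = fluctuation_score(areas, min_beats)
        except InsufficientDataError:
            continue
        scores[lead] = s
        flips[lead] = f
        n_beats[lead] = int(np.sum(~np.isnan(areas)))
    if not scores:
        raise InsufficientDataError("no lead has enough beats to score")
    lead_positive = {lead: s > threshold for lead, s in scores.items()}
    result = ScreenResult(
        scores=scores,
        sign_flips=flips,
        lead_positive=lead_positive,
        positive=any(lead_positive.values()),
        threshold=threshold,
        n_beats=n_beats,
        record_id=series.record_id,
    )
    if localize:
        result.localization = localize_occlusion(result)
    return result


def localize_occlusion(result: ScreenResult) -> list[tuple[tuple[str, ...], str]]:
    """Advisory artery hints from which leads are positive.

    Never alters the decision; a negative screen yields no hints.  Positive
    leads outside the mapped sets are reported as unlocalized.
    """
    if not result.positive:
        return []
    positive_leads = {lead for lead, p in result.lead_positive.items() if p}
    hints: list[tuple[tuple[str, ...], str]] = []
    mapped: set[str] = set()
    for lead_set, artery in ARTERY_MAP:
        overlap = positive_leads & lead_set
        if overlap:
            hints.append((tuple(sorted(overlap)), artery))
            mapped |= overlap
    rest = positive_leads - mapped
    if rest:
        hints.append((tuple(sorted(rest)), "unlocalized"))
    return hints


def subject_score(series: TwacSeries, min_beats: int = MIN_BEATS) -> float:
    """Maximum per-lead fluctuation score (the any-lead decision statistic)."""
    best = None
    for j in range(series.areas.shape[1]):
        try:
            s, _ = fluctuation_score(series.areas[:, j], min_beats)
        except InsufficientDataError:
            continue
        best = s if best is None else max(best, s)
    if best is None:
        raise InsufficientDataError("no lead has enough beats to score")
    return best


def calibrate_threshold(
    series_list: list[TwacSeries], labels: list[int], min_beats: int = MIN_BEATS
) -> float:
    """Youden-index-maximizing threshold over subject scores.

    Candidates are the midpoints between adjacent sorted subject scores, so
    on perfectly separated cohorts the midpoint of the separating gap is
    returned.  The result is independent of input order.
    """
    if len(series_list) != len(labels):
        raise ValueError("series and labels must align")
    labels_arr = np.asarray(labels, dtype=int)
    if len(set(labels_arr.tolist())) < 2:
        raise CalibrationError("both classes required for calibration")
    scores = np.asarray([subject_score(s, min_beats) for s in series_list])
    order = np.argsort(scores, kind="stable")
    scores, labels_arr = scores[order], labels_arr[order]
    candidates = (scores[1:] + scores[:-1]) / 2.0
    n_pos = labels_arr.sum()
    n_neg = labels_arr.size - n_pos
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        predicted = scores > thr
        sens = np.sum(predicted & (labels_arr == 1)) / n_pos
        spec = np.sum(~predicted & (labels_arr == 0)) / n_neg
        youden = sens + spec - 1.0
        if youden > best_j:
            best_thr, best_j = float(thr), youden
    assert best_thr is not None
    return best_thr
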