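"""Synthetic 12-lead ECG generator with exact ground-truth T-wave boundaries.

Each beat is a sum of five Gaussians (P, Q, R, S, T).  The T Gaussian is
truncated at three standard deviations from its centre, and those truncation
points *define* the ground-truth T-wave onset and offset — the generator's
annotations are exact by construction, which is what makes delineation-error
measurements interpretable.

A record is a train of such beats with jittered RR intervals.  Ischemic
beat-to-beat repolarization variability is emulated by multiplying each
beat's T amplitude by ``exp(eta)``, ``eta ~ N(0, t_area_variability)``
(a log-normal modulation, applied record-wide so all leads of a beat move
together).  Healthy records use a near-zero variability, diseased records a
large one, reproducing the contrast between flat and jagged T-wave area
curves.  White measurement noise and sinusoidal baseline wander are added
per lead.

One beat template is shared across leads with per-lead amplitude scaling;
the aVR scale is negative, so its T wave is inverted as on a real ECG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import STANDARD_LEADS, BeatAnnotations, EcgRecord

#: Per-lead amplitude scale of the shared beat template.  aVR is negative
#: (inverted complex), precordial leads are largest — a coarse caricature of
#: normal 12-lead proportions.
DEFAULT_LEAD_SCALES: dict[str, float] = {
    "I": 0.7, "II": 1.0, "III": 0.45, "aVR": -0.5, "aVL": 0.35, "aVF": 0.7,
    "V1": 0.5, "V2": 0.9, "V3": 1.1, "V4": 1.15, "V5": 1.0, "V6": 0.8,
}

#: (amplitude mV, centre offset from R in s, Gaussian width sigma in s)
Wave = tuple[float, float, float]


@dataclass
class BeatModelParams:
    """Gaussian-sum beat template plus rhythm parameters.

    The default T wave (centre 0.285 s after R, sigma 6 ms) together with the
    default 100 bpm heart rate places both true T boundaries inside the
    delineator's RR-adaptive search windows, so the generator can serve as
    ground truth for boundary-error measurements.
    """

    p_wave: Wave = (0.12, -0.20, 0.020)
    q_wave: Wave = (-0.08, -0.030, 0.008)
    r_wave: Wave = (1.1, 0.0, 0.010)
    s_wave: Wave = (-0.15, 0.030, 0.008)
    t_wave: Wave = (0.30, 0.285, 0.006)
    heart_rate_bpm: float = 100.0
    rr_jitter_sd: float = 0.010

    # beat span rendered around the R peak by synthesize_beat
    pre_s: float = 0.30
    post_s: float = 0.50

    def __post_init__(self) -> None:
        for name in ("p_wave", "q_wave", "r_wave", "s_wave", "t_wave"):
            amp, cen, wid = getattr(self, name)
            if not wid > 0:
                raise ValueError(f"{name}: width must be positive")
        if not 30.0 < self.heart_rate_bpm < 200.0:
            raise ValueError("heart rate must lie in (30, 200) bpm")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be non-negative")
        t_amp, t_cen, t_wid = self.t_wave
        if t_amp != 0 and t_cen + 3 * t_wid > self.post_s:
            raise ValueError("T wave extends beyond the rendered beat span")

    @property
    def rr_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def t_boundaries_s(self) -> tuple[float, float] | None:
        """Ground-truth (onset, offset) offsets from R in seconds, or None."""
        amp, cen, wid = self.t_wave
        if amp == 0:
            return None
        return cen - 3 * wid, cen + 3 * wid


@dataclass
class CohortParams:
    """Study-condition parameters for a labelled synthetic cohort.

    Positives carry a large beat-to-beat log-normal T-amplitude variability,
    negatives a near-zero one; everything else is shared.
    """

    n_subjects: int = 100
    prevalence: float = 0.5
    t_area_variability_pos: float = 0.35
    t_area_variability_neg: float = 0.02
    t_morphology: str = "upright"
    noise_sd: float = 0.010
    baseline_wander_amp: float = 0.05
    baseline_wander_freq: float = 0.25
    duration_s: float = 15.0
    fs: float = 1000.0
    seed: int = 0
    beat: BeatModelParams = field(default_factory=BeatModelParams)
    lead_names: tuple[str, ...] = STANDARD_LEADS

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.t_morphology not in ("upright", "inverted", "biphasic"):
            raise ValueError("t_morphology must be upright/inverted/biphasic")


@dataclass
class SyntheticRecord:
    """A generated record with its exact annotations and disease label."""

    record: EcgRecord
    annotations: BeatAnnotations
    label: int | None = None


def _gaussian(idx: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((idx - center) / sigma) ** 2)


def _render_t(
    out: np.ndarray, center: float, sigma_samp: float, amp: float, morphology: str
) -> None:
    """Add a truncated T deflection (support = centre +/- 3 sigma) in place."""
    lo = int(np.ceil(center - 3 * sigma_samp))
    hi = int(np.floor(center + 3 * sigma_samp))
    lo_c, hi_c = max(lo, 0), min(hi, out.size - 1)
    if lo_c > hi_c:
        return
    idx = np.arange(lo_c, hi_c + 1)
    g = _gaussian(idx, center, sigma_samp)
    if morphology == "biphasic":
        # odd (derivative-of-Gaussian) shape, peak amplitude matched to amp
        shape = -(idx - center) / sigma_samp * g
        shape = shape / np.exp(-0.5)  # normalize so extrema equal +/-1
        out[idx] += amp * shape
    else:
        sign = -1.0 if morphology == "inverted" else 1.0
        out[idx] += sign * amp * g


def synthesize_beat(
    params: BeatModelParams, fs: float, *, t_morphology: str = "upright"
) -> tuple[np.ndarray, tuple[int, int] | None]:
    """Render one beat and its ground-truth T boundaries.

    Returns the samples over ``[-pre_s, post_s]`` around the R peak (R at
    index ``round(pre_s*fs)``) and ``(t_on, t_off)`` sample indices within
    that span, or ``None`` when the T amplitude is zero.
    """
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    n = int(round((params.pre_s + params.post_s) * fs)) + 1
    r_idx = int(round(params.pre_s * fs))
    out = np.zeros(n)
    idx = np.arange(n, dtype=float)
    for amp, cen, wid in (params.p_wave, params.q_wave, params.r_wave, params.s_wave):
        if amp != 0:
            out += amp * _gaussian(idx, r_idx + cen * fs, wid * fs)
    t_amp, t_cen, t_wid = params.t_wave
    bounds = None
    if t_amp != 0:
        _render_t(out, r_idx + t_cen * fs, t_wid * fs, t_amp, t_morphology)
        on_off = params.t_boundaries_s()
        assert on_off is not None
        t_on = max(int(round(r_idx + on_off[0] * fs)), 0)
        t_off = min(int(round(r_idx + on_off[1] * fs)), n - 1)
        bounds = (t_on, t_off)
    return out, bounds


def synthesize_record(
    beat: BeatModelParams,
    duration_s: float = 15.0,
    fs: float = 1000.0,
    seed: int | np.random.Generator = 0,
    *,
    t_area_variability: float = 0.0,
    noise_sd: float = 0.0,
    baseline_wander_amp: float = 0.0,
    baseline_wander_freq: float = 0.25,
    lead_scales: dict[str, float] | None = None,
    lead_names: tuple[str, ...] = STANDARD_LEADS,
    t_morphology: str = "upright",
    label: int | None = None,
    record_id: str = "synthetic",
) -> SyntheticRecord:
    """Generate a multi-lead record with exact ground-truth annotations.

    Beats whose rendering span (0.35 s before to 0.6 s after R) would leave
    the record are excluded from the ground truth, so every annotated beat is
    complete and fully delineable.
    """
    if duration_s <= 2 * beat.rr_s:
        raise ValueError("duration must exceed two beats")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scales = dict(DEFAULT_LEAD_SCALES if lead_scales is None else lead_scales)
    n = int(round(duration_s * fs))

    # jittered beat train
    r_times = []
    t = 0.30
    while t < duration_s:
        r_times.append(t)
        rr = beat.rr_s + rng.normal(0.0, beat.rr_jitter_sd)
        t += max(rr, 0.3)
    r_samples = np.round(np.asarray(r_times) * fs).astype(int)

    t_amp, t_cen, t_wid = beat.t_wave
    template = np.zeros(n)
    idx = np.arange(n, dtype=float)
    t_factors = np.exp(rng.normal(0.0, t_area_variability, size=len(r_samples)))
    for r, m in zip(r_samples, t_factors):
        for amp, cen, wid in (beat.p_wave, beat.q_wave, beat.r_wave, beat.s_wave):
            if amp == 0:
                continue
            c, s = r + cen * fs, wid * fs
            lo = max(int(c - 5 * s), 0)
            hi = min(int(c + 5 * s) + 1, n)
            template[lo:hi] += amp * _gaussian(idx[lo:hi], c, s)
        if t_amp != 0:
            _render_t(template, r + t_cen * fs, t_wid * fs, t_amp * m, t_morphology)

    signal = np.empty((n, len(lead_names)))
    time = idx / fs
    for j, lead in enumerate(lead_names):
        sig = template * scales.get(lead, 1.0)
        if baseline_wander_amp > 0:
            phase = rng.uniform(0.0, 2 * np.pi)
            sig = sig + baseline_wander_amp * np.sin(
                2 * np.pi * baseline_wander_freq * time + phase
            )
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=n)
        signal[:, j] = sig
    record = EcgRecord(signal, fs, lead_names, record_id=record_id)

    # ground truth for complete beats only
    pre_margin = int(round(0.35 * fs))
    post_margin = int(round(0.60 * fs))
    keep = (r_samples - pre_margin >= 0) & (r_samples + post_margin <= n)
    r_kept = r_samples[keep]
    bounds = beat.t_boundaries_s()
    if bounds is None:
        on = np.full(r_kept.size, np.nan)
        off = np.full(r_kept.size, np.nan)
    else:
        on = np.round(r_kept + bounds[0] * fs)
        off = np.round(r_kept + bounds[1] * fs)
    onsets = {lead: on.astype(float).copy() for lead in lead_names}
    offsets = {lead: off.astype(float).copy() for lead in lead_names}
    ann = BeatAnnotations(r_kept, fs, onsets, offsets)
    ann.validate_against(record)
    return SyntheticRecord(record, ann, label)


def synthesize_cohort(params: CohortParams) -> list[SyntheticRecord]:
    """Generate a labelled cohort, reproducible bit-for-bit from the seed.

    Exactly ``round(n_subjects * prevalence)`` subjects are positive; label
    order is a seeded shuffle and per-subject generators are spawned
    deterministically from the master seed.
    """
    n_pos = int(round(params.n_subjects * params.prevalence))
    labels = np.array([1] * n_pos + [0] * (params.n_subjects - n_pos))
    master = np.random.SeedSequence(params.seed)
    shuffle_rng = np.random.default_rng(master.spawn(1)[0])
    shuffle_rng.shuffle(labels)
    children = master.spawn(params.n_subjects + 1)[1:]
    out = []
    for i, (label, child) in enumerate(zip(labels, children)):
        variability = (
            params.t_area_variability_pos if label == 1 else params.t_area_variability_neg
        )
        out.append(
            synthesize_record(
                params.beat,
                params.duration_s,
                params.fs,
                np.random.default_rng(child),
                t_area_variability=variability,
                noise_sd=params.noise_sd,
                baseline_wander_amp=params.baseline_wander_amp,
                baseline_wander_freq=params.baseline_wander_freq,
                lead_names=params.lead_names,
                t_morphology=params.t_morphology,
                label=int(label),
                record_id=f"synthetic-{i:03d}",
            )
        )
    return out
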