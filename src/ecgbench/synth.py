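"""Synthetic annotated single-lead ECG generator.

Produces datasets of both annotation categories with exact ground-truth
annotations, so the whole pipeline (reading, segmentation, splitting,
training, evaluation) is exercisable without downloading clinical data.

Beats are rendered as sums of Gaussian bumps (P wave, biphasic QRS pair,
T wave) rather than with a dynamical ECG model: that is sufficient to make
the classes morphologically separable (the premature ventricular template is
wide and of inverted polarity), trivially parameterizable and fast.  Rhythm
classes are encoded through their RR-interval statistics: sinus rhythm is
regular around 0.8 s, sinus tachycardia regular and fast (< 0.6 s), sinus
bradycardia regular and slow (> 1.0 s), and atrial fibrillation irregular
with a coefficient of variation >= 0.15.  No physiological realism beyond
this is claimed; noise is additive Gaussian only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    BEAT_LEVEL,
    RECORDING_LEVEL,
    BeatAnnotation,
    DatasetHandle,
    EcgRecord,
    RhythmEpisode,
    open_dataset,
    write_dataset_meta,
    write_label_table,
    write_record,
)

logger = logging.getLogger(__name__)

#: Raw annotation symbols written on disk, as entered in the default label
#: dictionary under dataset name ``synth``.
BEAT_SYMBOL = {"N": "N", "PVC": "V", "PAC": "A"}
RHYTHM_SYMBOL = {
    "SINUS": "N", "AFIB": "AFIB", "AFL": "AFL",
    "STACH": "ST", "SBRAD": "SBR", "SVTA": "SVTA",
}


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology parameters of one beat class (Gaussian-bump rendering)."""

    class_code: str
    qrs_width_s: float
    qrs_amp: float
    p_wave: bool
    t_amp: float

    def __post_init__(self) -> None:
        if not self.qrs_width_s > 0:
            raise ValueError("QRS width must be > 0")
        if self.qrs_amp == 0:
            raise ValueError("QRS amplitude must be nonzero")


#: Normal, premature-ventricular and premature-atrial defaults.  PVC: wide
#: QRS, inverted polarity, discordant tall T, no P wave.  PAC: near-normal
#: morphology without a P wave; its distinguishing feature is premature
#: timing (the preceding RR interval is shortened).
DEFAULT_TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate("N", qrs_width_s=0.08, qrs_amp=1.0, p_wave=True, t_amp=0.3),
    "PVC": BeatTemplate("PVC", qrs_width_s=0.16, qrs_amp=-1.4, p_wave=False, t_amp=0.5),
    "PAC": BeatTemplate("PAC", qrs_width_s=0.08, qrs_amp=0.9, p_wave=False, t_amp=0.25),
}


@dataclass(frozen=True)
class RRModel:
    """RR-interval model: ``regular`` (mean + Gaussian jitter) or
    ``irregular`` (gamma-distributed with a target coefficient of variation)."""

    kind: str  # "regular" | "irregular"
    mean_rr_s: float
    jitter_s: float = 0.0  # regular only
    cv: float = 0.0  # irregular only

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "regular":
            rr = self.mean_rr_s + self.jitter_s * rng.standard_normal()
        elif self.kind == "irregular":
            shape = 1.0 / (self.cv**2)
            rr = rng.gamma(shape, self.mean_rr_s / shape)
        else:
            raise ValueError(f"unknown RR model kind {self.kind!r}")
        return max(rr, 0.25 * self.mean_rr_s)


#: Per-rhythm RR defaults consistent with the clinical definitions of the
#: rhythm classes (rates in the ranges named in the module docstring).
DEFAULT_RR: dict[str, RRModel] = {
    "SINUS": RRModel("regular", 0.80, jitter_s=0.03),
    "STACH": RRModel("regular", 0.45, jitter_s=0.02),
    "SBRAD": RRModel("regular", 1.20, jitter_s=0.04),
    "SVTA": RRModel("regular", 0.38, jitter_s=0.01),
    "AFIB": RRModel("irregular", 0.70, cv=0.25),
    "AFL": RRModel("regular", 0.50, jitter_s=0.02),
}


@dataclass(frozen=True)
class EpisodeSpec:
    code: str
    duration_s: float
    rr_model: RRModel

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("episode duration must be > 0")


@dataclass
class RhythmPlan:
    episodes: list[EpisodeSpec]

    @classmethod
    def from_codes(cls, codes_durations: list[tuple[str, float]]) -> "RhythmPlan":
        return cls([EpisodeSpec(c, d, DEFAULT_RR[c]) for c, d in codes_durations])


@dataclass
class GeneratorConfig:
    n_patients: int = 40
    records_per_patient: int = 1
    record_duration_s: float = 60.0
    fs: float = 250.0
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {"SINUS": 0.7, "AFIB": 0.3}
    )
    noise_sd: float = 0.05
    seed: int = 0
    pvc_rate: float = 0.08
    pac_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.records_per_patient < 1:
            raise ValueError("counts must be >= 1")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-6:
            raise ValueError("class mixture probabilities must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for r in (self.pvc_rate, self.pac_rate):
            if not 0 <= r <= 1:
                raise ValueError("substitution rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def render_beat(template: BeatTemplate, fs: float) -> tuple[np.ndarray, int]:
    """Render one beat waveform; returns (samples, index of the R peak)."""
    if round(template.qrs_width_s * fs) < 3:
        raise ValueError(
            f"fs={fs} Hz too low to render QRS of width {template.qrs_width_s}s "
            "(fewer than 3 samples across the QRS)"
        )
    t = np.arange(round(-0.25 * fs), round(0.45 * fs)) / fs
    sigma = template.qrs_width_s / 5.0
    y = template.qrs_amp * _gauss(t, 0.0, sigma)
    # biphasic pair: small opposite-sign deflection just before the R peak
    y -= 0.25 * template.qrs_amp * _gauss(t, -template.qrs_width_s / 2.0, sigma / 1.5)
    if template.p_wave:
        y += 0.15 * np.sign(template.qrs_amp) * _gauss(t, -0.17, 0.025)
    y += template.t_amp * _gauss(t, 0.28, 0.05)
    return y, int(-round(-0.25 * fs))


def generate_record(
    plan: RhythmPlan,
    templates: Optional[dict[str, BeatTemplate]] = None,
    pvc_rate: float = 0.0,
    pac_rate: float = 0.0,
    fs: float = 250.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, list[BeatAnnotation], list[RhythmEpisode]]:
    """Render one record from a rhythm plan.

    Beats are placed at cumulative RR times drawn from each episode's RR
    model.  Each beat is normal except for independent PVC/PAC substitutions
    (a PAC additionally arrives 20% early, shortening the preceding RR).
    Returned annotations are exact ground truth for the rendered signal;
    episode spans reflect the plan exactly.
    """
    if templates is None:
        templates = DEFAULT_TEMPLATES
    if not plan.episodes:
        raise ValueError("empty rhythm plan")
    if not (0 <= pvc_rate <= 1 and 0 <= pac_rate <= 1 and pvc_rate + pac_rate <= 1):
        raise ValueError("substitution rates must be probabilities summing to <= 1")
    if rng is None:
        rng = np.random.default_rng()
    for tmpl in templates.values():
        render_beat(tmpl, fs)  # validates fs against every template

    bounds_s = np.concatenate([[0.0], np.cumsum([e.duration_s for e in plan.episodes])])
    total = int(round(bounds_s[-1] * fs))
    y = np.zeros(total)
    beat_times: list[float] = []
    beat_codes: list[str] = []
    for ep, start_s, end_s in zip(plan.episodes, bounds_s[:-1], bounds_s[1:]):
        t = start_s + 0.5 * ep.rr_model.mean_rr_s
        while t < end_s:
            rr = ep.rr_model.draw(rng)
            u = rng.random()
            if u < pvc_rate:
                code = "PVC"
            elif u < pvc_rate + pac_rate:
                code = "PAC"
                t_beat = t - 0.2 * rr  # premature arrival
                if beat_times and t_beat <= beat_times[-1] + 0.2:
                    t_beat = t
                beat_times.append(t_beat)
                beat_codes.append(code)
                t += rr
                continue
            else:
                code = "N"
            beat_times.append(t)
            beat_codes.append(code)
            t += rr

    beats: list[BeatAnnotation] = []
    prev = -1
    for t, code in zip(beat_times, beat_codes):
        r_idx = int(round(t * fs))
        if not 0 <= r_idx < total or r_idx <= prev:
            continue
        wave, r_off = render_beat(templates[code], fs)
        lo = r_idx - r_off
        hi = lo + wave.size
        s0, s1 = max(lo, 0), min(hi, total)
        y[s0:s1] += wave[s0 - lo : s1 - lo]
        beats.append(BeatAnnotation(r_idx, BEAT_SYMBOL[code]))
        prev = r_idx
    if noise_sd > 0:
        y += noise_sd * rng.standard_normal(total)

    episodes: list[RhythmEpisode] = []
    for ep, start_s, end_s in zip(plan.episodes, bounds_s[:-1], bounds_s[1:]):
        s0, s1 = int(round(start_s * fs)), int(round(end_s * fs))
        if s1 > s0:
            episodes.append(RhythmEpisode(s0, s1, RHYTHM_SYMBOL[ep.code]))
    return y, beats, episodes


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _patient_mixture(
    mixture: dict[str, float], rng: np.random.Generator, concentration: float = 12.0
) -> dict[str, float]:
    """Perturb the global mixture per patient (Dirichlet around the mixture)
    so patients differ in class composition; expectation is preserved."""
    codes = sorted(mixture)
    alpha = np.array([max(mixture[c], 1e-3) for c in codes]) * concentration
    p = rng.dirichlet(alpha)
    return dict(zip(codes, p))


def _sample_plan(
    duration_s: float, mixture: dict[str, float], rng: np.random.Generator
) -> RhythmPlan:
    codes = sorted(mixture)
    probs = np.array([mixture[c] for c in codes])
    probs = probs / probs.sum()
    episodes: list[EpisodeSpec] = []
    remaining = duration_s
    while remaining > 1e-9:
        dur = float(min(remaining, rng.uniform(6.0, 15.0)))
        if remaining - dur < 3.0:
            dur = remaining
        code = str(rng.choice(codes, p=probs))
        if episodes and episodes[-1].code == code:
            episodes[-1] = replace(
                episodes[-1], duration_s=episodes[-1].duration_s + dur
            )
        else:
            episodes.append(EpisodeSpec(code, dur, DEFAULT_RR[code]))
        remaining -= dur
    return RhythmPlan(episodes)


def generate_beat_level_dataset(
    cfg: GeneratorConfig, out_dir: str | Path, name: str = "synth"
) -> DatasetHandle:
    """Write a beat-level annotated dataset (signals + beat/rhythm annotation
    files) and return a handle onto it.

    Per-patient class mixtures and ectopic-beat rates are drawn around the
    configured values so that patients differ, which is what makes
    stratified patient splits non-trivial to test.
    """
    rng = np.random.default_rng(cfg.seed)
    ddir = Path(out_dir) / name
    records: list[tuple[str, str]] = []
    for p in range(cfg.n_patients):
        pid = f"p{p:04d}"
        mix = _patient_mixture(cfg.class_mixture, rng)
        pvc = min(cfg.pvc_rate * rng.uniform(0.5, 1.5), 0.5)
        pac = min(cfg.pac_rate * rng.uniform(0.5, 1.5), 0.5)
        for r in range(cfg.records_per_patient):
            rid = f"{pid}r{r:02d}"
            plan = _sample_plan(cfg.record_duration_s, mix, rng)
            y, beats, episodes = generate_record(
                plan, pvc_rate=pvc, pac_rate=pac, fs=cfg.fs,
                noise_sd=cfg.noise_sd, rng=rng,
            )
            write_record(
                ddir, rid, cfg.fs, {"II": y}, pid, beats=beats,
                rhythm_points=[(e.start, e.symbol) for e in episodes],
            )
            records.append((rid, pid))
    write_dataset_meta(ddir, name, BEAT_LEVEL, ["II"], records)
    return open_dataset(Path(out_dir), name, lead="II")


def generate_recording_level_dataset(
    cfg: GeneratorConfig, out_dir: str | Path, name: str = "synth_rec"
) -> DatasetHandle:
    """Write a recording-level dataset: short single-class records (default
    10 s) with one label each in a CSV label table."""
    rng = np.random.default_rng(cfg.seed)
    ddir = Path(out_dir) / name
    codes = sorted(cfg.class_mixture)
    probs = np.array([cfg.class_mixture[c] for c in codes])
    records: list[tuple[str, str]] = []
    label_rows: list[tuple[str, str, list[str]]] = []
    for p in range(cfg.n_patients):
        pid = f"p{p:04d}"
        for r in range(cfg.records_per_patient):
            rid = f"{pid}r{r:02d}"
            code = str(rng.choice(codes, p=probs))
            plan = RhythmPlan.from_codes([(code, cfg.record_duration_s)])
            y, _, _ = generate_record(
                plan, fs=cfg.fs, noise_sd=cfg.noise_sd, rng=rng
            )
            write_record(ddir, rid, cfg.fs, {"II": y}, pid)
            records.append((rid, pid))
            label_rows.append((rid, pid, [RHYTHM_SYMBOL[code]]))
    write_dataset_meta(ddir, name, RECORDING_LEVEL, ["II"], records)
    write_label_table(ddir, label_rows)
    return open_dataset(Path(out_dir), name, lead="II")


def beat_dataset_in_memory(
    n_per_class: int,
    duration_s: float = 0.72,
    fs: float = 250.0,
    noise_sd: float = 0.05,
    classes: tuple[str, ...] = ("N", "PAC", "PVC"),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: a balanced array of single-beat segments (one beat
    centered in each window) and integer labels, for classifier smoke tests."""
    rng = np.random.default_rng(seed)
    w = int(round(duration_s * fs))
    X = np.zeros((n_per_class * len(classes), w))
    y = np.zeros(n_per_class * len(classes), dtype=int)
    i = 0
    for ci, code in enumerate(classes):
        for _ in range(n_per_class):
            wave, r_off = render_beat(DEFAULT_TEMPLATES[code], fs)
            seg = np.zeros(w)
            lo = w // 2 - r_off
            hi = lo + wave.size
            s0, s1 = max(lo, 0), min(hi, w)
            seg[s0:s1] = wave[s0 - lo : s1 - lo]
            # small amplitude/timing variation plus noise
            seg = np.roll(seg, rng.integers(-3, 4)) * rng.uniform(0.9, 1.1)
            seg += noise_sd * rng.standard_normal(w)
            X[i], y[i] = seg, ci
            i += 1
    return X, y
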