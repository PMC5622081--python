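"""Synthetic neonatal EEG cohorts with word-locked ERP structure.

The forward model injects, on top of 1/f + white background noise, a
fronto-central ERP component whose amplitude evolves across the learning
stream (block-1 -> block-2 dynamics, different for flat vs. melodically
enriched streams), and — for illegal word-forms in the melodic test stream
only — positive mismatch responses in the 300–400 and 800–900 ms windows.
Each subject also receives an 18-month expressive-vocabulary outcome (MCDI)
generated from a linear model on the melodic learning dynamic and the second
mismatch response, so that the downstream regression/cross-validation layer
has a recoverable ground truth.

Subject traits are expressed on the all-channel-mean scale: the spatial
topography of every injected component averages to 1 over the 16 scalp
channels (fronto-central maximum ≈ 1.4), so a trait of 1 μV produces a 1 μV
all-channel mean amplitude after the reference pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stimgen
from .erp_pipeline import ALL_CHANNELS, FS, Recording, SCALP_CHANNELS

PHASES = ("learning", "test")
CONDITIONS = ("flat", "melodic")

# Fronto-central topography, normalised to mean 1.0 over the 16 scalp
# channels. Relative profile: maximum at Fz/Cz, low occipital weight.
_TOPO_RAW = {
    "Fp1": 0.85, "Fp2": 0.85, "F3": 0.95, "F4": 0.95, "Fz": 1.0,
    "T7": 0.55, "C3": 0.90, "C4": 0.90, "Cz": 1.0, "T8": 0.55,
    "P3": 0.50, "P4": 0.50, "Pz": 0.55, "O1": 0.10, "O2": 0.10, "Oz": 0.10,
}
_TOPO_MEAN = float(np.mean([_TOPO_RAW[c] for c in SCALP_CHANNELS]))
TOPOGRAPHY = {c: _TOPO_RAW[c] / _TOPO_MEAN for c in SCALP_CHANNELS}


@dataclass
class EffectParams:
    """Population-level generative parameters (all amplitudes in μV on the
    all-channel-mean scale; SDs are across-subject)."""

    # Learning phase: block-1 / block-2 mean amplitudes (200–500 ms).
    block_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"flat": (0.35, -0.11), "melodic": (-0.48, 0.88)})
    block_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"flat": (1.41, 1.72), "melodic": (1.65, 2.36)})
    # Test phase: mismatch (illegal − legal) amplitudes in the two windows.
    mmr_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"flat": (0.0, 0.0), "melodic": (1.06, 1.10)})
    mmr_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"flat": (0.0, 0.0), "melodic": (1.50, 1.08)})
    # Outcome model: MCDI = b0 + b1·L_melody + b2·TW2_melody + N(0, sd).
    mcdi_coefs: tuple[float, float, float] = (47.575, 6.263, -22.929)
    mcdi_noise_sd: float = 27.4
    # BSID-III language subscale as a noisy affine transform of MCDI.
    bsid_slope: float = 0.1836
    bsid_intercept: float = 93.0
    bsid_noise_sd: float = 8.4
    # Background EEG noise (per-channel RMS) and artifact rate.
    noise_sd_uv: float = 15.0
    noise_sd_spread: float = 3.0
    artifact_rate_per_min: float = 0.5
    # Component windows (ms post word-onset).
    learning_window: tuple[float, float] = (200.0, 500.0)
    mmr_windows: tuple[tuple[float, float], ...] = ((300.0, 400.0), (800.0, 900.0))


def default_effect_params() -> EffectParams:
    """Generative defaults: flat blocks (+0.35, −0.11) μV, melodic blocks
    (−0.48, +0.88) μV, melodic mismatch ≈ 1.1 μV per window (≈1.4 μV
    fronto-centrally), flat mismatch 0."""
    return EffectParams()


@dataclass
class SubjectTraits:
    subject: str
    flat_blocks: tuple[float, float]
    melodic_blocks: tuple[float, float]
    tw1_melody: float
    tw2_melody: float
    noise_sd: float
    artifact_rate: float
    mcdi: float
    bsid_lang: float

    @property
    def l_flat(self) -> float:
        return self.flat_blocks[1] - self.flat_blocks[0]

    @property
    def l_melody(self) -> float:
        return self.melodic_blocks[1] - self.melodic_blocks[0]

    def block_means(self, condition: str) -> tuple[float, float]:
        return self.flat_blocks if condition == "flat" else self.melodic_blocks

    def mmr_amplitudes(self, condition: str) -> tuple[float, float]:
        if condition == "flat":
            return (0.0, 0.0)
        return (self.tw1_melody, self.tw2_melody)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["l_flat"] = self.l_flat
        d["l_melody"] = self.l_melody
        return d


def sample_cohort(n_subjects: int = 28, params: EffectParams | None = None,
                  seed: int | None = 0,
                  truncate_mcdi: bool = False) -> list[SubjectTraits]:
    """Draw per-subject latent ERP traits and linked vocabulary outcomes.

    Block amplitudes are independent Gaussians at the printed group mean/SD;
    the MCDI score is the linear model of L_melody and TW2_melody plus
    Gaussian noise. Under these population parameters roughly a fifth of the
    linear predictor's mass lies below zero, so clamping at zero
    (`truncate_mcdi=True`) censors the outcome and attenuates the generative
    coefficients well beyond their standard errors; the default keeps the
    linear model intact (occasional negative synthetic scores) so the
    coefficients remain identifiable.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    p = params or default_effect_params()
    for sds in (*p.block_sds.values(), *p.mmr_sds.values()):
        if any(s < 0 for s in sds):
            raise ValueError("trait SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        fb = tuple(rng.normal(m, s) for m, s in
                   zip(p.block_means["flat"], p.block_sds["flat"]))
        mb = tuple(rng.normal(m, s) for m, s in
                   zip(p.block_means["melodic"], p.block_sds["melodic"]))
        tw1, tw2 = (rng.normal(m, s) for m, s in
                    zip(p.mmr_means["melodic"], p.mmr_sds["melodic"]))
        l_mel = mb[1] - mb[0]
        b0, b1, b2 = p.mcdi_coefs
        mcdi = b0 + b1 * l_mel + b2 * tw2 + rng.normal(0.0, p.mcdi_noise_sd)
        if truncate_mcdi:
            mcdi = max(0.0, mcdi)
        bsid = (p.bsid_intercept + p.bsid_slope * mcdi
                + rng.normal(0.0, p.bsid_noise_sd))
        cohort.append(SubjectTraits(
            subject=f"sub-{i + 1:02d}",
            flat_blocks=(float(fb[0]), float(fb[1])),
            melodic_blocks=(float(mb[0]), float(mb[1])),
            tw1_melody=float(tw1), tw2_melody=float(tw2),
            noise_sd=float(max(1.0, rng.normal(p.noise_sd_uv, p.noise_sd_spread))),
            artifact_rate=float(max(0.0, p.artifact_rate_per_min)),
            mcdi=float(mcdi), bsid_lang=float(bsid),
        ))
    return cohort


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _background_noise(n_channels: int, n_samples: int, sd: float,
                      rng: np.random.Generator, fs: float = FS) -> np.ndarray:
    """Half 1/f ("pink"), half white noise by power, per-channel RMS = sd."""
    if sd == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    from scipy.signal import lfilter

    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    # Paul Kellet's 3-pole 1/f approximation (accurate to ~±0.5 dB over the
    # EEG band); the pink component is derived from the same white source,
    # giving a mixed 1/f-plus-white spectrum.
    b = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
    a = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])
    pink = lfilter(b, a, white, axis=1)
    rms = pink.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    pink /= rms
    mix = (pink + white) / np.sqrt(2.0)
    return (sd * mix).astype(np.float32)


def _component_kernel(window_ms: tuple[float, float], fs: float = FS
                      ) -> tuple[int, np.ndarray]:
    """Raised-cosine bump over the window, scaled so its mean over the window
    is exactly 1: a trait of a μV yields an a μV window-mean amplitude."""
    lo, hi = window_ms
    i0 = int(round(lo / 1000.0 * fs))
    i1 = int(round(hi / 1000.0 * fs))
    n = i1 - i0 + 1
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))
    return i0, bump / bump.mean()


def _ramp_amplitudes(b1: float, b2: float, n_trials: int) -> np.ndarray:
    """Per-trial linear amplitude ramp whose first-half and second-half means
    equal the latent block amplitudes (b1, b2)."""
    if n_trials == 1:
        return np.array([(b1 + b2) / 2.0])
    k = np.arange(n_trials, dtype=float)
    h = n_trials // 2
    m1, m2 = k[:h].mean(), k[h:].mean()
    slope = (b2 - b1) / (m2 - m1)
    return b1 + slope * (k - m1)


def simulate_recording(traits: SubjectTraits, stream: stimgen.Stream,
                       condition: str, phase: str,
                       effect_params: EffectParams | None = None,
                       seed: int | None = 0,
                       pad_s: float = 1.0) -> Recording:
    """Continuous 18-channel recording (16 scalp + M1/M2) at 250 Hz for one
    subject and phase, with the stream's word-locked components injected."""
    p = effect_params or default_effect_params()
    if stream.condition != condition:
        raise ValueError(f"stream condition {stream.condition!r} != {condition!r}")
    if stream.phase != phase:
        raise ValueError(f"stream phase {stream.phase!r} != {phase!r}")
    rng = np.random.default_rng(seed)
    pad = int(round(pad_s * FS))
    n_samples = int(round(stream.total_duration_ms / 1000.0 * FS)) + 2 * pad
    data = _background_noise(len(ALL_CHANNELS), n_samples, traits.noise_sd, rng)

    topo = np.array([TOPOGRAPHY[c] for c in SCALP_CHANNELS])
    onsets_ms = np.array([e.onset_ms for e in stream.events
                          if e.position_in_word == 1])
    onset_idx = np.round(onsets_ms / 1000.0 * FS).astype(int) + pad
    scalp_slice = slice(0, len(SCALP_CHANNELS))

    def inject(trial_idx: np.ndarray, amps: np.ndarray,
               window: tuple[float, float]) -> None:
        off, bump = _component_kernel(window)
        for i, a in zip(trial_idx, amps):
            s = onset_idx[i] + off
            data[scalp_slice, s:s + len(bump)] += a * topo[:, None] * bump[None, :]

    if phase == "learning":
        b1, b2 = traits.block_means(condition)
        amps = _ramp_amplitudes(b1, b2, len(onset_idx))
        inject(np.arange(len(onset_idx)), amps, p.learning_window)
    else:
        legality = np.array([e.legality for e in stream.events
                             if e.position_in_word == 1])
        illegal = np.flatnonzero(legality == "illegal")
        for w, amp in zip(p.mmr_windows, traits.mmr_amplitudes(condition)):
            inject(illegal, np.full(len(illegal), amp), w)

    # Artifact excursions: brief high-amplitude events on random channel
    # subsets, exponential-decay envelope, ±(120–300) μV peak.
    n_art = rng.poisson(traits.artifact_rate * n_samples / FS / 60.0)
    for _ in range(n_art):
        t0 = int(rng.integers(0, max(1, n_samples - 100)))
        dur = int(rng.integers(25, 100))
        chans = rng.choice(len(SCALP_CHANNELS),
                           size=rng.integers(1, 5), replace=False)
        peak = rng.uniform(120.0, 300.0) * rng.choice([-1.0, 1.0])
        env = peak * np.exp(-np.arange(dur) / (dur / 4.0))
        data[chans, t0:t0 + dur] += env[None, : data.shape[1] - t0]

    events = stream.to_frame()
    events["onset_ms"] = events["onset_ms"] + pad / FS * 1000.0
    return Recording(data=data, channels=ALL_CHANNELS, fs=FS, events=events,
                     subject=traits.subject, condition=condition, phase=phase)


# ---------------------------------------------------------------------------
# Cohort assembly and on-disk format
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    traits: list[SubjectTraits]
    languages: Mapping[str, Mapping[str, str]]  # subject -> condition -> language id
    seed: int | None = None


def assign_languages(traits: Sequence[SubjectTraits]) -> dict[str, dict[str, str]]:
    """Counterbalance language-to-condition assignment across subjects."""
    out = {}
    for i, t in enumerate(traits):
        if i % 2 == 0:
            out[t.subject] = {"flat": "L1", "melodic": "L2"}
        else:
            out[t.subject] = {"flat": "L2", "melodic": "L1"}
    return out


def subject_seed(master_seed: int, subject_index: int, condition: str,
                 phase: str) -> int:
    """Deterministic per-recording seed fan-out, kept below 2**31."""
    ci = CONDITIONS.index(condition)
    pi = PHASES.index(phase)
    ss = np.random.SeedSequence([master_seed, subject_index, ci, pi])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_cohort(n_subjects: int = 28, params: EffectParams | None = None,
                    seed: int = 0, learning_reps: int = 50,
                    legal_reps: int = 66, illegal_reps: int = 22):
    """Yield (traits, condition, phase, recording) for a full cohort.

    Streams are regenerated per subject/condition/phase with seeds fanned out
    from the master seed; condition order is flat first, as in the protocol.
    """
    p = params or default_effect_params()
    traits = sample_cohort(n_subjects, p, seed)
    langs = assign_languages(traits)
    for i, t in enumerate(traits):
        for condition in CONDITIONS:
            lang = stimgen.build_language(id=langs[t.subject][condition])
            lang = stimgen.assign_pitches(lang, condition)
            for phase in PHASES:
                s = subject_seed(seed, i, condition, phase)
                if phase == "learning":
                    stream = stimgen.generate_learning_stream(
                        lang, reps=learning_reps, seed=s)
                else:
                    stream = stimgen.generate_test_stream(
                        lang, legal_reps=legal_reps, illegal_reps=illegal_reps,
                        seed=s)
                rec = simulate_recording(t, stream, condition, phase, p, seed=s)
                yield t, condition, phase, rec


def write_recording(rec: Recording, directory: Path, stem: str) -> None:
    """Raw float32 binary (channel-major) + JSON header + events TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec.data.astype("<f4").tofile(directory / f"{stem}_eeg.bin")
    header = {
        "fs": rec.fs, "channels": list(rec.channels),
        "n_samples": int(rec.data.shape[1]), "dtype": "<f4", "units": "uV",
        "subject": rec.subject, "condition": rec.condition, "phase": rec.phase,
    }
    (directory / f"{stem}_eeg.json").write_text(json.dumps(header, indent=1))
    rec.events.to_csv(directory / f"{stem}_events.tsv", sep="\t", index=False)


def read_recording(directory: Path, stem: str) -> Recording:
    directory = Path(directory)
    header = json.loads((directory / f"{stem}_eeg.json").read_text())
    raw = np.fromfile(directory / f"{stem}_eeg.bin", dtype=header["dtype"])
    n_ch = len(header["channels"])
    if raw.size != n_ch * header["n_samples"]:
        raise ValueError(f"truncated or corrupt recording {stem!r}: "
                         f"{raw.size} values, expected {n_ch * header['n_samples']}")
    data = raw.reshape(n_ch, header["n_samples"]).astype(np.float64)
    events = pd.read_csv(directory / f"{stem}_events.tsv", sep="\t")
    return Recording(data=data, channels=tuple(header["channels"]),
                     fs=header["fs"], events=events, subject=header["subject"],
                     condition=header["condition"], phase=header["phase"])


def write_cohort(out_dir: Path, n_subjects: int = 28,
                 params: EffectParams | None = None, seed: int = 0) -> Path:
    """Simulate and write a cohort: per subject/phase recordings, an outcomes
    CSV, and a ground-truth traits sidecar for recovery tests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = []
    seen = set()
    for t, condition, phase, rec in simulate_cohort(n_subjects, params, seed):
        stem = f"{t.subject}_{condition}_{phase}"
        write_recording(rec, out_dir / t.subject, stem)
        if t.subject not in seen:
            truth.append(t.to_dict())
            seen.add(t.subject)
    outcomes = pd.DataFrame(
        [{"subject": t["subject"], "mcdi": t["mcdi"], "bsid_lang": t["bsid_lang"]}
         for t in truth])
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir
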