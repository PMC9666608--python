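"""Synthetic two-class oddball-ERP cohort generator.

Real pediatric oddball recordings of the kind this pipeline analyses
(midline electrodes, auditory + visual stimulation, 640 samples/s) are
rarely shareable, so every downstream stage is exercised against cohorts
drawn from an explicit generative model instead.

The model: each record is a sum of four band-limited Gaussian processes
(filtered white noise, one per clinical EEG band), a stereotyped biphasic
evoked deflection after each target stimulus, broadband sensor noise, and
optional super-threshold square artifacts.  Class structure is planted
purely as multiplicative band-power ratios (ADHD relative to control), the
weakest model under which every band-content feature downstream has an
analysable expectation.  The default ratios follow the classic ADHD EEG
profile: elevated slow-wave (Delta, Theta) power and a Beta deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BAND_NAMES",
    "CohortSpec",
    "StimulusSequence",
    "ERPRecord",
    "generate_stimulus_sequence",
    "synthesize_record",
    "generate_cohort",
]

BAND_NAMES = ("Delta", "Theta", "Alpha", "Beta")

# Generation band edges (Hz).  Delta is given a 0.5 Hz floor so that DC
# drift never dominates band power.
_GEN_BANDS = {
    "Delta": (0.5, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 12.0),
    "Beta": (13.0, 30.0),
}

# Control-group mean band power (uV^2), a roughly 1/f profile giving a
# background RMS near 8 uV — the order of magnitude of pediatric scalp EEG.
_DEFAULT_BASELINE_POWER = {
    "Delta": 25.0,
    "Theta": 16.0,
    "Alpha": 9.0,
    "Beta": 4.0,
}


def _default_band_effects() -> dict[str, float]:
    return {"Delta": 1.5, "Theta": 1.5, "Alpha": 1.0, "Beta": 0.6}


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort.

    Parameters
    ----------
    n_per_group : subjects per class (ADHD and control).
    sampling_rate : samples per second.
    n_stimuli : stimuli per run; record duration is ``n_stimuli * isi``.
    target_fraction : fraction of stimuli that are targets (exact count).
    isi : inter-stimulus interval in seconds.
    band_effects : ADHD/control multiplicative band-power ratio per band.
    power_jitter_sd : SD of per-record log-power jitter (biological
        between-record variability; 0 makes realized band power exact).
    noise_sd : broadband sensor-noise SD in uV.
    artifact_rate : square artifacts injected per record (integer count).
    artifact_amplitude : artifact plateau amplitude in uV (must exceed the
        +-100 uV rejection threshold to be seen by the cleaner).
    evoked_amplitude : peak amplitude in uV of the biphasic deflection
        added after each target stimulus.
    demographic_association : log-odds linking gender/first-child to class
        (0 means demographics are pure noise).
    seed : RNG seed; identical specs produce identical cohorts.
    """

    n_per_group: int = 30
    sampling_rate: float = 640.0
    n_stimuli: int = 200
    target_fraction: float = 0.20
    isi: float = 1.5
    electrodes: tuple[str, ...] = ("Fz", "Cz", "Pz")
    modalities: tuple[str, ...] = ("auditory", "visual")
    band_effects: dict[str, float] = field(default_factory=_default_band_effects)
    baseline_power: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_POWER)
    )
    power_jitter_sd: float = 0.3
    noise_sd: float = 2.0
    artifact_rate: int = 1
    artifact_amplitude: float = 150.0
    evoked_amplitude: float = 5.0
    demographic_association: float = 0.0
    seed: int = 0

    @property
    def duration(self) -> float:
        """Record duration in seconds (one full stimulation run)."""
        return self.n_stimuli * self.isi

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def n_targets(self) -> int:
        return int(round(self.n_stimuli * self.target_fraction))

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not (0.0 <= self.target_fraction <= 1.0):
            raise ValueError("target_fraction must lie in [0, 1]")
        n_targets = self.n_stimuli * self.target_fraction
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ValueError(
                f"n_stimuli * target_fraction = {n_targets} is not a whole "
                "number of target stimuli"
            )
        for band in BAND_NAMES:
            if self.band_effects.get(band, 1.0) <= 0:
                raise ValueError(f"band effect for {band} must be > 0")
            if self.baseline_power.get(band, 1.0) <= 0:
                raise ValueError(f"baseline power for {band} must be > 0")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 100.0:
            raise ValueError(
                "artifact_amplitude must exceed 100 uV so injected artifacts "
                "are visible to the rejection threshold"
            )
        nyquist = self.sampling_rate / 2.0
        if nyquist <= _GEN_BANDS["Beta"][1]:
            raise ValueError("sampling_rate too low for the Beta band")


@dataclass(frozen=True)
class StimulusSequence:
    """Onsets (s) and target flags of one oddball run."""

    onsets: np.ndarray
    is_target: np.ndarray

    def __post_init__(self):
        if len(self.onsets) != len(self.is_target):
            raise ValueError("onsets and is_target must have equal length")

    @property
    def n_targets(self) -> int:
        return int(np.count_nonzero(self.is_target))


@dataclass
class ERPRecord:
    """One electrode x stimulation-modality time series for one subject."""

    subject_id: str
    group_label: str  # "ADHD" | "control"
    modality: str  # "auditory" | "visual"
    electrode: str  # "Fz" | "Cz" | "Pz"
    sampling_rate: float
    signal: np.ndarray  # uV
    gender: str  # "M" | "F"
    first_child: bool

    @property
    def duration(self) -> float:
        return len(self.signal) / self.sampling_rate


def generate_stimulus_sequence(
    spec: CohortSpec, rng: np.random.Generator
) -> StimulusSequence:
    """Draw one oddball run: regular onsets, exact target count.

    Target positions are sampled uniformly without replacement, so the
    number of targets is exactly ``round(n_stimuli * target_fraction)``
    rather than binomial.
    """
    spec.validate()
    onsets = np.arange(spec.n_stimuli, dtype=float) * spec.isi
    is_target = np.zeros(spec.n_stimuli, dtype=bool)
    if spec.n_targets > 0:
        pos = rng.choice(spec.n_stimuli, size=spec.n_targets, replace=False)
        is_target[pos] = True
    return StimulusSequence(onsets=onsets, is_target=is_target)


def _evoked_kernel(sampling_rate: float, amplitude: float) -> np.ndarray:
    """Biphasic deflection (one Hann-windowed sine cycle, 600 ms)."""
    n = int(round(0.6 * sampling_rate))
    t = np.arange(n) / sampling_rate
    return amplitude * np.sin(2 * np.pi * t / 0.6) * np.hanning(n)


def _band_noise(
    n: int, lo: float, hi: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-power Gaussian noise confined to [lo, hi) Hz.

    Synthesized in the frequency domain (white Gaussian spectrum zeroed
    outside the band, inverse rFFT) so the process is exactly
    band-limited: planted band-power ratios are then not diluted by
    spectral leakage between neighbouring bands.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = np.zeros(len(freqs), dtype=complex)
    mask = (freqs >= lo) & (freqs < hi)
    k = int(mask.sum())
    if k == 0:
        raise ValueError(f"band {lo}-{hi} Hz contains no FFT bin at n={n}")
    spectrum[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spectrum, n=n)
    p = np.mean(x**2)
    return x / math.sqrt(p) if p > 0 else x


def synthesize_record(
    subject_meta: dict,
    modality: str,
    electrode: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> ERPRecord:
    """Synthesize one record for one (subject, modality, electrode) cell.

    The background is a sum over the four bands of band-limited noise whose
    expected power equals ``baseline_power[band] * band_effects[band]`` for
    ADHD subjects (control baseline otherwise), modulated by per-record
    log-normal jitter.  Targets in a fresh stimulus sequence each add the
    evoked kernel; broadband noise and square artifacts are added last.
    """
    spec.validate()
    n = spec.n_samples
    fs = spec.sampling_rate
    group = subject_meta["group_label"]
    x = np.zeros(n)

    for band in BAND_NAMES:
        power = spec.baseline_power[band]
        if group == "ADHD":
            power *= spec.band_effects[band]
        if spec.power_jitter_sd > 0:
            power *= math.exp(
                rng.normal(-spec.power_jitter_sd**2 / 2, spec.power_jitter_sd)
            )
        lo, hi = _GEN_BANDS[band]
        x += math.sqrt(power) * _band_noise(n, lo, hi, fs, rng)

    seq = generate_stimulus_sequence(spec, rng)
    if spec.evoked_amplitude != 0:
        kernel = _evoked_kernel(fs, spec.evoked_amplitude)
        for onset in seq.onsets[seq.is_target]:
            start = int(round(onset * fs))
            stop = min(start + len(kernel), n)
            if start < n:
                x[start:stop] += kernel[: stop - start]

    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=n)

    # Square artifacts: plateau set to +-artifact_amplitude so each one is
    # guaranteed to trip the |x| > 100 uV rejection rule.
    width = max(1, int(round(0.03 * fs)))
    for _ in range(int(spec.artifact_rate)):
        start = int(rng.integers(0, max(1, n - width)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x[start : start + width] = sign * spec.artifact_amplitude

    return ERPRecord(
        subject_id=subject_meta["subject_id"],
        group_label=group,
        modality=modality,
        electrode=electrode,
        sampling_rate=fs,
        signal=x,
        gender=subject_meta["gender"],
        first_child=subject_meta["first_child"],
    )


def _draw_demographics(
    group: str, assoc: float, rng: np.random.Generator
) -> tuple[str, bool]:
    # log-odds +assoc/2 for ADHD, -assoc/2 for control, for both attributes
    shift = assoc / 2 if group == "ADHD" else -assoc / 2
    p = 1.0 / (1.0 + math.exp(-shift))
    gender = "M" if rng.random() < p else "F"
    first_child = bool(rng.random() < p)
    return gender, first_child


def generate_cohort(spec: CohortSpec) -> list[ERPRecord]:
    """Generate the full labelled cohort: ``2 * n_per_group`` subjects,
    one record per (electrode, modality) pair each, reproducible from
    ``spec.seed`` alone."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[ERPRecord] = []
    n_total = 2 * spec.n_per_group
    for i in range(n_total):
        group = "ADHD" if i < spec.n_per_group else "control"
        gender, first_child = _draw_demographics(
            group, spec.demographic_association, rng
        )
        meta = {
            "subject_id": f"S{i + 1:03d}",
            "group_label": group,
            "gender": gender,
            "first_child": first_child,
        }
        for modality in spec.modalities:
            for electrode in spec.electrodes:
                records.append(
                    synthesize_record(meta, modality, electrode, spec, rng)
                )
    return records


def null_spec(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A copy of ``spec`` with all class effects removed (null cohort)."""
    base = spec if spec is not None else CohortSpec()
    return replace(
        base,
        band_effects={b: 1.0 for b in BAND_NAMES},
        demographic_association=0.0,
        **overrides,
    )
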