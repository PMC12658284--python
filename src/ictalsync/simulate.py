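"""Synthetic cyclic-seizure EEG cohorts with known ground truth.

The generator emulates the statistical structure the synchronization
analysis relies on, without any biophysical head modeling:

* cyclic recurrence of stereotyped nonconvulsive electrographic seizures
  (inter-onset intervals around a mean cycle period, optionally a
  two-component mixture to mimic clustering);
* a rhythmic ictal discharge whose frequency chirps linearly downward
  (default 6 Hz at onset to 2 Hz at termination), with raised-cosine
  amplitude ramps at both ends;
* genuinely lagged inter-channel coupling: a common ictal source drives
  both members of each configured electrode pair, the second member
  receiving a delayed, scaled copy — this is what imaginary coherence
  detects;
* a programmable multiplicative boost of the lagged-coupling gain during
  the final seconds of each seizure (terminal hypersynchronization);
* instantaneous volume-conduction mixing of all 8 channels through a
  near-identity matrix — zero-lag leakage that plain coherence would count
  as synchrony and imaginary coherence must reject;
* independent per-channel 1/f background noise.

Every cohort carries exact ground truth (marker times, coupled pairs,
boosted phase) so that downstream phase windowing, connectivity estimation
and mixed-model inference can be validated end to end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .io import MarkerSet, Recording, write_markers, write_recording
from .montage import DEFAULT_MONTAGE, Montage

#: background RMS in µV applied when rendering signals for EDF export
_OUTPUT_RMS_UV = 20.0


@dataclass(frozen=True)
class CoupledPair:
    """A lagged coupling between two electrodes: j receives the common ictal
    source delayed by ``lag_ms`` and scaled by ``gain``.

    The default sub-unity gain keeps the pair's low-frequency imaginary
    coherence mid-range (scalp-realistic, and with headroom for a terminal
    boost) instead of saturating toward 1.
    """

    i: str
    j: str
    lag_ms: float = 62.5  # quarter period at the 4 Hz band center
    gain: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters for one synthetic cyclic-seizure recording.

    Defaults mirror a neuro-ICU cyclic-seizure recording: 256 Hz sampling,
    seizures of 118 ± 34 s (floored at 21 s so the duration filter never
    rejects them) recurring every ~380 s (≈ 9/h, well above the 3/h
    cyclic-seizure threshold), an ictal rhythm slowing from 6 to 2 Hz, and
    an ictal-rhythm amplitude of 0.7× the background RMS (nonconvulsive
    discharges are not high-voltage on scalp; the narrowband rhythm still
    dominates its own frequency bins). ``terminal_boost`` multiplies the
    injection gain of every coupled pair — on both members — during the
    final ``terminal_window_s`` of each seizure.
    """

    fs: float = 256.0
    n_seizures: int = 50
    cycle_period_s: float = 380.0
    cycle_sd_s: float = 30.0
    duration_mean_s: float = 118.0
    duration_sd_s: float = 34.0
    duration_floor_s: float = 21.0
    f_start: float = 6.0
    f_end: float = 2.0
    coupled_pairs: tuple[CoupledPair, ...] = (CoupledPair("C3", "C4"),)
    terminal_boost: float = 1.0
    terminal_window_s: float = 10.0
    mixing: np.ndarray | None = None  # None -> I + 0.05 off-diagonal
    noise_exponent: float = 1.0  # power ∝ 1/f^exponent
    snr: float = 0.7  # ictal rhythm amplitude / background RMS
    ramp_s: float = 2.0
    lead_in_s: float = 660.0
    lead_out_s: float = 660.0
    clustered: bool = False
    cluster_long_period_s: float = 1200.0
    cluster_p_long: float = 0.15
    seed: int = 0
    montage: Montage = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        errors: list[str] = []
        if self.fs <= 0:
            errors.append("fs must be positive")
        if self.n_seizures < 1:
            errors.append("n_seizures must be at least 1")
        if not 0 < self.f_end <= self.f_start:
            errors.append("require 0 < f_end <= f_start")
        if self.duration_floor_s <= self.terminal_window_s:
            errors.append(
                "duration_floor_s must exceed terminal_window_s "
                "(the boosted terminal window must fit inside every seizure)"
            )
        if self.cycle_period_s <= self.duration_mean_s + 2 * self.duration_sd_s:
            errors.append(
                "cycle_period_s must exceed duration_mean_s + 2*duration_sd_s "
                "(seizures would overlap their successors)"
            )
        labels = self.montage.labels
        for p in self.coupled_pairs:
            if p.i not in labels or p.j not in labels:
                errors.append(f"coupled pair ({p.i}, {p.j}) references electrodes outside the montage")
            lag_samples = p.lag_ms * self.fs / 1000.0
            if abs(lag_samples - round(lag_samples)) > 1e-6:
                errors.append(
                    f"lag {p.lag_ms} ms is not a whole number of samples at fs={self.fs:g}"
                )
        mix = self.mixing
        if mix is not None:
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (8, 8):
                errors.append("mixing matrix must be 8x8")
            elif abs(np.linalg.det(mix)) < 1e-9:
                errors.append("mixing matrix must be invertible")
            object.__setattr__(self, "mixing", mix)
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))

    def mixing_matrix(self) -> np.ndarray:
        if self.mixing is not None:
            return self.mixing
        return np.eye(8) + 0.05 * (np.ones((8, 8)) - np.eye(8))


@dataclass(frozen=True)
class SimGroundTruth:
    """Exact generation record for a simulated cohort."""

    markers: MarkerSet
    coupled_pairs: tuple[CoupledPair, ...]
    terminal_boost: float
    boosted_phase: str = "termination"
    seed: int = 0


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, exponent: float) -> np.ndarray:
    """Independent unit-RMS noise with power ∝ 1/f^exponent per channel.

    Shaped in the frequency domain at the next fast FFT length and truncated,
    so generation cost does not depend on the prime factorization of ``n``.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n)
    white = rng.standard_normal((n_channels, n_fft))
    if exponent == 0:
        return white[:, :n]
    spec = rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_fft)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = irfft(spec * shaping, n=n_fft, axis=-1)[:, :n]
    rms = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(rms > 0, rms, 1.0)


def _draw_durations(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Truncated-normal seizure durations, floored at duration_floor_s."""
    out = np.empty(cfg.n_seizures)
    for k in range(cfg.n_seizures):
        for _ in range(1000):
            d = rng.normal(cfg.duration_mean_s, cfg.duration_sd_s)
            if d > cfg.duration_floor_s:
                out[k] = d
                break
        else:  # pathological sd; fall back to the floor
            out[k] = cfg.duration_floor_s + 1.0
    return out


def _draw_onsets(rng: np.random.Generator, cfg: SimConfig, durations: np.ndarray) -> np.ndarray:
    onsets = np.empty(cfg.n_seizures)
    onsets[0] = cfg.lead_in_s
    for k in range(1, cfg.n_seizures):
        if cfg.clustered and rng.uniform() < cfg.cluster_p_long:
            period, sd = cfg.cluster_long_period_s, cfg.cycle_sd_s
        else:
            period, sd = cfg.cycle_period_s, cfg.cycle_sd_s
        gap_floor = durations[k - 1] + cfg.terminal_window_s + 1.0
        interval = max(rng.normal(period, sd), gap_floor)
        onsets[k] = onsets[k - 1] + interval
    return onsets


def _chirp(t: np.ndarray, duration: float, cfg: SimConfig, phase0: float) -> np.ndarray:
    """Linear down-chirp with raised-cosine onset/offset ramps.

    ``t`` is time since seizure onset; samples outside [0, duration] are 0.
    """
    inside = (t >= 0) & (t <= duration)
    ts = np.where(inside, t, 0.0)
    # instantaneous frequency f(t) = f_start + (f_end - f_start) * t/duration
    sweep = (cfg.f_end - cfg.f_start) / duration
    phase = 2 * np.pi * (cfg.f_start * ts + 0.5 * sweep * ts**2) + phase0
    env = np.ones_like(ts)
    ramp = min(cfg.ramp_s, duration / 2)
    if ramp > 0:
        rising = ts < ramp
        falling = ts > duration - ramp
        env = np.where(rising, 0.5 * (1 - np.cos(np.pi * ts / ramp)), env)
        env = np.where(falling, 0.5 * (1 - np.cos(np.pi * (duration - ts) / ramp)), env)
    return np.where(inside, env * np.cos(phase), 0.0)


def simulate_cohort(config: SimConfig) -> tuple[Recording, SimGroundTruth]:
    """Generate one synthetic cyclic-seizure recording plus ground truth.

    Deterministic for a fixed config (including seed). The 8-channel source
    signal (noise + lagged ictal chirps) is left-multiplied sample-wise by
    the volume-conduction mixing matrix before being returned in µV.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    durations = _draw_durations(rng, cfg)
    onsets = _draw_onsets(rng, cfg, durations)
    terminations = onsets + durations
    total_s = float(np.ceil(terminations[-1] + cfg.lead_out_s))
    n = int(round(total_s * cfg.fs))

    sources = _pink_noise(rng, 8, n, cfg.noise_exponent)  # unit-RMS background

    t_axis = np.arange(n) / cfg.fs
    labels = cfg.montage.labels
    for k in range(cfg.n_seizures):
        onset, dur = onsets[k], durations[k]
        phase0 = rng.uniform(0, 2 * np.pi)
        # restrict evaluation to the seizure's sample range (plus max lag)
        max_lag_s = max((p.lag_ms for p in cfg.coupled_pairs), default=0.0) / 1000.0
        i0 = max(0, int(np.floor(onset * cfg.fs)))
        i1 = min(n, int(np.ceil((onset + dur + max_lag_s) * cfg.fs)) + 1)
        if i1 <= i0:
            continue
        t_local = t_axis[i0:i1] - onset
        boost_on = (t_local >= dur - cfg.terminal_window_s) & (t_local <= dur)
        boost_t = np.where(boost_on, cfg.terminal_boost, 1.0)
        for pair in cfg.coupled_pairs:
            lag_s = pair.lag_ms / 1000.0
            direct = _chirp(t_local, dur, cfg, phase0)
            delayed = _chirp(t_local - lag_s, dur, cfg, phase0)
            sources[cfg.montage.index(pair.i), i0:i1] += cfg.snr * boost_t * direct
            sources[cfg.montage.index(pair.j), i0:i1] += cfg.snr * boost_t * pair.gain * delayed

    mixed = cfg.mixing_matrix() @ sources
    recording = Recording(signal=_OUTPUT_RMS_UV * mixed, fs=cfg.fs, montage=cfg.montage)

    interictal: list[float] = []
    if cfg.lead_in_s >= 620.0:
        interictal.append(cfg.lead_in_s / 2.0)
    for k in range(cfg.n_seizures - 1):
        gap = onsets[k + 1] - terminations[k]
        if gap >= 610.0:
            interictal.append(terminations[k] + gap / 2.0)
    if cfg.lead_out_s >= 620.0:
        interictal.append(terminations[-1] + cfg.lead_out_s / 2.0)

    markers = MarkerSet(
        seizures=tuple((float(o), float(t)) for o, t in zip(onsets, terminations)),
        interictal=tuple(sorted(interictal)),
    )
    truth = SimGroundTruth(
        markers=markers,
        coupled_pairs=cfg.coupled_pairs,
        terminal_boost=cfg.terminal_boost,
        seed=cfg.seed,
    )
    return recording, truth


def write_cohort(recording: Recording, truth: SimGroundTruth, out_dir) -> dict[str, str]:
    """Persist a simulated cohort as EDF + marker CSV + ground-truth JSON.

    Returns the mapping of artifact names to paths. The EDF and marker files
    round-trip through :func:`ictalsync.io.read_recording` /
    :func:`ictalsync.io.read_markers`.
    """
    out_dir = str(out_dir)
    if not os.path.isdir(out_dir):
        try:
            os.makedirs(out_dir, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"cohort directory {out_dir} is not writable")

    paths = {
        "edf": os.path.join(out_dir, "cohort.edf"),
        "markers": os.path.join(out_dir, "markers.csv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_recording(paths["edf"], recording)
    write_markers(truth.markers, paths["markers"])
    payload = {
        "coupled_pairs": [
            {"i": p.i, "j": p.j, "lag_ms": p.lag_ms, "gain": p.gain}
            for p in truth.coupled_pairs
        ],
        "terminal_boost": truth.terminal_boost,
        "boosted_phase": truth.boosted_phase,
        "seed": truth.seed,
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    return paths


def read_ground_truth(path) -> SimGroundTruth:
    """Re-read the ground-truth JSON written by :func:`write_cohort`.

    Marker times live in the marker CSV; the returned object carries an
    empty MarkerSet.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    pairs = tuple(
        CoupledPair(i=p["i"], j=p["j"], lag_ms=p["lag_ms"], gain=p["gain"])
        for p in payload["coupled_pairs"]
    )
    return SimGroundTruth(
        markers=MarkerSet(),
        coupled_pairs=pairs,
        terminal_boost=payload["terminal_boost"],
        boosted_phase=payload.get("boosted_phase", "termination"),
        seed=payload.get("seed", 0),
    )
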