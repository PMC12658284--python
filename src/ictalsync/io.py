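"""EDF recording and seizure-marker I/O, plus seizure-selection filters.

Recordings are continuous multichannel scalp EEG stored as EDF/EDF+ (16-bit,
physical dimension µV). Seizure annotations travel as a small CSV with one
row per marker: ``kind,time_s,label`` where ``kind`` is one of ``onset``,
``termination`` or ``interictal``. EDF reading goes through :mod:`mne`;
writing uses a minimal 16-bit EDF encoder implemented here.
"""

from __future__ import annotations

import csv
import datetime
import warnings
from dataclasses import dataclass

import numpy as np

from .montage import DEFAULT_MONTAGE, Montage, normalize_label

#: minimum separation (s) between an inter-ictal marker and any seizure boundary
INTERICTAL_MIN_GAP_S = 300.0


class EdfFormatError(ValueError):
    """Raised for unreadable or structurally invalid EDF files."""


class MissingChannelError(KeyError):
    """Raised when a montage electrode is absent from an EDF file."""


class MarkerFormatError(ValueError):
    """Raised for malformed marker files (bad pairing, negative times, ...)."""


@dataclass(frozen=True)
class Recording:
    """Multichannel EEG signal in µV, channels in canonical montage order."""

    signal: np.ndarray  # (n_channels, n_samples) float64, µV
    fs: float
    montage: Montage = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be a (n_channels, n_samples) array")
        if sig.shape[0] != len(self.montage.labels):
            raise ValueError(
                f"signal has {sig.shape[0]} channels, montage has {len(self.montage.labels)}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.signal[self.montage.index(label)]


@dataclass(frozen=True)
class MarkerSet:
    """Seizure onset/termination pairs and inter-ictal marker times (s)."""

    seizures: tuple[tuple[float, float], ...] = ()
    interictal: tuple[float, ...] = ()
    excluded: frozenset[int] = frozenset()  # indices flagged for manual exclusion

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for i, (onset, term) in enumerate(self.seizures):
            if onset < 0 or term < 0:
                raise MarkerFormatError(f"seizure {i}: negative marker time")
            if onset >= term:
                raise MarkerFormatError(
                    f"seizure {i}: onset {onset} not before termination {term}"
                )
            if onset < prev_end:
                raise MarkerFormatError(f"seizure {i}: overlaps previous seizure")
            prev_end = term
        if any(t < 0 for t in self.interictal):
            raise MarkerFormatError("negative inter-ictal marker time")

    @property
    def n_seizures(self) -> int:
        return len(self.seizures)

    def durations(self) -> np.ndarray:
        return np.array([t - o for o, t in self.seizures])


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the seizure-selection filters."""

    n_input: int
    n_retained: int
    rejected: tuple[tuple[int, str], ...] = ()
    dropped_interictal: tuple[float, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_retained + len(self.rejected) != self.n_input:
            raise ValueError("selection report does not account for every input seizure")


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def write_recording(path, recording: Recording) -> None:
    """Write a Recording as 16-bit EDF with 1-s data records.

    The recording length must be a whole number of seconds and the sampling
    rate an integer, so that samples fill complete records.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record, per channel
    data = recording.signal
    n_ch, n = data.shape
    if n % spr != 0:
        raise ValueError(
            f"recording length {n} samples is not a whole number of 1-s records at fs={spr}"
        )
    n_rec = n // spr

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    # header fields carry 8 ascii chars; round physical extremes accordingly
    pmin = np.floor(pmin * 1e3) / 1e3
    pmax = np.ceil(pmax * 1e3) / 1e3

    start = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field(start.strftime("%d.%m.%y"), 8),
            _ascii_field(start.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (1 + n_ch), 8),
            _ascii_field("", 44),
            _ascii_field(n_rec, 8),
            _ascii_field("1", 8),
            _ascii_field(n_ch, 4),
        ]
    )
    header += b"".join(_ascii_field(f"EEG {lab}", 16) for lab in recording.montage.labels)
    header += b"".join(_ascii_field("AgAgCl cup electrode", 80) for _ in range(n_ch))
    header += b"".join(_ascii_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_ascii_field(f"{v:.3f}", 8) for v in pmin)
    header += b"".join(_ascii_field(f"{v:.3f}", 8) for v in pmax)
    header += b"".join(_ascii_field(_EDF_DIG_MIN, 8) for _ in range(n_ch))
    header += b"".join(_ascii_field(_EDF_DIG_MAX, 8) for _ in range(n_ch))
    header += b"".join(_ascii_field("", 80) for _ in range(n_ch))
    header += b"".join(_ascii_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_ascii_field("", 32) for _ in range(n_ch))

    gain = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.clip(
        np.round((data - pmin[:, None]) / gain[:, None] + _EDF_DIG_MIN),
        _EDF_DIG_MIN,
        _EDF_DIG_MAX,
    ).astype("<i2")

    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for r in range(n_rec):
                fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    except OSError as exc:
        raise OSError(f"cannot write EDF to {path}: {exc}") from exc


def read_recording(path, montage: Montage = DEFAULT_MONTAGE) -> Recording:
    """Read an EDF/EDF+ file and return channels in canonical montage order.

    Channel matching is case-insensitive and tolerant of clinical label
    decorations such as ``"EEG Fp1-Ref"``. A missing montage electrode is an
    explicit error naming the absent label.
    """
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various exception types on bad headers
        raise EdfFormatError(f"cannot read EDF file {path}: {exc}") from exc

    by_canonical: dict[str, int] = {}
    for idx, name in enumerate(raw.ch_names):
        canon = normalize_label(name)
        by_canonical.setdefault(canon, idx)

    order = []
    for lab in montage.labels:
        if lab not in by_canonical:
            raise MissingChannelError(f"channel {lab} not found in {path}")
        order.append(by_canonical[lab])

    data_uv = raw.get_data(picks=order, units="uV")
    return Recording(signal=np.asarray(data_uv, dtype=float), fs=float(raw.info["sfreq"]), montage=montage)


# ---------------------------------------------------------------------------
# Marker CSV I/O
# ---------------------------------------------------------------------------


def write_markers(markers: MarkerSet, path) -> None:
    """Write a MarkerSet as ``kind,time_s,label`` CSV (UTF-8, '.' decimals)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "time_s", "label"])
        for i, (onset, term) in enumerate(markers.seizures):
            label = "exclude" if i in markers.excluded else ""
            writer.writerow(["onset", repr(float(onset)), label])
            writer.writerow(["termination", repr(float(term)), ""])
        for t in markers.interictal:
            writer.writerow(["interictal", repr(float(t)), ""])


def read_markers(path) -> MarkerSet:
    """Parse a marker CSV into a MarkerSet.

    Onset and termination rows pair in file order; an onset opened before the
    previous one closes, or a dangling marker, is a pairing error reporting
    the seizure index.
    """
    seizures: list[tuple[float, float]] = []
    interictal: list[float] = []
    excluded: set[int] = set()
    open_onset: float | None = None
    open_excluded = False

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "kind" not in reader.fieldnames or "time_s" not in reader.fieldnames:
            raise MarkerFormatError(f"{path}: expected CSV header 'kind,time_s,label'")
        for lineno, row in enumerate(reader, start=2):
            kind = (row["kind"] or "").strip().lower()
            try:
                t = float(row["time_s"])
            except (TypeError, ValueError):
                raise MarkerFormatError(f"{path}:{lineno}: invalid time {row['time_s']!r}") from None
            if t < 0:
                raise MarkerFormatError(f"{path}:{lineno}: negative marker time {t}")
            label = (row.get("label") or "").strip().lower()
            if kind == "onset":
                if open_onset is not None:
                    raise MarkerFormatError(
                        f"{path}:{lineno}: onset at {t} s while seizure {len(seizures)} is still open"
                    )
                open_onset = t
                open_excluded = label == "exclude"
            elif kind == "termination":
                if open_onset is None:
                    raise MarkerFormatError(
                        f"{path}:{lineno}: termination at {t} s without a matching onset"
                    )
                if open_excluded:
                    excluded.add(len(seizures))
                seizures.append((open_onset, t))
                open_onset = None
                open_excluded = False
            elif kind == "interictal":
                interictal.append(t)
            else:
                raise MarkerFormatError(f"{path}:{lineno}: unknown marker kind {kind!r}")

    if open_onset is not None:
        raise MarkerFormatError(
            f"{path}: onset of seizure {len(seizures)} at {open_onset} s has no termination"
        )
    return MarkerSet(seizures=tuple(seizures), interictal=tuple(interictal), excluded=frozenset(excluded))


# ---------------------------------------------------------------------------
# Seizure selection
# ---------------------------------------------------------------------------


def select_seizures(
    markers: MarkerSet,
    min_duration_s: float = 20.0,
    min_count: int = 50,
    interictal_min_gap_s: float = INTERICTAL_MIN_GAP_S,
) -> tuple[MarkerSet, SelectionReport]:
    """Apply the seizure-selection filters.

    Retains seizures strictly longer than ``min_duration_s`` and not flagged
    as manually excluded; drops inter-ictal markers closer than
    ``interictal_min_gap_s`` to any retained seizure boundary. A retained
    count at or below ``min_count`` is reported as a warning, not an error,
    so that small cohorts remain analyzable.
    """
    retained: list[tuple[float, float]] = []
    rejected: list[tuple[int, str]] = []
    for i, (onset, term) in enumerate(markers.seizures):
        if i in markers.excluded:
            rejected.append((i, "manually excluded"))
        elif term - onset <= min_duration_s:
            rejected.append((i, f"duration ≤ {min_duration_s:g} s"))
        else:
            retained.append((onset, term))

    boundaries = np.array([t for sz in retained for t in sz]) if retained else np.empty(0)
    kept_ii: list[float] = []
    dropped_ii: list[float] = []
    for t in markers.interictal:
        if boundaries.size and np.min(np.abs(boundaries - t)) < interictal_min_gap_s:
            dropped_ii.append(t)
        else:
            kept_ii.append(t)

    warns: list[str] = []
    if len(retained) <= min_count:
        warns.append(
            f"retained seizure count {len(retained)} ≤ {min_count}; "
            "cohort below the cyclic-seizure selection threshold"
        )
    if dropped_ii:
        warns.append(
            f"dropped {len(dropped_ii)} inter-ictal marker(s) within "
            f"{interictal_min_gap_s:g} s of a seizure boundary"
        )

    selected = MarkerSet(seizures=tuple(retained), interictal=tuple(kept_ii))
    report = SelectionReport(
        n_input=markers.n_seizures,
        n_retained=len(retained),
        rejected=tuple(rejected),
        dropped_interictal=tuple(dropped_ii),
        warnings=tuple(warns),
    )
    return selected, report
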