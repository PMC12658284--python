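"""From recording + markers to phase-resolved synchrony tables.

Each seizure contributes four 10-s analysis phases anchored on its onset
and termination markers — pre-ictal [onset−w, onset), onset [onset, onset+w),
termination [term−w, term) and post-ictal [term, term+w) — and each
inter-ictal marker contributes the two windows flanking it. Per window an
8×8 connectivity matrix of low-frequency imaginary coherence is computed
over all 28 electrode pairs. Ictal-phase matrices are adjusted entrywise
against the inter-ictal baseline Z_ic (the elementwise mean over all
inter-ictal windows) as (Z_n − Z_ic) / Z_ic, so 0 means "at baseline" and
positive values mean hypersynchronization relative to the inter-ictal
state. Adjusted matrices are reduced to five regional averages and eight
per-electrode row-sum totals, emitted as a long-format table ready for
mixed-model inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerSet, Recording
from .montage import DEFAULT_MONTAGE, Montage, RegionMap, default_region_map
from .spectral import (
    DEFAULT_BANDS,
    DEFAULT_PARAMS,
    BandScheme,
    EstimationError,
    SpectralParams,
    _lf_icoh_from_ffts,
    _require_two_segments,
    _segment_ffts,
)

logger = logging.getLogger(__name__)

ICTAL_PHASES: tuple[str, ...] = ("pre_ictal", "onset", "termination", "post_ictal")
INTER_ICTAL = "inter_ictal"
PHASES: tuple[str, ...] = ICTAL_PHASES + (INTER_ICTAL,)


class BaselineError(ValueError):
    """Raised when no inter-ictal baseline can be formed."""


class DegenerateBaselineError(ValueError):
    """Raised when a baseline entry is too close to zero to normalize by."""


@dataclass(frozen=True)
class PhaseWindow:
    """One analysis window: [start_s, end_s), half-open in samples."""

    seizure_index: int | None
    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.start_s < self.end_s:
            raise ValueError("window start must precede end")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric 8×8 synchrony matrix, raw (in [0,1]) or baseline-adjusted."""

    values: np.ndarray
    kind: str  # "raw" or "adjusted"
    phase: str | None = None
    seizure_index: int | None = None
    montage: Montage = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (8, 8):
            raise ValueError(f"connectivity matrix must be 8x8, got {vals.shape}")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0):
            raise ValueError("connectivity matrix diagonal must be 0 by convention")
        if self.kind not in ("raw", "adjusted"):
            raise ValueError(f"kind must be 'raw' or 'adjusted', got {self.kind!r}")
        if self.kind == "raw":
            off = vals[~np.eye(8, dtype=bool)]
            if off.min() < 0 or off.max() > 1 + 1e-9:
                raise ValueError("raw connectivity entries must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.montage.index(a), self.montage.index(b)])

    def to_frame(self) -> pd.DataFrame:
        labs = list(self.montage.labels)
        return pd.DataFrame(self.values, index=labs, columns=labs)


def phase_windows(
    markers: MarkerSet,
    window_s: float = 10.0,
    recording_duration_s: float | None = None,
) -> list[PhaseWindow]:
    """Build the per-seizure ictal windows and per-marker inter-ictal windows.

    Windows extending beyond the recording bounds (when the duration is
    known) are dropped with a logged warning rather than raised.
    """
    w = float(window_s)
    candidates: list[PhaseWindow] = []
    for k, (onset, term) in enumerate(markers.seizures):
        candidates += [
            PhaseWindow(k, "pre_ictal", onset - w, onset),
            PhaseWindow(k, "onset", onset, onset + w),
            PhaseWindow(k, "termination", term - w, term),
            PhaseWindow(k, "post_ictal", term, term + w),
        ]
    for m in markers.interictal:
        candidates.append(PhaseWindow(None, INTER_ICTAL, m - w, m))
        candidates.append(PhaseWindow(None, INTER_ICTAL, m, m + w))

    kept: list[PhaseWindow] = []
    for win in candidates:
        out_of_bounds = win.start_s < 0 or (
            recording_duration_s is not None and win.end_s > recording_duration_s
        )
        if out_of_bounds:
            logger.warning(
                "dropping %s window [%.1f, %.1f) s of seizure %s: outside recording",
                win.phase,
                win.start_s,
                win.end_s,
                win.seizure_index,
            )
        else:
            kept.append(win)
    return kept


def _window_ffts(
    recording: Recording, window: PhaseWindow, params: SpectralParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch segment FFTs over a window (freqs, F[8, n_seg, n_f])."""
    fs = recording.fs
    # markers between samples resolve to the nearest earlier sample
    i0 = int(np.floor(window.start_s * fs + 1e-9))
    i1 = int(np.floor(window.end_s * fs + 1e-9))
    if i0 < 0 or i1 > recording.n_samples:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}) s lies outside the recording"
        )
    segment = recording.signal[:, i0:i1]
    freqs, _, F = _segment_ffts(segment, fs, params)
    _require_two_segments(F)
    return freqs, F


def connectivity_matrix(
    recording: Recording,
    window: PhaseWindow,
    params: SpectralParams = DEFAULT_PARAMS,
    scheme: BandScheme = DEFAULT_BANDS,
) -> ConnectivityMatrix:
    """Raw LF imaginary-coherence matrix over one analysis window.

    Entry (i, j) is the LF imaginary coherence of channels i and j over the
    window, computed for all 28 unordered pairs and mirrored; the diagonal
    is 0 by convention.
    """
    try:
        freqs, F = _window_ffts(recording, window, params)
    except EstimationError as exc:
        raise EstimationError(
            f"{exc} (window [{window.start_s}, {window.end_s}) s, phase {window.phase})"
        ) from exc

    values = np.zeros((8, 8))
    for i in range(8):
        for j in range(i + 1, 8):
            try:
                v = float(_lf_icoh_from_ffts(F[i], F[j], freqs, scheme))
            except EstimationError as exc:
                pair = (recording.montage.labels[i], recording.montage.labels[j])
                raise EstimationError(
                    f"{exc} (pair {pair}, window [{window.start_s}, {window.end_s}) s)"
                ) from exc
            values[i, j] = values[j, i] = v
    return ConnectivityMatrix(
        values=values,
        kind="raw",
        phase=window.phase,
        seizure_index=window.seizure_index,
        montage=recording.montage,
    )


def interictal_baseline(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of the inter-ictal connectivity matrices (Z_ic)."""
    if not matrices:
        raise BaselineError(
            "no inter-ictal connectivity matrices: the baseline adjustment "
            "(Z_n - Z_ic)/Z_ic cannot proceed without at least one"
        )
    stack = np.stack([m.values for m in matrices])
    return ConnectivityMatrix(
        values=stack.mean(axis=0),
        kind="raw",
        phase=INTER_ICTAL,
        montage=matrices[0].montage,
    )


def adjust_matrix(
    Zn: ConnectivityMatrix,
    Zic: ConnectivityMatrix,
    epsilon: float = 1e-6,
) -> ConnectivityMatrix:
    """Baseline-adjust a raw matrix entrywise: (Z_n − Z_ic) / Z_ic.

    Requires every off-diagonal baseline entry to exceed ``epsilon`` (the
    noise floor of the estimator guarantees this in practice); a degenerate
    entry raises an error naming the offending electrode pair.
    """
    off = ~np.eye(8, dtype=bool)
    small = off & (Zic.values <= epsilon)
    if np.any(small):
        i, j = np.argwhere(small)[0]
        labs = Zic.montage.labels
        raise DegenerateBaselineError(
            f"baseline entry for pair ({labs[i]}, {labs[j]}) is "
            f"{Zic.values[i, j]:.2e} <= {epsilon:g}; cannot normalize"
        )
    adjusted = np.zeros_like(Zn.values)
    adjusted[off] = (Zn.values[off] - Zic.values[off]) / Zic.values[off]
    return ConnectivityMatrix(
        values=adjusted,
        kind="adjusted",
        phase=Zn.phase,
        seizure_index=Zn.seizure_index,
        montage=Zn.montage,
    )


def regional_average(
    matrix: ConnectivityMatrix,
    region_map: RegionMap | None = None,
) -> dict[str, float]:
    """Mean connectivity over each region's five designated electrode pairs."""
    if region_map is None:
        region_map = default_region_map(matrix.montage)
    out: dict[str, float] = {}
    for region, pairs in region_map.regions.items():
        out[region] = float(np.mean([matrix.entry(a, b) for a, b in pairs]))
    return out


def electrode_totals(matrix: ConnectivityMatrix) -> dict[str, float]:
    """Row-sum total synchrony of each electrode (7 off-diagonal entries)."""
    sums = matrix.values.sum(axis=1)  # diagonal is 0
    return {lab: float(sums[k]) for k, lab in enumerate(matrix.montage.labels)}


def build_synchrony_table(
    recording: Recording,
    markers: MarkerSet,
    region_map: RegionMap | None = None,
    params: SpectralParams = DEFAULT_PARAMS,
    scheme: BandScheme = DEFAULT_BANDS,
    patient_id: str = "p01",
    window_s: float = 10.0,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Run the full windowing → connectivity → adjustment → reduction chain.

    Returns a long-format table with one row per (seizure, ictal phase,
    location) at both the region level (5 rows per seizure-phase) and the
    electrode level (8 rows). Seizures missing any of their four windows
    are omitted with a warning. ``adjusted=False`` emits raw reductions
    for descriptive displays; modeling uses the adjusted default.
    """
    if region_map is None:
        region_map = default_region_map(recording.montage)
    windows = phase_windows(markers, window_s, recording_duration_s=recording.duration_s)

    interictal_mats = [
        connectivity_matrix(recording, w, params, scheme)
        for w in windows
        if w.phase == INTER_ICTAL
    ]
    baseline = interictal_baseline(interictal_mats)

    by_seizure: dict[int, dict[str, PhaseWindow]] = {}
    for w in windows:
        if w.seizure_index is not None:
            by_seizure.setdefault(w.seizure_index, {})[w.phase] = w

    rows: list[tuple] = []
    for k in sorted(by_seizure):
        phase_map = by_seizure[k]
        if set(phase_map) != set(ICTAL_PHASES):
            logger.warning(
                "seizure %d omitted: only %d of 4 phase windows inside the recording",
                k,
                len(phase_map),
            )
            continue
        for phase in ICTAL_PHASES:
            raw = connectivity_matrix(recording, phase_map[phase], params, scheme)
            mat = adjust_matrix(raw, baseline) if adjusted else raw
            for region, value in regional_average(mat, region_map).items():
                rows.append((patient_id, k, phase, "region", region, value))
            for electrode, value in electrode_totals(mat).items():
                rows.append((patient_id, k, phase, "electrode", electrode, value))

    return pd.DataFrame(
        rows,
        columns=["patient_id", "seizure_index", "phase", "level", "location", "value"],
    )
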