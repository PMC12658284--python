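"""Reduced 10-20 scalp montage used for long-term neuro-ICU EEG monitoring.

The analysis operates on an 8-electrode montage — frontopolar (Fp1/Fp2),
central (C3/C4), temporal (T3/T4) and occipital (O1/O2) — yielding 28
unordered channel pairs for pairwise connectivity.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

DEFAULT_LABELS: tuple[str, ...] = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2")

_LEFT = frozenset({"Fp1", "C3", "T3", "O1"})
_POSITION = {
    "Fp1": "frontopolar",
    "Fp2": "frontopolar",
    "C3": "central",
    "C4": "central",
    "T3": "temporal",
    "T4": "temporal",
    "O1": "occipital",
    "O2": "occipital",
}

# Clinical EDF exports decorate electrode names ("EEG Fp1-Ref", "FP1-REF", ...).
_PREFIX = re.compile(r"^\s*EEG[\s_]*", re.IGNORECASE)
_SUFFIX = re.compile(r"[-_\s]*REF\s*$", re.IGNORECASE)


def normalize_label(raw: str) -> str:
    """Strip clinical decorations from an electrode label.

    ``"EEG Fp1-Ref"`` -> ``"Fp1"``; matching is case-insensitive, the
    canonical capitalization of the 10-20 name is restored when recognized.
    """
    name = _SUFFIX.sub("", _PREFIX.sub("", raw)).strip()
    for canonical in DEFAULT_LABELS:
        if name.lower() == canonical.lower():
            return canonical
    return name


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with hemisphere and anteroposterior maps."""

    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 8 or len(set(self.labels)) != 8:
            raise ValueError("montage requires exactly 8 unique electrode labels")

    @property
    def hemisphere_map(self) -> dict[str, str]:
        return {lab: ("left" if lab in _LEFT else "right") for lab in self.labels}

    @property
    def position_map(self) -> dict[str, str]:
        return {lab: _POSITION.get(lab, "unknown") for lab in self.labels}

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage {self.labels}") from None

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered electrode pairs (28 for the 8-channel montage)."""
        return list(itertools.combinations(self.labels, 2))


DEFAULT_MONTAGE = Montage()


@dataclass(frozen=True)
class RegionMap:
    """Assignment of five electrode pairs to each synchrony region.

    Regional synchrony is the mean connectivity over five designated
    electrode pairs per area: three anteroposterior regions (anterior,
    centrotemporal, posterior) and the two hemispheres (left, right).
    The assignment is configuration, not inference.
    """

    regions: dict[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)
    montage: Montage = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        for region, pairs in self.regions.items():
            if len(pairs) != 5:
                raise ValueError(
                    f"region {region!r} must list exactly 5 electrode pairs, got {len(pairs)}"
                )
            for a, b in pairs:
                for lab in (a, b):
                    if lab not in self.montage.labels:
                        raise ValueError(
                            f"region {region!r} references electrode {lab!r} outside the montage"
                        )
                if a == b:
                    raise ValueError(f"region {region!r} contains degenerate pair ({a}, {b})")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)


def default_region_map(montage: Montage = DEFAULT_MONTAGE) -> RegionMap:
    """Default five-pair regional assignment.

    Each region is anchored on its own electrodes; hemispheric regions use
    only within-hemisphere pairs. The assignment is logged with every run
    and fully configurable.
    """
    regions = {
        "anterior": (("Fp1", "Fp2"), ("Fp1", "C3"), ("Fp2", "C4"), ("Fp1", "T3"), ("Fp2", "T4")),
        "centrotemporal": (("C3", "C4"), ("T3", "T4"), ("C3", "T3"), ("C4", "T4"), ("C3", "T4")),
        "posterior": (("O1", "O2"), ("O1", "C3"), ("O2", "C4"), ("O1", "T3"), ("O2", "T4")),
        "left": (("Fp1", "C3"), ("Fp1", "T3"), ("C3", "T3"), ("C3", "O1"), ("T3", "O1")),
        "right": (("Fp2", "C4"), ("Fp2", "T4"), ("C4", "T4"), ("C4", "O2"), ("T4", "O2")),
    }
    return RegionMap(regions=regions, montage=montage)
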