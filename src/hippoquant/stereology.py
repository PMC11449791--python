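"""Stereology and scalar quantifications: Cavalieri volume, fractionator
counts, NanoSIMS isotope ratios, and marker co-expression percentages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotopeMeasurement",
    "cavalieri_volume",
    "fractionator_count",
    "isotope_ratio",
    "coexpression_percent",
]


@dataclass
class IsotopeMeasurement:
    """NanoSIMS ion counts for one ROI (12C14N- and 12C15N- channels)."""

    n15_counts: float
    n14_counts: float
    roi_label: str  # "positive" (e.g. PV+) or "negative"

    def __post_init__(self) -> None:
        if self.n15_counts < 0 or self.n14_counts < 0:
            raise ValueError("counts must be non-negative")

    @property
    def ratio(self) -> float:
        if self.n14_counts == 0:
            raise ValueError("n14 counts must be positive for a ratio")
        return self.n15_counts / self.n14_counts


def cavalieri_volume(
    areas: list[float], thickness_um: float = 50.0, series_factor: int = 6
) -> float:
    """Cavalieri estimate: sum of section areas x thickness x series factor.

    Units are the caller's: areas in mm^2 with thickness in mm give mm^3.
    """
    a = np.asarray(list(areas), dtype=float)
    if a.size and a.min() < 0:
        raise ValueError("section areas must be non-negative")
    return float(a.sum() * thickness_um * series_factor)


def fractionator_count(
    cells: list[set[str]], markers: list[str], series_factor: int = 6
) -> dict[str, float]:
    """Fractionator totals per marker and per marker intersection.

    ``cells`` holds one label-set per counted cell; every label must come
    from ``markers``. Counts (including pairwise co-localization, keyed
    ``"A+B"``) are scaled by the series sampling factor.
    """
    marker_set = set(markers)
    for c in cells:
        unknown = set(c) - marker_set
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")
    out: dict[str, float] = {}
    for m in markers:
        out[m] = sum(m in c for c in cells) * series_factor
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1:]:
            out[f"{m1}+{m2}"] = sum(
                m1 in c and m2 in c for c in cells
            ) * series_factor
    return out


def isotope_ratio(measurements: list[IsotopeMeasurement]) -> float:
    """Normalized 15N/14N: mean positive-ROI ratio over mean negative-ROI ratio."""
    pos = [m.ratio for m in measurements if m.roi_label == "positive"]
    neg = [m.ratio for m in measurements if m.roi_label == "negative"]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative ROI")
    return float(np.mean(pos) / np.mean(neg))


def coexpression_percent(
    cells: list[set[str]], base_marker: str, probe_marker: str
) -> float:
    """Percentage of ``base_marker`` cells that also carry ``probe_marker``."""
    base = [c for c in cells if base_marker in c]
    if not base:
        raise ValueError(f"no cells carry base marker {base_marker!r}")
    both = sum(probe_marker in c for c in base)
    return 100.0 * both / len(base)
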