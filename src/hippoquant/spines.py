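"""Dendritic spine classification, spine densities, and bouton detection.

The spine taxonomy follows the manual criteria used for hippocampal
interneurons: stubby (short, neckless), mushroom (clear head at least 1.5x
the neck, total length under 1.5 um), thin (long, or intermediate without a
discernible head). Boundary conventions are fixed as: stubby strictly
< 1 um; the mushroom head ratio is inclusive ("at least 1.5 times"); thin
takes over at length >= 1.5 um.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpineRecord",
    "classify_spine",
    "spine_density",
    "detect_boutons",
    "UNCLASSIFIED",
]

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class SpineRecord:
    """Geometry of one dendritic protrusion.

    ``head_diam_um`` is the maximum head diameter and ``neck_len_um`` the
    average neck length; both may be absent when the feature cannot be
    resolved. ``position_um`` is the distance from the soma along the
    dendrite.
    """

    length_um: float
    head_diam_um: float | None = None
    neck_len_um: float | None = None
    head_discernible: bool = False
    neck_present: bool = False
    position_um: float = 0.0
    true_class: str | None = None  # filled by the synthetic generator

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise ValueError("length_um must be >= 0")
        if self.head_diam_um is None:
            self.head_discernible = False


def classify_spine(s: SpineRecord) -> str:
    """Assign one of {stubby, mushroom, thin} to a spine.

    Rules, evaluated in order:

    1. stubby   — length < 1 um and no neck;
    2. mushroom — head discernible, head diameter >= 1.5 x neck length,
       and length < 1.5 um;
    3. thin     — length > 1.5 um, or length in [1, 1.5] um with no
       discernible head (length exactly 1.5 um goes to thin).

    A geometry satisfying no rule is labelled ``unclassified``.
    """
    if s.length_um < 1.0 and not s.neck_present:
        return "stubby"
    if (
        s.head_discernible
        and s.neck_len_um is not None
        and s.head_diam_um >= 1.5 * s.neck_len_um
        and s.length_um < 1.5
    ):
        return "mushroom"
    if s.length_um >= 1.5 or (1.0 <= s.length_um and not s.head_discernible):
        return "thin"
    log.info("spine satisfies no classification rule: %s", s)
    return UNCLASSIFIED


def spine_density(
    spines: list[SpineRecord],
    segment_bounds_um: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0),
) -> pd.DataFrame:
    """Spine counts and densities per dendritic segment plus the total.

    Segments are half-open ``[lo, hi)`` (a spine at exactly 50 um belongs
    to the 50-100 segment); spines beyond the last bound are excluded with
    a notice. The total row spans the full extent of the bounds.
    """
    bounds = np.asarray(segment_bounds_um, dtype=float)
    pos = np.array([s.position_um for s in spines])
    beyond = pos >= bounds[-1]
    if beyond.any():
        log.info("%d spines beyond %.0f um excluded", beyond.sum(), bounds[-1])
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        n = int(np.sum((pos >= lo) & (pos < hi)))
        rows.append(
            {"segment": f"{lo:.0f}-{hi:.0f}", "count": n,
             "density_per_um": n / (hi - lo)}
        )
    n_total = int(np.sum(~beyond))
    rows.append(
        {"segment": "total", "count": n_total,
         "density_per_um": n_total / (bounds[-1] - bounds[0])}
    )
    return pd.DataFrame(rows)


def detect_boutons(
    position_um: np.ndarray,
    brightness: np.ndarray,
    width_um: np.ndarray,
    excluded: np.ndarray | None = None,
    brightness_factor: float = 2.0,
    width_factor: float = 2.0,
) -> tuple[int, float, np.ndarray]:
    """En passant bouton detection along an axonal intensity profile.

    The axonal backbone brightness and width are the medians over the
    profile. Candidates are local brightness maxima; a candidate is an EPB
    when it is at least ``brightness_factor``x brighter and
    ``width_factor``x wider than the backbone. ``excluded`` marks
    candidates crossed by other axons (a manual criterion supplied as
    input). Returns (count, density per um, indices of accepted boutons).
    """
    from .emd import local_maxima

    pos = np.asarray(position_um, dtype=float)
    bri = np.asarray(brightness, dtype=float)
    wid = np.asarray(width_um, dtype=float)
    length = float(pos.max() - pos.min())
    if length < 10.0:
        raise ValueError("axonal profile must span at least 10 um")
    backbone_b = float(np.median(bri))
    backbone_w = float(np.median(wid))
    cand = local_maxima(bri)
    ok = (bri[cand] >= brightness_factor * backbone_b) & (
        wid[cand] >= width_factor * backbone_w
    )
    if excluded is not None:
        ok &= ~np.asarray(excluded, dtype=bool)[cand]
    accepted = cand[ok]
    return accepted.size, accepted.size / length, accepted
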