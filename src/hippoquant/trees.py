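"""Neuron morphologies (SWC) and Sholl analysis.

Sholl intersections are counted analytically: along each straight
parent→child segment the squared distance to the soma is a convex quadratic
in the segment parameter, so crossings of each sphere are found by root
counting on the (at most two) monotone pieces. A point landing exactly on a
sphere counts as a crossing once; grazing tangencies are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["NeuronTree", "ShollProfile", "read_swc", "write_swc", "sholl",
           "sholl_bruteforce"]


@dataclass
class NeuronTree:
    """SWC-semantics rooted tree: node ids, types, 3-D positions, parents."""

    ids: np.ndarray        # int
    types: np.ndarray      # int (1 = soma, 3 = dendrite)
    xyz: np.ndarray        # (n, 3) float, micrometres
    radius: np.ndarray     # float
    parent: np.ndarray     # int, -1 for the root
    soma_id: int

    @classmethod
    def from_rows(cls, rows, soma_id: int | None = None) -> "NeuronTree":
        rows = list(rows)
        ids = np.array([r[0] for r in rows], dtype=int)
        types = np.array([r[1] for r in rows], dtype=int)
        xyz = np.array([[r[2], r[3], r[4]] for r in rows], dtype=float)
        radius = np.array([r[5] for r in rows], dtype=float)
        parent = np.array([r[6] for r in rows], dtype=int)
        if soma_id is None:
            roots = ids[parent == -1]
            if roots.size != 1:
                raise ValueError("tree must have exactly one root")
            soma_id = int(roots[0])
        tree = cls(ids, types, xyz, radius, parent, soma_id)
        tree.validate()
        return tree

    def validate(self) -> None:
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        seen = set()
        index = {int(i): k for k, i in enumerate(self.ids)}
        for i, p in zip(self.ids, self.parent):
            if p != -1 and int(p) not in seen:
                raise ValueError("parent must precede child in SWC order")
            seen.add(int(i))
        if int(self.soma_id) not in index:
            raise ValueError("soma node missing")

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    def soma_xyz(self) -> np.ndarray:
        k = int(np.flatnonzero(self.ids == self.soma_id)[0])
        return self.xyz[k]

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(parent_xyz, child_xyz) arrays for every non-root node."""
        index = {int(i): k for k, i in enumerate(self.ids)}
        child = np.flatnonzero(self.parent != -1)
        par = np.array([index[int(p)] for p in self.parent[child]])
        return self.xyz[par], self.xyz[child]

    def max_radial_extent(self) -> float:
        return float(np.linalg.norm(self.xyz - self.soma_xyz(), axis=1).max())


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write("# SWC generated by hippoquant\n")
        for i, t, p, r, par in zip(
            tree.ids, tree.types, tree.xyz, tree.radius, tree.parent
        ):
            f.write(
                f"{i} {t} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {r:.17g} {par}\n"
            )


def read_swc(path: str | Path) -> NeuronTree:
    rows = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append(
                (int(parts[0]), int(parts[1]), float(parts[2]),
                 float(parts[3]), float(parts[4]), float(parts[5]),
                 int(parts[6]))
            )
    return NeuronTree.from_rows(rows)


@dataclass
class ShollProfile:
    """Intersections of the arbor with concentric spheres around the soma."""

    radii_um: np.ndarray
    intersections: np.ndarray
    step_um: float

    @property
    def total(self) -> int:
        return int(self.intersections.sum())


_SNAP_UM = 1e-6  # distances this close to a sphere count as on it


def _snap(d: float, r: float) -> float:
    return r if abs(d - r) < _SNAP_UM else d


def _segment_crossings(a: np.ndarray, b: np.ndarray, r: float) -> int:
    """Crossings of the sphere of radius ``r`` by the segment a→b.

    Distance to the origin along the segment is convex with at most one
    internal minimum; on each monotone piece a crossing is counted when
    ``min(d) < r <= max(d)`` — i.e. landing exactly on the sphere counts,
    grazing without reaching does not. Distances within 1 nm of the sphere
    are snapped onto it so a node sitting on a sphere is treated
    consistently by its two adjacent segments.
    """
    v = b - a
    vv = float(v @ v)
    if vv == 0:
        return 0
    t_star = float(np.clip(-(a @ v) / vv, 0.0, 1.0))
    d0 = _snap(float(np.linalg.norm(a)), r)
    d1 = _snap(float(np.linalg.norm(b)), r)
    dm = _snap(float(np.linalg.norm(a + t_star * v)), r)
    count = 0
    for da, db in ((d0, dm), (dm, d1)):
        lo, hi = (da, db) if da <= db else (db, da)
        if lo < r <= hi:
            count += 1
    return count


def sholl(tree: NeuronTree, step_um: float) -> ShollProfile:
    """Sholl profile at radii ``step, 2*step, …`` up to the arbor extent.

    Distances are Euclidean 3-D from the soma node; crossings are counted
    per parent-child segment with within-segment linear interpolation.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    soma = tree.soma_xyz()
    pa, ch = tree.segments()
    pa = pa - soma
    ch = ch - soma
    rmax = tree.max_radial_extent()
    radii = np.arange(step_um, rmax + _SNAP_UM, step_um)
    counts = np.zeros(radii.size, dtype=int)
    for j, r in enumerate(radii):
        counts[j] = sum(
            _segment_crossings(pa[k], ch[k], float(r)) for k in range(pa.shape[0])
        )
    return ShollProfile(radii, counts, step_um)


def sholl_bruteforce(
    tree: NeuronTree, step_um: float, ds_um: float = 0.01
) -> ShollProfile:
    """Brute-force oracle: sample every segment densely and count sign
    changes of (distance − r), treating distance == r as 'outside'."""
    soma = tree.soma_xyz()
    pa, ch = tree.segments()
    rmax = tree.max_radial_extent()
    radii = np.arange(step_um, rmax + _SNAP_UM, step_um)
    counts = np.zeros(radii.size, dtype=int)
    for k in range(pa.shape[0]):
        a, b = pa[k] - soma, ch[k] - soma
        length = float(np.linalg.norm(b - a))
        n = max(int(np.ceil(length / ds_um)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:]  # exclude the shared parent node
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
        pts[-1] = b  # land exactly on the shared child node
        d = np.linalg.norm(pts, axis=1)
        d0 = float(np.linalg.norm(a))
        for j, r in enumerate(radii):
            dd = np.concatenate([[d0], d])
            on = np.abs(dd - r) < _SNAP_UM
            s = (dd >= r) | on
            counts[j] += int(np.sum(s[1:] != s[:-1]))
    return ShollProfile(radii, counts, step_um)
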