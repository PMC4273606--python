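"""Neuron morphometry: Sholl profiles, spine density and bouton size classes.

Operates on reconstructed neuron skeletons in SWC form (node id, type,
x, y, z, radius, parent; coordinates in µm) and on manually counted
structures (spines per dendrite, traced bouton areas).  Detection of
spines or boutons from rasters is out of scope — counts, lengths and
areas are inputs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SwcNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


class NeuronTree:
    """Rooted 3-D neuron skeleton with SWC semantics.

    Exactly one root (parent −1); every other node's parent must exist;
    the graph must be a single connected tree.  Structural violations
    raise ``ValueError`` naming the problem.
    """

    def __init__(self, nodes: list[SwcNode]):
        if not nodes:
            raise ValueError("tree has no nodes")
        ids = [n.id for n in nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        self._by_id = {n.id: n for n in nodes}
        roots = [n for n in nodes if n.parent == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n in nodes:
            if n.parent != -1 and n.parent not in self._by_id:
                raise ValueError(f"node {n.id} references missing parent {n.parent}")
        # connectivity + acyclicity: walk up from every node to the root
        for n in nodes:
            seen = set()
            cur = n
            while cur.parent != -1:
                if cur.id in seen:
                    raise ValueError(f"cycle detected at node {cur.id}")
                seen.add(cur.id)
                cur = self._by_id[cur.parent]
            if cur.id != self.root.id:
                raise ValueError(f"node {n.id} is disconnected from the root")
        self.nodes = list(nodes)

    # -- geometry ----------------------------------------------------------

    def positions(self) -> dict[int, np.ndarray]:
        return {n.id: np.array([n.x, n.y, n.z]) for n in self.nodes}

    def edges(self) -> list[tuple[int, int]]:
        """(parent_id, child_id) for every non-root node."""
        return [(n.parent, n.id) for n in self.nodes if n.parent != -1]

    def total_cable_length(self) -> float:
        pos = self.positions()
        return float(sum(np.linalg.norm(pos[c] - pos[p])
                         for p, c in self.edges()))

    def tips(self) -> list[int]:
        parents = {n.parent for n in self.nodes}
        return [n.id for n in self.nodes
                if n.id not in parents and n.parent != -1]

    def transformed(self, rotation=None, offset=(0.0, 0.0, 0.0)) -> "NeuronTree":
        """Rigidly re-posed copy (rotation matrix about origin, then shift)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        off = np.asarray(offset, float)
        out = []
        for n in self.nodes:
            p = R @ np.array([n.x, n.y, n.z]) + off
            out.append(SwcNode(n.id, n.type_code, float(p[0]), float(p[1]),
                               float(p[2]), n.radius, n.parent))
        return NeuronTree(out)

    # -- SWC I/O -----------------------------------------------------------

    def to_swc(self, path=None) -> str:
        """Serialise as 7-column whitespace-separated SWC (µm)."""
        buf = io.StringIO()
        buf.write("# id type x y z radius parent\n")
        for n in sorted(self.nodes, key=lambda m: m.id):
            buf.write(f"{n.id} {n.type_code} {n.x:.6f} {n.y:.6f} "
                      f"{n.z:.6f} {n.radius:.6f} {n.parent}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_swc(cls, source) -> "NeuronTree":
        """Parse SWC from a path or a literal string ('#' lines are comments)."""
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        nodes = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            nodes.append(SwcNode(int(parts[0]), int(parts[1]),
                                 float(parts[2]), float(parts[3]),
                                 float(parts[4]), float(parts[5]),
                                 int(parts[6])))
        return cls(nodes)


@dataclass
class ShollProfile:
    """Crossing counts of concentric circles centred at the tree stem."""

    radii: np.ndarray
    crossings: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.crossings = np.asarray(self.crossings, dtype=int)
        if self.radii.shape != self.crossings.shape:
            raise ValueError("radii and crossings must align")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly ascending")
        if np.any(self.crossings < 0):
            raise ValueError("crossings must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii,
                             "crossings": self.crossings})


def sholl_radii(r_start: float = 10.0, r_step: float = 10.0,
                r_end: float = 300.0) -> np.ndarray:
    """Radius grid {r_start, r_start+r_step, ..., <= r_end}."""
    if r_start <= 0 or r_step <= 0 or r_end < r_start:
        raise ValueError("need r_start > 0, r_step > 0, r_end >= r_start")
    n = int(np.floor((r_end - r_start) / r_step + 1e-9)) + 1
    return r_start + r_step * np.arange(n)


def sholl(tree: NeuronTree, r_start: float = 10.0, r_step: float = 10.0,
          r_end: float = 300.0, projection: str = "3d") -> ShollProfile:
    """Sholl profile: neurite crossings of concentric circles about the soma.

    For each radius ``r``, an edge (parent→child segment) whose endpoint
    distances from the root straddle ``r`` contributes one crossing; an
    edge spanning several circles contributes one crossing to each.  An
    endpoint lying exactly on a circle is counted with the edge arriving
    at it from inside (half-open rule ``d_min < r <= d_max``), so a touch
    is included exactly once along a path.  Distances are 3-D Euclidean by
    default; ``projection="xy"`` restricts to the xy-plane.
    """
    radii = sholl_radii(r_start, r_step, r_end)
    pos = tree.positions()
    root = pos[tree.root.id]
    if projection == "xy":
        def dist(p):
            return float(np.hypot(p[0] - root[0], p[1] - root[1]))
    elif projection == "3d":
        def dist(p):
            return float(np.linalg.norm(p - root))
    else:
        raise ValueError("projection must be '3d' or 'xy'")

    crossings = np.zeros(radii.shape, dtype=int)
    for parent, child in tree.edges():
        d1, d2 = dist(pos[parent]), dist(pos[child])
        lo, hi = (d1, d2) if d1 <= d2 else (d2, d1)
        crossings += (lo < radii) & (radii <= hi)
    return ShollProfile(radii=radii, crossings=crossings)


def spine_density(n_spines, dendrite_length_um):
    """Linear spine density: total spines divided by dendrite length (µm)."""
    n = np.asarray(n_spines, dtype=float)
    length = np.asarray(dendrite_length_um, dtype=float)
    if np.any(length <= 0):
        raise ValueError("dendrite length must be positive")
    if np.any(n < 0):
        raise ValueError("spine count must be non-negative")
    out = n / length
    return float(out) if out.ndim == 0 else out


def bouton_size_histogram(areas_um2, bin_width: float = 3.0) -> pd.DataFrame:
    """Percentage of boutons per size class.

    Size classes are half-open bins [0, w), [w, 2w), ... starting from
    0 µm² with ``bin_width`` w (default 3 µm²).  Returns bin edges, counts
    and percentages; percentages sum to 100 for non-empty input.  Empty
    input yields an empty (flagged) table.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        warnings.warn("no bouton areas supplied; histogram is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=["bin_left_um2", "bin_right_um2",
                                     "count", "percent"])
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    n_bins = int(np.floor(areas.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.floor(areas / bin_width).astype(int)  # half-open by construction
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame({
        "bin_left_um2": edges[:-1],
        "bin_right_um2": edges[1:],
        "count": counts,
        "percent": 100.0 * counts / counts.sum(),
    })


def compare_profiles(group_profiles: dict[str, list[ShollProfile]]) -> pd.DataFrame:
    """Per-radius mean, SEM and n for groups of Sholl profiles.

    All profiles must share one radius grid.  Returns a tidy long table
    (group, radius_um, mean, sem, n) ready for downstream statistics;
    group-comparison testing itself is delegated to standard packages.
    With a single profile the SEM is undefined and reported as NaN.
    """
    if not group_profiles:
        raise ValueError("no groups supplied")
    ref = None
    rows = []
    for group, profiles in group_profiles.items():
        if not profiles:
            raise ValueError(f"group {group!r} has no profiles")
        for p in profiles:
            if ref is None:
                ref = p.radii
            elif not np.array_equal(p.radii, ref):
                raise ValueError("all profiles must share the radius grid")
        mat = np.vstack([p.crossings for p in profiles]).astype(float)
        n = mat.shape[0]
        mean = mat.mean(axis=0)
        sem = (mat.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
            else np.full(mat.shape[1], np.nan)
        for r, m, s in zip(ref, mean, sem):
            rows.append({"group": group, "radius_um": r, "mean": m,
                         "sem": s, "n": n})
    return pd.DataFrame(rows, columns=["group", "radius_um", "mean", "sem", "n"])
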