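"""Ground-truthed synthetic data: marked cell populations, rendered scenes,
and neuron trees.

The generator encodes the statistical premise of combinatorial colour
marking: per-cell vector copy numbers are independent Poisson draws per
colour, channel intensity is proportional to copy number with a shared
per-cell expression factor (so the intensity *ratios* — the hue — are a
property of the copy-number combination, not of expression level), plus
additive autofluorescence background and multiplicative channel noise.
Every downstream stage of the pipeline can therefore be tested against
known truth without any acquired data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as _draw_ellipse
from skimage.filters import gaussian as _gaussian

from .model import VectorSet, class_of_pattern
from .morphometry import NeuronTree, SwcNode

log = logging.getLogger(__name__)

_TRUTH_COLUMNS = [
    "cell_id", "copies_r", "copies_g", "copies_b", "expr_factor",
    "intensity_r", "intensity_g", "intensity_b", "row", "col",
    "truth_class", "saturated", "clone_id",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise structure of the intensity model.

    Parameters
    ----------
    expr_cv
        Coefficient of variation of the per-cell expression factor
        (lognormal, mean 1) shared across channels.  Default 0.35,
        a typical cell-to-cell spread of transgene expression.
    channel_cv
        Independent multiplicative Gaussian noise per channel (CV).
    autofluor_mean
        Additive autofluorescence background, 8-bit units, applied to
        every channel of every cell.
    """

    expr_cv: float = 0.35
    channel_cv: float = 0.05
    autofluor_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.expr_cv < 0 or self.channel_cv < 0 or self.autofluor_mean < 0:
            raise ValueError("noise parameters must be non-negative")


NOISELESS = NoiseModel(expr_cv=0.0, channel_cv=0.0, autofluor_mean=10.0)


@dataclass
class CellRecord:
    """One simulated (or measured) cell with its ground truth."""

    cell_id: int
    copies_r: int
    copies_g: int
    copies_b: int
    expr_factor: float
    intensity_r: float
    intensity_g: float
    intensity_b: float
    centroid: tuple[float, float] | None = None  # (row, col) pixels
    truth_class: str = "unlabelled"
    saturated: bool = False
    clone_id: int | None = None

    @property
    def copies(self) -> np.ndarray:
        return np.array([self.copies_r, self.copies_g, self.copies_b])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([self.intensity_r, self.intensity_g, self.intensity_b])


def _intensities(copies: np.ndarray, expr_factor: np.ndarray,
                 expr: np.ndarray, noise: NoiseModel, rng) -> tuple[np.ndarray, np.ndarray]:
    n = copies.shape[0]
    eps = rng.normal(0.0, noise.channel_cv, size=(n, 3)) if noise.channel_cv > 0 \
        else np.zeros((n, 3))
    raw = expr_factor[:, None] * copies * expr[None, :] * (1.0 + eps) \
        + noise.autofluor_mean
    saturated = np.any(raw > 255.0, axis=1)
    return np.clip(raw, 0.0, 255.0), saturated


def _expression_factors(n: int, cv: float, rng) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _records_from_arrays(copies, expr_factor, intens, saturated,
                         clone_ids=None, start_id: int = 1) -> list[CellRecord]:
    records = []
    for i in range(copies.shape[0]):
        records.append(CellRecord(
            cell_id=start_id + i,
            copies_r=int(copies[i, 0]), copies_g=int(copies[i, 1]),
            copies_b=int(copies[i, 2]),
            expr_factor=float(expr_factor[i]),
            intensity_r=float(intens[i, 0]), intensity_g=float(intens[i, 1]),
            intensity_b=float(intens[i, 2]),
            truth_class=class_of_pattern(*(copies[i] > 0)),
            saturated=bool(saturated[i]),
            clone_id=None if clone_ids is None else int(clone_ids[i]),
        ))
    return records


def generate_population(vector_set: VectorSet, n_cells: int,
                        noise: NoiseModel = NoiseModel(),
                        rng=None) -> list[CellRecord]:
    """Simulate a population of cells exposed to the vector mixture.

    Copy numbers per vector are independent ``Poisson(MOI)``; channel
    intensity is ``clip(expr_factor * copies * per_copy_strength *
    (1 + eps) + autofluorescence, 0, 255)`` with ``eps ~ N(0, channel_cv)``
    and a lognormal mean-1 expression factor shared across the three
    channels of a cell.  Reproducible given ``rng`` (Generator or seed).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(rng)
    copies = rng.poisson(vector_set.mois, size=(int(n_cells), 3))
    expr_factor = _expression_factors(int(n_cells), noise.expr_cv, rng)
    intens, saturated = _intensities(copies, expr_factor, vector_set.expr,
                                     noise, rng)
    frac_sat = saturated.mean()
    if frac_sat > 0.5:
        log.warning("%.0f%% of cells saturated at 255; consider lowering "
                    "expression strengths", 100 * frac_sat)
    return _records_from_arrays(copies, expr_factor, intens, saturated)


def generate_clones(clone_copy_vectors, cells_per_clone: int,
                    noise: NoiseModel = NoiseModel(),
                    expr=(80.0, 80.0, 80.0), rng=None) -> list[CellRecord]:
    """Population of planted clones sharing exact copy-number vectors.

    Each entry of ``clone_copy_vectors`` is an integer (r, g, b) copy
    triplet; all cells of a clone inherit it, while expression factors and
    channel noise vary per cell.  This is the ground truth for hue-based
    clonal grouping: within a clone the noiseless hue is identical.
    """
    if cells_per_clone <= 0:
        raise ValueError("cells_per_clone must be positive")
    rng = np.random.default_rng(rng)
    vectors = np.asarray(clone_copy_vectors, dtype=int)
    if vectors.ndim != 2 or vectors.shape[1] != 3 or np.any(vectors < 0):
        raise ValueError("clone_copy_vectors must be (k, 3) non-negative ints")
    copies = np.repeat(vectors, cells_per_clone, axis=0)
    clone_ids = np.repeat(np.arange(len(vectors)), cells_per_clone)
    n = copies.shape[0]
    expr_factor = _expression_factors(n, noise.expr_cv, rng)
    intens, saturated = _intensities(copies, expr_factor,
                                     np.asarray(expr, dtype=float), noise, rng)
    return _records_from_arrays(copies, expr_factor, intens, saturated,
                                clone_ids=clone_ids)


def population_table(records: list[CellRecord]) -> pd.DataFrame:
    """Tidy per-cell truth table (one row per cell)."""
    rows = []
    for r in records:
        row_px, col_px = (r.centroid if r.centroid is not None
                          else (float("nan"), float("nan")))
        rows.append({
            "cell_id": r.cell_id,
            "copies_r": r.copies_r, "copies_g": r.copies_g,
            "copies_b": r.copies_b,
            "expr_factor": r.expr_factor,
            "intensity_r": r.intensity_r, "intensity_g": r.intensity_g,
            "intensity_b": r.intensity_b,
            "row": row_px, "col": col_px,
            "truth_class": r.truth_class,
            "saturated": r.saturated,
            "clone_id": -1 if r.clone_id is None else r.clone_id,
        })
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


@dataclass
class SyntheticScene:
    """Rendered 3-channel raster with its ground truth.

    ``image`` is (rows, cols, 3) float32 in 8-bit units [0, 255], channel
    order (R, G, B); ``label_mask`` is uint16 with 0 = background and k =
    cell k; ``truth_table`` lists one record per mask label.
    """

    image: np.ndarray
    label_mask: np.ndarray
    truth_table: list[CellRecord] = field(default_factory=list)

    def save(self, directory) -> dict[str, Path]:
        """Write scene.tif (3×H×W float32), mask.tif (uint16), truth.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "image": directory / "scene.tif",
            "mask": directory / "mask.tif",
            "truth": directory / "truth.csv",
        }
        tifffile.imwrite(paths["image"],
                         np.moveaxis(self.image.astype(np.float32), -1, 0),
                         photometric="minisblack", planarconfig="separate")
        tifffile.imwrite(paths["mask"], self.label_mask.astype(np.uint16))
        population_table(self.truth_table).to_csv(paths["truth"], index=False)
        return paths

    @classmethod
    def load(cls, directory) -> "SyntheticScene":
        directory = Path(directory)
        image = np.moveaxis(tifffile.imread(directory / "scene.tif"), 0, -1)
        mask = tifffile.imread(directory / "mask.tif")
        truth = pd.read_csv(directory / "truth.csv")
        records = []
        for _, r in truth.iterrows():
            records.append(CellRecord(
                cell_id=int(r.cell_id),
                copies_r=int(r.copies_r), copies_g=int(r.copies_g),
                copies_b=int(r.copies_b),
                expr_factor=float(r.expr_factor),
                intensity_r=float(r.intensity_r),
                intensity_g=float(r.intensity_g),
                intensity_b=float(r.intensity_b),
                centroid=(float(r.row), float(r.col)),
                truth_class=str(r.truth_class),
                saturated=bool(r.saturated),
                clone_id=None if int(r.clone_id) < 0 else int(r.clone_id),
            ))
        return cls(image=image, label_mask=mask, truth_table=records)


def _place_centroids(n: int, shape: tuple[int, int], r_max: float,
                     rng, max_attempts_per_cell: int = 400) -> np.ndarray:
    """Rejection-sample non-overlapping centres; error names achievable max."""
    margin = r_max + 2.0
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError(
            f"frame {shape} too small for any cell of radius {r_max}")
    min_sep = 2.0 * r_max + 2.0
    placed: list[tuple[float, float]] = []
    # bucket grid of cell size min_sep: only neighbouring buckets can clash
    buckets: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    budget = max_attempts_per_cell * n
    while len(placed) < n and attempts < budget:
        attempts += 1
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        key = (int(cand[0] // min_sep), int(cand[1] // min_sep))
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for idx in buckets.get((key[0] + dr, key[1] + dc), ()):
                    p = placed[idx]
                    if (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 < min_sep ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault(key, []).append(len(placed))
            placed.append(cand)
    if len(placed) < n:
        raise ValueError(
            f"could not place {n} non-overlapping cells in frame {shape}; "
            f"achievable maximum here was {len(placed)}")
    return np.asarray(placed)


def render_scene(population: list[CellRecord], shape: tuple[int, int] = (512, 512),
                 cell_radius_px: tuple[float, float] = (6.0, 10.0),
                 blur_sigma: float = 0.0, background: float = 0.0,
                 rng=None, mixing_matrix=None) -> SyntheticScene:
    """Raster a population into a 3-channel scene with a ground-truth mask.

    Somata are drawn as randomly oriented ellipses at non-overlapping
    centres (rejection sampling; an unplaceable request raises with the
    achievable maximum).  An optional per-pixel Gaussian blur emulates
    optical spread; the label mask is never blurred.  ``mixing_matrix``
    (3×3, default identity) applies spectral cross-talk to rendered
    intensities without touching the truth table.
    """
    rng = np.random.default_rng(rng)
    r_min, r_max = cell_radius_px
    if r_min <= 0 or r_max < r_min:
        raise ValueError("cell radii must satisfy 0 < r_min <= r_max")
    n = len(population)
    centroids = _place_centroids(n, shape, r_max, rng)

    image = np.full(shape + (3,), float(background), dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint16)
    mix = np.eye(3) if mixing_matrix is None else np.asarray(mixing_matrix, float)
    if mix.shape != (3, 3):
        raise ValueError("mixing_matrix must be 3x3")

    placed_records = []
    for rec, (cr, cc) in zip(population, centroids):
        a = rng.uniform(r_min, r_max)
        b = rng.uniform(r_min, r_max)
        theta = rng.uniform(0, np.pi)
        rr, ccx = _draw_ellipse(cr, cc, a, b, shape=shape, rotation=theta)
        colour = mix @ rec.intensity
        image[rr, ccx, :] = colour[None, :]
        mask[rr, ccx] = rec.cell_id
        placed_records.append(replace(rec, centroid=(float(cr), float(cc))))

    if blur_sigma > 0:
        for c in range(3):
            image[..., c] = _gaussian(image[..., c], sigma=blur_sigma,
                                      preserve_range=True)
    np.clip(image, 0.0, 255.0, out=image)
    return SyntheticScene(image=image, label_mask=mask,
                          truth_table=placed_records)


# --------------------------------------------------------------------------
# neuron-tree generators (fixtures for morphometry)

def _rotate_xy(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def generate_neuron_tree(kind: str, params: dict | None = None,
                         rng=None) -> NeuronTree:
    """Parametric neuron skeletons rooted at the origin.

    ``kind``:

    * ``"straight"`` — single unbranched radial neurite; params ``length``
      (µm, default 300) and ``step`` (node spacing, default 10).
    * ``"binary"`` — symmetric bifurcating tree; params ``depth`` (number
      of bifurcation levels after the trunk, default 2), ``segment_length``
      (default 50) and ``branch_angle`` (radians, default 0.5).
    * ``"random"`` — stochastic branching with segment directions
      constrained never to point back toward the root, so the radial
      distance is monotone along every edge; params ``max_depth``,
      ``segment_length``, ``branch_prob``, ``jitter`` (radians).
    """
    params = dict(params or {})
    rng = np.random.default_rng(rng)
    nodes: list[SwcNode] = [SwcNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]

    def add(parent: int, pos: np.ndarray, radius: float = 0.5,
            type_code: int = 3) -> int:
        nid = len(nodes) + 1
        nodes.append(SwcNode(nid, type_code, float(pos[0]), float(pos[1]),
                             float(pos[2]), radius, parent))
        return nid

    if kind == "straight":
        length = float(params.pop("length", 300.0))
        step = float(params.pop("step", 10.0))
        if params:
            raise ValueError(f"unknown params for 'straight': {sorted(params)}")
        if length <= 0 or step <= 0:
            raise ValueError("length and step must be positive")
        parent, travelled = 1, 0.0
        while travelled < length - 1e-9:
            travelled = min(travelled + step, length)
            parent = add(parent, np.array([travelled, 0.0, 0.0]))
        return NeuronTree(nodes)

    if kind == "binary":
        depth = int(params.pop("depth", 2))
        seg = float(params.pop("segment_length", 50.0))
        angle = float(params.pop("branch_angle", 0.5))
        if params:
            raise ValueError(f"unknown params for 'binary': {sorted(params)}")
        if seg <= 0 or not (0 < angle < math.pi):
            raise ValueError("segment_length > 0 and branch_angle in (0, pi)")

        def grow(parent: int, pos: np.ndarray, direction: np.ndarray,
                 level: int) -> None:
            tip_pos = pos + seg * direction
            tip = add(parent, tip_pos)
            if level < depth:
                for sign in (+1.0, -1.0):
                    grow(tip, tip_pos, _rotate_xy(direction, sign * angle),
                         level + 1)

        grow(1, np.zeros(3), np.array([1.0, 0.0, 0.0]), 0)
        return NeuronTree(nodes)

    if kind == "random":
        max_depth = int(params.pop("max_depth", 5))
        seg = float(params.pop("segment_length", 25.0))
        branch_prob = float(params.pop("branch_prob", 0.4))
        jitter = float(params.pop("jitter", 0.6))
        if params:
            raise ValueError(f"unknown params for 'random': {sorted(params)}")
        if seg <= 0 or not (0 <= jitter < math.pi):
            raise ValueError("segment_length > 0 and jitter in [0, pi)")

        def outward_direction(pos: np.ndarray, direction: np.ndarray) -> np.ndarray:
            # perturb, then reject directions pointing back toward the root:
            # distance from the root is then monotone along the segment
            for _ in range(100):
                cand = _rotate_xy(direction, rng.normal(0.0, jitter))
                tilt = rng.normal(0.0, jitter * 0.3)
                cand = np.array([cand[0], cand[1] * math.cos(tilt),
                                 cand[1] * math.sin(tilt) + cand[2]])
                cand /= np.linalg.norm(cand)
                if np.dot(cand, pos) >= 0:
                    return cand
            return pos / max(np.linalg.norm(pos), 1e-12)

        def grow(parent: int, pos: np.ndarray, direction: np.ndarray,
                 depth: int) -> None:
            if depth > max_depth:
                return
            d = outward_direction(pos, direction) if np.linalg.norm(pos) > 0 \
                else direction
            length = seg * rng.uniform(0.7, 1.3)
            tip_pos = pos + length * d
            tip = add(parent, tip_pos)
            n_children = 2 if rng.uniform() < branch_prob else 1
            if depth < max_depth:
                for _ in range(n_children):
                    grow(tip, tip_pos, d, depth + 1)

        theta = rng.uniform(0, 2 * np.pi)
        grow(1, np.zeros(3), np.array([math.cos(theta), math.sin(theta), 0.0]), 0)
        return NeuronTree(nodes)

    raise ValueError(f"unknown tree kind {kind!r}")
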