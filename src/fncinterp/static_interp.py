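"""Static FNC interpolation on the 2D latent grid.

After training, evenly spaced latent coordinates are decoded into a
continuum of synthetic connectivity matrices, and the original subjects are
laid out next to them by solving a linear sum assignment (Jonker-Volgenant)
between their latent positions and the grid nodes.  Subject measures
overlaid on the grid, region-wise rank tests, and centroid-to-centroid
trajectory interpolation quantify what the latent layout encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .metrics import reconstruction_metrics, threshold_fractions


@dataclass
class GridLayout:
    """Square lattice of latent coordinates plus the subject assignment.

    ``coords`` is (side^2, 2), row-major over (row, col) with latent dim 1
    on x (increasing rightward, i.e. with column) and dim 2 on y (increasing
    upward, i.e. with decreasing row).  ``assignment`` maps latent-sample
    index -> grid-node index and is injective.
    """

    side: int
    radius: float
    coords: np.ndarray
    assignment: dict[int, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.side**2

    def node_rowcol(self, node: int) -> tuple[int, int]:
        return divmod(node, self.side)


def grid_range(latent_train: np.ndarray, percentile: float = 80.0) -> float:
    """Grid half-width: the 80th percentile of |latent coordinates|, pooled
    over samples and dimensions."""
    Z = np.asarray(latent_train, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 5:
        raise ValueError("need an N x D latent array with N >= 5")
    r = float(np.percentile(np.abs(Z).ravel(), percentile))
    if r <= 0:
        raise ValueError("degenerate latents: 80th percentile of |z| is 0")
    return r


def choose_grid_side(n_train: int) -> int:
    """Smallest side whose square holds all training samples (15 for 225)."""
    if n_train < 1:
        raise ValueError("need at least one training sample")
    return int(np.ceil(np.sqrt(n_train)))


def make_grid(radius: float, side: int = 15) -> GridLayout:
    """Evenly spaced side x side lattice over [-radius, radius]^2."""
    if side < 2:
        raise ValueError("side must be >= 2")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    axis = np.linspace(-radius, radius, side)
    coords = np.empty((side * side, 2))
    for row in range(side):
        for col in range(side):
            # row 0 is the top of the display: largest latent dim-2 value
            coords[row * side + col] = (axis[col], axis[side - 1 - row])
    return GridLayout(side=side, radius=radius, coords=coords)


def decode_grid(model, grid: GridLayout) -> np.ndarray:
    """Decode every grid node deterministically: (side^2, V) array."""
    if model.latent_dim != 2:
        raise ValueError("grid decoding requires a 2D latent space")
    return model.decode(grid.coords)


def assign_to_grid(latent: np.ndarray, grid: GridLayout,
                   order: np.ndarray | None = None) -> dict[int, int]:
    """Optimal injective map latent sample -> grid node (minimum total
    Euclidean distance, solved by the Jonker-Volgenant algorithm).

    ``order`` optionally gives a deterministic pre-sort (e.g. by subject
    id); it does not change the optimal cost, only tie resolution.
    """
    Z = np.atleast_2d(np.asarray(latent, dtype=float))
    n = Z.shape[0]
    if n > grid.n_nodes:
        raise ValueError(
            f"{n} samples exceed {grid.n_nodes} grid nodes; increase side "
            f"(need >= {choose_grid_side(n)})"
        )
    if order is not None:
        Z = Z[np.asarray(order)]
    cost = np.linalg.norm(Z[:, None, :] - grid.coords[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    assignment = {int(r): int(c) for r, c in zip(rows, cols)}
    if order is not None:
        inv = {int(pos): int(orig) for pos, orig in enumerate(np.asarray(order))}
        assignment = {inv[r]: c for r, c in assignment.items()}
    return assignment


def assignment_cost(latent: np.ndarray, grid: GridLayout,
                    assignment: dict[int, int]) -> float:
    Z = np.atleast_2d(np.asarray(latent, dtype=float))
    return float(sum(np.linalg.norm(Z[i] - grid.coords[j])
                     for i, j in assignment.items()))


def grid_correspondence(decoded_nodes: np.ndarray, originals: np.ndarray,
                        assignment: dict[int, int],
                        groups=None, sample_ids=None) -> dict:
    """Per-subject correspondence between each original vector and the
    generated vector at its assigned node, plus threshold fractions."""
    idx = sorted(assignment)
    gen = np.vstack([decoded_nodes[assignment[i]] for i in idx])
    orig = np.vstack([originals[i] for i in idx])
    sub = None if groups is None else [groups[i] for i in idx]
    ids = idx if sample_ids is None else [sample_ids[i] for i in idx]
    df = reconstruction_metrics(gen, orig, groups=sub, sample_ids=ids)
    return {"metrics": df, "fractions": threshold_fractions(df)}


def overlay_measures(assignment: dict[int, int], metadata: pd.DataFrame,
                     measure: str, grid: GridLayout) -> np.ndarray:
    """side x side array of the measure at each assigned node; NaN elsewhere.

    ``metadata`` rows correspond positionally to latent-sample indices.
    Missing values stay missing (NaN), never 0.
    """
    if measure not in metadata.columns:
        raise KeyError(
            f"unknown measure {measure!r}; available: {list(metadata.columns)}"
        )
    out = np.full((grid.side, grid.side), np.nan)
    values = metadata[measure].to_numpy()
    for i, node in assignment.items():
        row, col = grid.node_rowcol(node)
        out[row, col] = values[i]
    return out


#: The six half-grid regions used for subject-measure comparisons on a
#: 15 x 15 grid: upper seven rows vs lower eight; left seven columns vs
#: right eight; upper triangle including the diagonal vs lower triangle
#: excluding it.
REGION_PAIRS = (("upper", "lower"), ("left", "right"),
                ("upper_triangle", "lower_triangle"))


def _region_of(row: int, col: int, side: int) -> dict[str, bool]:
    half = side // 2  # 7 for side 15
    return {
        "upper": row < half,
        "lower": row >= half,
        "left": col < half,
        "right": col >= half,
        "upper_triangle": col >= row,
        "lower_triangle": col < row,
    }


def region_tests(assignment: dict[int, int], metadata: pd.DataFrame,
                 measure: str, grid: GridLayout,
                 label_subset: tuple[str, ...] | None = None,
                 label_column: str = "group") -> pd.DataFrame:
    """Mean (sd, n) of a measure per half-grid region plus Mann-Whitney U
    p-values (two-sided and both one-sided) between paired halves.

    ``label_subset`` restricts to given diagnostic labels (e.g. patients
    only).  Empty regions are reported with n = 0 and the pair's test
    skipped with a flag.
    """
    values = metadata[measure].to_numpy(dtype=float)
    labels = metadata[label_column].to_numpy() if label_column in metadata else None
    region_values: dict[str, list[float]] = {
        r: [] for pair in REGION_PAIRS for r in pair
    }
    for i, node in assignment.items():
        if label_subset is not None and labels is not None \
                and labels[i] not in label_subset:
            continue
        v = values[i]
        if np.isnan(v):
            continue
        row, col = grid.node_rowcol(node)
        membership = _region_of(row, col, grid.side)
        for r in region_values:
            if membership[r]:
                region_values[r].append(v)

    rows = []
    for a, b in REGION_PAIRS:
        va, vb = np.array(region_values[a]), np.array(region_values[b])
        skipped = va.size == 0 or vb.size == 0
        if skipped:
            p2 = p_a = p_b = np.nan
        else:
            p2 = stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
            p_a = stats.mannwhitneyu(va, vb, alternative="greater").pvalue
            p_b = stats.mannwhitneyu(va, vb, alternative="less").pvalue
        for name, v in ((a, va), (b, vb)):
            rows.append({
                "measure": measure, "region": name, "n": int(v.size),
                "mean": float(v.mean()) if v.size else np.nan,
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                "p_two_sided": float(p2) if not skipped else np.nan,
                "p_this_greater": float(p_a if name == a else p_b) if not skipped else np.nan,
                "skipped": skipped,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Linear latent trajectory with stochastic decoding.

    ``draw_count`` posterior-style draws z = point + noise_scale * eps are
    decoded at each of ``n_points`` evenly spaced points from start to end;
    noise_scale 0 means a single deterministic decode per point.
    """

    start: np.ndarray
    end: np.ndarray
    n_points: int = 3
    draw_count: int = 50
    noise_scale: float = 0.0

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.draw_count < 1:
            raise ValueError("draw_count must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @property
    def points(self) -> np.ndarray:
        t = np.linspace(0.0, 1.0, self.n_points)[:, None]
        return (1 - t) * self.start + t * self.end


def group_centroid(latent: np.ndarray, labels, group) -> np.ndarray:
    """Coordinate-wise mean latent position of a group's members."""
    Z = np.atleast_2d(np.asarray(latent, dtype=float))
    mask = np.asarray(labels) == group
    if not mask.any():
        raise ValueError(f"empty group {group!r}")
    return Z[mask].mean(axis=0)


def interpolate_trajectory(model, spec: TrajectorySpec, seed: int = 0
                           ) -> list[np.ndarray]:
    """Decode ``draw_count`` draws at each trajectory point.

    Returns one (draw_count, V) array per point.  Draws at different points
    share the eps sequence (paired by draw index) so that per-edge paired
    tests along the trajectory are well defined.
    """
    rng = np.random.default_rng(seed)
    D = spec.start.size
    eps = (rng.standard_normal((spec.draw_count, D))
           if spec.noise_scale > 0 else np.zeros((spec.draw_count, D)))
    out = []
    for p in spec.points:
        Z = p[None, :] + spec.noise_scale * eps
        out.append(model.decode(Z))
    return out


_EDGE_CATEGORIES = {
    (1, 1, 1): "pos_stronger", (1, 1, -1): "pos_weaker",
    (-1, -1, 1): "neg_stronger", (-1, -1, -1): "neg_weaker",
    (1, -1, 0): "pos_to_neg", (-1, 1, 0): "neg_to_pos",
}


def classify_edge_change(mean_start: float, mean_end: float) -> str:
    """Direction category of an edge change along a trajectory: stronger or
    weaker within a sign, or a sign flip."""
    s0, s1 = int(np.sign(mean_start)), int(np.sign(mean_end))
    if s0 == 0 or s1 == 0:
        return "none" if mean_start == mean_end else (
            "pos_stronger" if mean_end > mean_start and s1 >= 0 else
            "neg_stronger" if mean_end < mean_start and s1 <= 0 else "none")
    if s0 != s1:
        return _EDGE_CATEGORIES[(s0, s1, 0)]
    grow = 1 if abs(mean_end) > abs(mean_start) else -1
    if abs(mean_end) == abs(mean_start):
        return "none"
    return _EDGE_CATEGORIES[(s0, s1, grow)]


def trajectory_edge_tests(draws_start: np.ndarray, draws_end: np.ndarray,
                          alpha: float = 1e-4) -> pd.DataFrame:
    """Per-edge Wilcoxon signed-rank between paired start/end draws,
    Bonferroni-corrected over the V edges.

    Returns a frame with one row per edge: mean at each end, the direction
    category, raw and adjusted p, and the significance mask at ``alpha``.
    Fewer than 6 draws makes the signed-rank test powerless; a warning
    column flags that case.
    """
    A = np.atleast_2d(np.asarray(draws_start, dtype=float))
    B = np.atleast_2d(np.asarray(draws_end, dtype=float))
    if A.shape != B.shape:
        raise ValueError("draws must be paired with equal shapes")
    M, V = A.shape
    low_power = M < 6
    p_raw = np.ones(V)
    for j in range(V):
        d = B[:, j] - A[:, j]
        if np.all(d == 0):
            p_raw[j] = 1.0
        else:
            p_raw[j] = stats.wilcoxon(d).pvalue
    p_adj = np.minimum(1.0, p_raw * V)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    return pd.DataFrame({
        "edge": np.arange(V),
        "mean_start": mean_a,
        "mean_end": mean_b,
        "category": [classify_edge_change(a, b) for a, b in zip(mean_a, mean_b)],
        "p_raw": p_raw,
        "p_adjusted": p_adj,
        "significant": p_adj < alpha,
        "low_power": low_power,
    })
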