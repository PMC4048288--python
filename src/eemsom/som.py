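"""Online Kohonen self-organising map on a hexagonal grid.

Implements the training recipe used throughout the package: learning rate
decreasing linearly from 0.05 to 0.01 over all presentations, an initial
bubble neighbourhood whose radius is the two-thirds quantile of all
pairwise unit distances, shrinking linearly to zero during the first third
of the iterations (after which only the winning unit is adapted), random
initialisation from distinct data rows, hexagonal topology, plus the
U-matrix and complete-linkage (Lance-Williams) hierarchical clustering of
the codebook.

The per-presentation update loop is JIT-compiled with numba; training is
bit-reproducible given (data, grid, schedule including seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.linalg import svds
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hexagonal grid geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Hexagonal map layout: offset rows, adjacent units at distance 1.

    Unit ``i = row * n_cols + col`` sits at
    ``(col + 0.5 * (row % 2), row * sqrt(3) / 2)``.
    """

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def unit_positions(self) -> np.ndarray:
        rows, cols = np.divmod(np.arange(self.n_units), self.n_cols)
        x = cols + 0.5 * (rows % 2)
        y = rows * (np.sqrt(3.0) / 2.0)
        return np.column_stack([x, y])

    def distance_matrix(self) -> np.ndarray:
        pos = self.unit_positions
        return cdist(pos, pos)


def grid_distance(grid: GridSpec, u: int, v: int) -> float:
    """Euclidean distance between two units' positions on the hex grid."""
    pos = grid.unit_positions
    if not (0 <= u < grid.n_units and 0 <= v < grid.n_units):
        raise IndexError("unit index out of range")
    return float(np.linalg.norm(pos[u] - pos[v]))


# ---------------------------------------------------------------------------
# Training schedule and model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSchedule:
    """Online-SOM schedule.

    ``alpha`` decreases linearly from ``alpha_start`` to ``alpha_end`` over
    *all* presentations.  The bubble-neighbourhood radius starts at the
    ``radius_quantile`` quantile of pairwise unit distances and decreases
    linearly to zero during the first ``radius_phase`` fraction of the
    presentations; afterwards only the winning unit is adapted.
    """

    n_epochs: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_quantile: float = 2.0 / 3.0
    radius_phase: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0 < self.radius_phase <= 1:
            raise ValueError("radius_phase must be in (0, 1]")


@dataclass
class SOMModel:
    """Trained map: grid, codebook of prototype vectors, BMU assignments."""

    grid: GridSpec
    codebook: np.ndarray  # (U, P)
    schedule: TrainingSchedule
    coordinate_index: np.ndarray | None = None
    bmu_assignments: np.ndarray | None = None  # per training sample
    sample_ids: list[str] | None = None

    def save(self, path: str | Path) -> None:
        """Serialise to JSON (metadata) + a CSV codebook sidecar."""
        path = Path(path)
        sidecar = path.with_suffix(".codebook.csv")
        np.savetxt(sidecar, self.codebook, delimiter=",")
        meta = {
            "n_rows": self.grid.n_rows,
            "n_cols": self.grid.n_cols,
            "schedule": {
                "n_epochs": self.schedule.n_epochs,
                "alpha_start": self.schedule.alpha_start,
                "alpha_end": self.schedule.alpha_end,
                "radius_quantile": self.schedule.radius_quantile,
                "radius_phase": self.schedule.radius_phase,
                "seed": self.schedule.seed,
            },
            "codebook_file": sidecar.name,
            "coordinate_index": None
            if self.coordinate_index is None
            else np.asarray(self.coordinate_index).tolist(),
            "bmu_assignments": None
            if self.bmu_assignments is None
            else np.asarray(self.bmu_assignments).tolist(),
            "sample_ids": self.sample_ids,
        }
        path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        path = Path(path)
        meta = json.loads(path.read_text())
        codebook = np.loadtxt(path.parent / meta["codebook_file"], delimiter=",", ndmin=2)
        return cls(
            grid=GridSpec(meta["n_rows"], meta["n_cols"]),
            codebook=codebook,
            schedule=TrainingSchedule(**meta["schedule"]),
            coordinate_index=None
            if meta["coordinate_index"] is None
            else np.array(meta["coordinate_index"]),
            bmu_assignments=None
            if meta["bmu_assignments"] is None
            else np.array(meta["bmu_assignments"], dtype=int),
            sample_ids=meta["sample_ids"],
        )


@dataclass
class UMatrix:
    """Unified distance matrix over hex-adjacent unit pairs."""

    edges: np.ndarray  # (E, 2) int unit pairs, u < v
    edge_distances: np.ndarray  # (E,)
    unit_summary: np.ndarray  # (U,) sum of distances to immediate neighbours


# ---------------------------------------------------------------------------
# Grid-size heuristics
# ---------------------------------------------------------------------------

def _top2_eigenvalues(data: np.ndarray) -> tuple[float, float]:
    """Two largest eigenvalues of the data covariance matrix."""
    X = data - data.mean(axis=0)
    n, p = X.shape
    if min(n - 1, p) < 3:
        ev = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False).reshape(p, p)))[::-1]
        ev = np.concatenate([ev, [0.0, 0.0]])
        return float(ev[0]), float(ev[1])
    # Truncated SVD of the centred matrix avoids forming a P x P covariance.
    v0 = np.full(min(n, p), 1.0 / np.sqrt(min(n, p)))
    s = svds(X, k=2, v0=v0, return_singular_vectors=False)
    ev = np.sort(s**2 / (n - 1))[::-1]
    return float(ev[0]), float(ev[1])


def suggest_grid(data: np.ndarray) -> GridSpec:
    """Map size from the Vesanto heuristic, shaped by the data covariance.

    Total units ~ 5 * sqrt(N); the row:column ratio follows
    ``sqrt(lambda1 / lambda2)`` of the two largest covariance eigenvalues,
    so the map mirrors the anisotropy of the data cloud.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to suggest a grid")
    target = 5.0 * np.sqrt(n)
    l1, l2 = _top2_eigenvalues(data)
    if l2 <= max(l1, 1.0) * 1e-12:
        warnings.warn(
            "covariance is rank-deficient; falling back to a square grid",
            stacklevel=2,
        )
        side = max(2, round(np.sqrt(target)))
        return GridSpec(side, side)
    ratio = np.sqrt(l1 / l2)
    ideal_cols = np.sqrt(target / ratio)
    ideal_rows = ratio * ideal_cols
    best = None
    for r in (int(np.floor(ideal_rows)), int(np.ceil(ideal_rows))):
        for c in (int(np.floor(ideal_cols)), int(np.ceil(ideal_cols))):
            r2, c2 = max(2, r), max(2, c)
            score = (abs(r2 * c2 - target), abs(r2 / c2 - ratio))
            if best is None or score < best[0]:
                best = (score, GridSpec(r2, c2))
    return best[1]


def stable_grid_size(
    data: np.ndarray,
    candidate_sizes: list[GridSpec],
    n_runs: int = 5,
    cv_threshold: float = 0.05,
    seed: int = 0,
    schedule: TrainingSchedule | None = None,
) -> GridSpec:
    """Largest candidate whose quantization error is stable across runs.

    For each candidate grid (ordered ascending by unit count), ``n_runs``
    maps are trained from different seeds and the coefficient of variation
    of SSIntra recorded; the largest grid with CV <= ``cv_threshold`` wins.
    Falls back to the smallest candidate with a warning when none passes.
    """
    if not candidate_sizes:
        raise ValueError("candidate_sizes is empty")
    counts = [g.n_units for g in candidate_sizes]
    if counts != sorted(counts):
        raise ValueError("candidate_sizes must be ordered ascending by unit count")
    base = schedule or TrainingSchedule()
    chosen = None
    for g in candidate_sizes:
        errs = []
        for m in range(n_runs):
            run_seed = derive_seed(seed, g.n_units, m)
            sched = TrainingSchedule(
                n_epochs=base.n_epochs, alpha_start=base.alpha_start,
                alpha_end=base.alpha_end, radius_quantile=base.radius_quantile,
                radius_phase=base.radius_phase, seed=run_seed,
            )
            model = train_som(data, g, sched)
            errs.append(ss_intra(model, data))
        errs = np.array(errs)
        mean = errs.mean()
        cv = errs.std(ddof=1) / mean if mean > 0 else 0.0
        logger.info("grid %dx%d: SSIntra CV=%.4f", g.n_rows, g.n_cols, cv)
        if cv <= cv_threshold:
            chosen = g
    if chosen is None:
        warnings.warn(
            "no candidate grid met the stability threshold; "
            "returning the smallest", stacklevel=2,
        )
        return candidate_sizes[0]
    return chosen


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and counters."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@njit(cache=True)
def _online_train(codebook, data, order, alphas, radii, grid_dist):  # pragma: no cover
    n_units, n_feat = codebook.shape
    for t in range(order.shape[0]):
        x = data[order[t]]
        best = 0
        best_d = np.inf
        for u in range(n_units):
            d = 0.0
            w = codebook[u]
            for j in range(n_feat):
                diff = x[j] - w[j]
                d += diff * diff
                if d >= best_d:
                    break
            if d < best_d:
                best_d = d
                best = u
        a = alphas[t]
        r = radii[t]
        if r <= 0.0:
            w = codebook[best]
            for j in range(n_feat):
                w[j] += a * (x[j] - w[j])
        else:
            for u in range(n_units):
                if grid_dist[best, u] <= r:
                    w = codebook[u]
                    for j in range(n_feat):
                        w[j] += a * (x[j] - w[j])


def initial_radius(grid: GridSpec, quantile: float = 2.0 / 3.0) -> float:
    """Quantile of all pairwise (i < j) unit distances on the grid."""
    d = grid.distance_matrix()
    iu = np.triu_indices(grid.n_units, k=1)
    if len(iu[0]) == 0:
        return 0.0
    return float(np.quantile(d[iu], quantile))


def train_som(
    data: np.ndarray, grid: GridSpec, schedule: TrainingSchedule,
    sample_ids: list[str] | None = None,
    coordinate_index: np.ndarray | None = None,
) -> SOMModel:
    """Train an online SOM; fully deterministic given the schedule seed.

    The codebook is initialised from a random sample of distinct data rows;
    presentation order is reshuffled every epoch.  Per presentation the best
    matching unit (BMU) is found by exhaustive Euclidean search and every
    unit within the current bubble radius is moved towards the sample.
    """
    data = np.ascontiguousarray(np.asarray(data, dtype=float))
    if data.ndim != 2 or data.size == 0:
        raise ValueError("data must be a non-empty 2-D array")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains missing/non-finite values")
    n, p = data.shape
    u = grid.n_units
    rng = np.random.default_rng(schedule.seed)
    if u <= n:
        init_idx = rng.choice(n, size=u, replace=False)
        codebook = data[init_idx].copy()
    else:
        warnings.warn(
            "more units than samples: initial codebook sampled with "
            "replacement plus jitter", stacklevel=2,
        )
        init_idx = rng.choice(n, size=u, replace=True)
        scale = max(np.std(data), 1e-12)
        codebook = data[init_idx] + rng.normal(0.0, 1e-6 * scale, size=(u, p))

    total = schedule.n_epochs * n
    order = np.concatenate(
        [rng.permutation(n) for _ in range(schedule.n_epochs)]
    ).astype(np.int64)
    t = np.arange(total, dtype=float)
    denom = max(total - 1, 1)
    alphas = schedule.alpha_start + (schedule.alpha_end - schedule.alpha_start) * t / denom
    r0 = initial_radius(grid, schedule.radius_quantile)
    t_phase = schedule.radius_phase * total
    radii = np.where(t < t_phase, r0 * (1.0 - t / t_phase), 0.0)

    gd = grid.distance_matrix()
    _online_train(codebook, data, order, alphas, radii, gd)

    model = SOMModel(
        grid=grid, codebook=codebook, schedule=schedule,
        coordinate_index=coordinate_index, sample_ids=sample_ids,
    )
    model.bmu_assignments = bmu_all(model, data)
    return model


def bmu_all(model: SOMModel, data: np.ndarray) -> np.ndarray:
    """BMU index for every row; ties broken by lowest unit index."""
    d = cdist(np.atleast_2d(data), model.codebook, metric="sqeuclidean")
    return np.argmin(d, axis=1)  # argmin takes the first (lowest) index on ties


def bmu(model: SOMModel, x: np.ndarray) -> int:
    """Best matching unit of one vector (lowest index on ties, logged)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.codebook.shape[1],):
        raise ValueError("vector length does not match codebook")
    d = np.linalg.norm(model.codebook - x, axis=1)
    winner = int(np.argmin(d))
    if np.sum(d <= d[winner] + 1e-12) > 1:
        logger.debug("BMU tie broken towards lowest unit index %d", winner)
    return winner


def ss_intra(model: SOMModel, data: np.ndarray) -> float:
    """Intra-class sum of squares: total squared distance to BMU prototypes."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d = cdist(data, model.codebook, metric="sqeuclidean")
    return float(np.sum(np.min(d, axis=1)))


# ---------------------------------------------------------------------------
# U-matrix and codebook clustering
# ---------------------------------------------------------------------------

def hex_adjacency(grid: GridSpec, tol: float = 1e-9) -> np.ndarray:
    """(E, 2) array of unit pairs (u < v) at hex distance 1."""
    d = grid.distance_matrix()
    iu, jv = np.nonzero(np.triu(np.abs(d - 1.0) <= tol, k=1))
    return np.column_stack([iu, jv])


def u_matrix(model: SOMModel) -> UMatrix:
    """Codebook distance per adjacent unit pair + per-unit neighbour sums."""
    edges = hex_adjacency(model.grid)
    dists = np.linalg.norm(
        model.codebook[edges[:, 0]] - model.codebook[edges[:, 1]], axis=1
    )
    summary = np.zeros(model.grid.n_units)
    np.add.at(summary, edges[:, 0], dists)
    np.add.at(summary, edges[:, 1], dists)
    return UMatrix(edges=edges, edge_distances=dists, unit_summary=summary)


def _relabel_by_size(raw_labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by decreasing size (ties: lowest member)."""
    ids, counts = np.unique(raw_labels, return_counts=True)
    first_member = np.array([np.argmax(raw_labels == i) for i in ids])
    order = np.lexsort((first_member, -counts))
    mapping = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in raw_labels])


def cluster_codebook(model: SOMModel, k: int) -> np.ndarray:
    """Complete-linkage hierarchical clustering of the prototype vectors.

    Agglomeration follows the Lance-Williams recurrence for complete
    linkage (alpha_i = alpha_j = 0.5, beta = 0, gamma = 0.5) under
    Euclidean distance.  Labels run 1..k ordered by decreasing cluster
    size (ties by lowest member unit index); singleton clusters are
    legitimate outcomes.
    """
    u = model.codebook.shape[0]
    if not 1 <= k <= u:
        raise ValueError(f"k={k} out of range 1..{u}")
    if u == 1:
        return np.array([1])
    Z = linkage(model.codebook, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _relabel_by_size(raw)
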