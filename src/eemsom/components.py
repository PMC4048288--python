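"""R-mode analysis: from component planes to fluorescence components.

The Q-mode map's codebook is transposed into *component planes* (one per
wavelength coordinate: that coordinate's intensity across all unit
prototypes).  Pearson correlation between every pair of planes yields a
P x P matrix whose rows are fed to a second ("R-mode") SOM, grouping
highly correlated wavelength coordinates into the same or nearby units.
Complete-linkage clustering of the R-mode codebook, with the partition
size chosen by silhouette inspection over k = 2..9, labels every
coordinate with a fluorescence component C1..Ck.  Per-sample component
abundances are quantified by fluorescence regional integration (FRI):
region volumes normalised by inverse fractional area, expressed also as
percent responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eem_io import EEM, EEMDataset
from .preprocess import OpticalIndices
from .som import (
    GridSpec,
    SOMModel,
    TrainingSchedule,
    cluster_codebook,
    suggest_grid,
    train_som,
)

logger = logging.getLogger(__name__)


@dataclass
class ComponentPlaneSet:
    """One plane per wavelength coordinate: its values across map units."""

    planes: np.ndarray  # (P, U)
    coordinate_index: np.ndarray  # (P, 2)


@dataclass
class ComponentPartition:
    """Assignment of wavelength coordinates to fluorescence components.

    Components are numbered C1..Ck by ascending mean emission wavelength,
    mirroring the protein-like -> humic-like emission progression.
    """

    n_components: int
    coordinate_labels: np.ndarray  # (P,) ints 1..k
    unit_labels: np.ndarray  # (U,) ints 1..k
    coordinate_index: np.ndarray  # (P, 2)
    silhouette_table: pd.DataFrame | None = None
    selected_by: str = "auto_rule"

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "ex": self.coordinate_index[:, 0],
                "em": self.coordinate_index[:, 1],
                "component": self.coordinate_labels,
            }
        ).to_csv(path, index=False)


@dataclass
class FRIResult:
    """Fluorescence regional integration of one EEM over a partition."""

    components: np.ndarray  # component ids 1..k
    phi: np.ndarray  # raw region volumes
    mf: np.ndarray  # multiplication factors (inverse fractional area)
    phi_n: np.ndarray  # area-normalised volumes
    percent: np.ndarray  # percent responses P_i,n (sum to 100)
    method: str = "riemann"


# ---------------------------------------------------------------------------
# Component planes and their correlation
# ---------------------------------------------------------------------------

def component_planes(qmodel: SOMModel) -> ComponentPlaneSet:
    """Transpose the Q-mode codebook into per-coordinate planes."""
    if qmodel.coordinate_index is None:
        raise ValueError("Q-mode model carries no coordinate index")
    return ComponentPlaneSet(
        planes=qmodel.codebook.T.copy(),
        coordinate_index=np.asarray(qmodel.coordinate_index),
    )


def plane_correlation(planes: ComponentPlaneSet) -> np.ndarray:
    """Pearson correlation between every pair of component planes.

    Planes are z-scored first (a no-op for Pearson's r, kept for
    fidelity to the published recipe).  Zero-variance planes cannot be
    correlated; they get r = 0 off-diagonal and 1 on the diagonal, with a
    warning, instead of propagating NaN.
    """
    M = np.asarray(planes.planes, dtype=float)
    p, u = M.shape
    if u < 3:
        raise ValueError("need at least 3 map units for meaningful correlations")
    sd = M.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance component plane(s): "
            "correlations set to 0", stacklevel=2,
        )
    Z = np.zeros_like(M)
    ok = ~degenerate
    Z[ok] = (M[ok] - M[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    corr = Z @ Z.T / u
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def rmode_som(
    corr: np.ndarray,
    grid: GridSpec | None = None,
    schedule: TrainingSchedule | None = None,
    coordinate_index: np.ndarray | None = None,
) -> SOMModel:
    """SOM of the plane-correlation matrix (one row per coordinate).

    Each coordinate's vector of correlations with every other coordinate
    is one observation; training is identical to the Q-mode map.  BMU
    assignments of the coordinates are stored on the model.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if grid is None:
        grid = suggest_grid(corr)
    sched = schedule or TrainingSchedule()
    return train_som(corr, grid, sched, coordinate_index=coordinate_index)


# ---------------------------------------------------------------------------
# Silhouette-guided partition of the R-mode units
# ---------------------------------------------------------------------------

def silhouette_values(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette s(i) = (b - a) / max(a, b) under Euclidean distance.

    ``a`` is the mean distance to the other members of i's cluster, ``b``
    the smallest mean distance to any other cluster.  Members of
    singleton clusters get s = 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    from scipy.spatial.distance import squareform, pdist

    n = len(points)
    D = squareform(pdist(points))
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


SILHOUETTE_COLUMNS = ["k", "S_mean", "S_min", "S_max", "n_neg"]


def silhouette_scan(
    rmodel: SOMModel, k_range: range | list[int] = range(2, 10)
) -> pd.DataFrame:
    """Silhouette statistics of hierarchical partitions of the R-mode units.

    For each candidate k the codebook is cut into k complete-linkage
    clusters and the silhouettes of the *units* summarised: mean, min,
    max and the count of units with negative silhouette.
    """
    rows = []
    for k in k_range:
        labels = cluster_codebook(rmodel, k)
        s = silhouette_values(rmodel.codebook, labels)
        rows.append(
            {"k": int(k), "S_mean": s.mean(), "S_min": s.min(),
             "S_max": s.max(), "n_neg": int((s < 0).sum())}
        )
    return pd.DataFrame(rows, columns=SILHOUETTE_COLUMNS)


def select_partition(table: pd.DataFrame, tolerance: float = 0.05) -> int:
    """Pick k: high mean silhouette, then fewest negative silhouettes.

    Candidates are all k whose mean silhouette is within ``tolerance`` of
    the best; among them the smallest ``n_neg`` wins, ties resolved by
    larger mean silhouette, then by smaller k.
    """
    if len(table) == 0:
        raise ValueError("empty silhouette table")
    t = table.reset_index(drop=True)
    cand = t[t["S_mean"] >= t["S_mean"].max() - tolerance]
    cand = cand.sort_values(
        by=["n_neg", "S_mean", "k"], ascending=[True, False, True]
    )
    k = int(cand.iloc[0]["k"])
    logger.info(
        "selected k=%d (tolerance %.3g on mean silhouette)", k, tolerance
    )
    return k


# ---------------------------------------------------------------------------
# Coordinate partition and regions
# ---------------------------------------------------------------------------

def coordinate_partition(
    rmodel: SOMModel,
    unit_labels: np.ndarray,
    silhouette_table: pd.DataFrame | None = None,
    selected_by: str = "auto_rule",
) -> ComponentPartition:
    """Label every wavelength coordinate with its BMU's cluster.

    Component ids are renumbered C1..Ck by ascending mean emission
    wavelength of their member coordinates (clusters without coordinates
    are ordered last, by their original label).
    """
    if rmodel.bmu_assignments is None or rmodel.coordinate_index is None:
        raise ValueError("R-mode model lacks BMU assignments or coordinates")
    unit_labels = np.asarray(unit_labels)
    coord_raw = unit_labels[rmodel.bmu_assignments]
    coords = np.asarray(rmodel.coordinate_index, dtype=float)
    uniq = np.unique(unit_labels)
    mean_em = {}
    for c in uniq:
        member = coord_raw == c
        mean_em[int(c)] = (
            coords[member, 1].mean() if member.any() else np.inf
        )
    order = sorted(uniq, key=lambda c: (mean_em[int(c)], int(c)))
    mapping = {int(c): rank + 1 for rank, c in enumerate(order)}
    return ComponentPartition(
        n_components=len(uniq),
        coordinate_labels=np.array([mapping[int(c)] for c in coord_raw]),
        unit_labels=np.array([mapping[int(c)] for c in unit_labels]),
        coordinate_index=coords,
        silhouette_table=silhouette_table,
        selected_by=selected_by,
    )


def region_boundaries(partition: ComponentPartition) -> pd.DataFrame:
    """Bounding wavelength ranges and coordinate counts per component.

    Regions are unions of grid cells and need not be rectangular; the
    exact member coordinates are available through
    ``partition.coordinate_labels``.
    """
    rows = []
    coords = partition.coordinate_index
    for c in range(1, partition.n_components + 1):
        member = partition.coordinate_labels == c
        if not member.any():
            rows.append(
                {"component": c, "ex_min": np.nan, "ex_max": np.nan,
                 "em_min": np.nan, "em_max": np.nan, "n_coordinates": 0}
            )
            continue
        rows.append(
            {
                "component": c,
                "ex_min": coords[member, 0].min(),
                "ex_max": coords[member, 0].max(),
                "em_min": coords[member, 1].min(),
                "em_max": coords[member, 1].max(),
                "n_coordinates": int(member.sum()),
            }
        )
    return pd.DataFrame(rows)


def render_partition(partition: ComponentPartition, path) -> None:
    """Plot the component label map over the excitation-emission plane."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = partition.coordinate_index
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        coords[:, 1], coords[:, 0], c=partition.coordinate_labels,
        cmap="tab10", s=18, marker="s",
    )
    ax.set_xlabel("emission wavelength (nm)")
    ax.set_ylabel("excitation wavelength (nm)")
    ax.set_title(f"{partition.n_components} fluorescence components")
    fig.colorbar(sc, ax=ax, label="component")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Fluorescence regional integration
# ---------------------------------------------------------------------------

def _cell_widths(wavelengths: np.ndarray) -> np.ndarray:
    """Per-point cell width; np.gradient gives midpoint spacing."""
    w = np.asarray(wavelengths, dtype=float)
    if len(w) == 1:
        return np.array([1.0])
    return np.gradient(w)


def fri_volumes(
    eem: EEM, partition: ComponentPartition, method: str = "riemann"
) -> FRIResult:
    """Quantify each component in one sample as area-normalised volume.

    ``riemann`` (the classical FRI rule): Phi_i = sum over region cells of
    I * d(ex) * d(em).  ``trapezoid``: composite trapezoidal integration
    of I restricted to the region over the full grid, which weighs region
    boundaries more smoothly.  The multiplication factor MF_i is the total
    masked cell area over the region's cell area; Phi_i,n = MF_i * Phi_i
    and P_i,n = 100 * Phi_i,n / sum_j Phi_j,n.
    """
    coords = partition.coordinate_index
    k = partition.n_components
    ex, em = eem.ex_wavelengths, eem.em_wavelengths
    i_idx = np.searchsorted(ex, coords[:, 0])
    j_idx = np.searchsorted(em, coords[:, 1])
    if (
        np.any(i_idx >= len(ex)) or np.any(j_idx >= len(em))
        or np.any(np.abs(ex[np.clip(i_idx, 0, len(ex) - 1)] - coords[:, 0]) > 1e-9)
        or np.any(np.abs(em[np.clip(j_idx, 0, len(em) - 1)] - coords[:, 1]) > 1e-9)
    ):
        raise ValueError("EEM grid does not contain the partition's coordinates")

    wex = _cell_widths(ex)
    wem = _cell_widths(em)
    cell_area = wex[i_idx] * wem[j_idx]
    intens = eem.intensity[i_idx, j_idx]
    if np.any(~eem.mask[i_idx, j_idx]):
        raise ValueError("partition covers masked cells of this EEM")

    total_area = float(cell_area.sum())
    phi = np.zeros(k)
    mf = np.zeros(k)
    for c in range(1, k + 1):
        member = partition.coordinate_labels == c
        area = float(cell_area[member].sum())
        if area == 0:
            mf[c - 1] = np.nan
            continue
        mf[c - 1] = total_area / area
        if method == "riemann":
            phi[c - 1] = float(np.sum(intens[member] * cell_area[member]))
        elif method == "trapezoid":
            surface = np.zeros_like(eem.intensity)
            sel_i, sel_j = i_idx[member], j_idx[member]
            surface[sel_i, sel_j] = intens[member]
            phi[c - 1] = float(np.trapezoid(np.trapezoid(surface, em, axis=1), ex))
        else:
            raise ValueError(f"unknown FRI method {method!r}")

    phi_n = mf * phi
    total = np.nansum(phi_n)
    if total == 0:
        warnings.warn(
            f"{eem.sample_id}: zero total volume, percent responses undefined",
            stacklevel=2,
        )
        percent = np.full(k, np.nan)
    else:
        percent = 100.0 * phi_n / total
    return FRIResult(
        components=np.arange(1, k + 1), phi=phi, mf=mf, phi_n=phi_n,
        percent=percent, method=method,
    )


def component_table(
    ds: EEMDataset,
    partition: ComponentPartition,
    indices: dict[str, OpticalIndices] | None = None,
    method: str = "riemann",
) -> pd.DataFrame:
    """Tidy per-sample table of normalised volumes, percent responses and
    optical indices; one row per sample."""
    rows = []
    for e in ds.eems:
        res = fri_volumes(e, partition, method=method)
        row: dict[str, float | str] = {"sample_id": e.sample_id}
        for c, pn, pct in zip(res.components, res.phi_n, res.percent):
            row[f"phi_n_C{c}"] = pn
            row[f"pct_C{c}"] = pct
        if indices and e.sample_id in indices:
            oi = indices[e.sample_id]
            row.update({"HIX": oi.hix, "FI": oi.fi, "SUVA": oi.suva})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class ComponentAnalysis:
    """Everything the two-stage analysis produces."""

    qmodel: SOMModel
    planes: ComponentPlaneSet
    correlation: np.ndarray
    rmodel: SOMModel
    partition: ComponentPartition
    selected_k: int
    silhouette_table: pd.DataFrame = field(repr=False, default=None)


def fluorescence_components(
    X: np.ndarray,
    coordinate_index: np.ndarray,
    seed: int = 0,
    q_grid: GridSpec | None = None,
    r_grid: GridSpec | None = None,
    q_epochs: int = 30,
    r_epochs: int = 15,
    k_range: range = range(2, 10),
    tolerance: float = 0.05,
    k: int | None = None,
) -> ComponentAnalysis:
    """Full Q-mode -> correlation -> R-mode -> silhouette pipeline.

    ``X`` is the max-normalised, linearised (N, P) data matrix on
    ``coordinate_index``.  Grids default to the covariance-shaped Vesanto
    heuristic; pass ``k`` to skip the silhouette selection.
    """
    from .som import derive_seed

    if q_grid is None:
        q_grid = suggest_grid(X)
    q_sched = TrainingSchedule(n_epochs=q_epochs, seed=derive_seed(seed, 0))
    qmodel = train_som(X, q_grid, q_sched, coordinate_index=coordinate_index)

    planes = component_planes(qmodel)
    corr = plane_correlation(planes)

    if r_grid is None:
        r_grid = suggest_grid(corr)
    r_sched = TrainingSchedule(n_epochs=r_epochs, seed=derive_seed(seed, 1))
    rmodel = rmode_som(corr, r_grid, r_sched, coordinate_index=coordinate_index)

    table = silhouette_scan(rmodel, k_range)
    if k is None:
        selected_k = select_partition(table, tolerance)
        selected_by = "auto_rule"
    else:
        selected_k = int(k)
        selected_by = "user"
    labels = cluster_codebook(rmodel, selected_k)
    partition = coordinate_partition(
        rmodel, labels, silhouette_table=table, selected_by=selected_by
    )
    return ComponentAnalysis(
        qmodel=qmodel, planes=planes, correlation=corr, rmodel=rmodel,
        partition=partition, selected_k=selected_k, silhouette_table=table,
    )
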