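"""Leave-one-out outlier-sensitivity diagnostics for SOM analyses.

Two complementary stability views, following the reliability criteria of
de Bodt and co-workers:

* **Quantization stability** -- for every leave-one-out (LOO) subset the
  intra-class sum of squares (SSIntra) is averaged over M independently
  seeded trainings; a data set is robust when the per-subset means are
  tightly and symmetrically distributed (mean close to median, no
  1.5 * IQR outliers).
* **Topology stability** -- for every sample pair the fraction of runs in
  which their BMUs fall within a grid radius r ("neighbourhood
  stability" q_ij); histograms of q over all pairs are compared with the
  binomial reference of a randomly organised map.  Real structure shows
  up as mass piled near 0 and 1, far from the binomial.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .eem_io import EEMDataset, linearize
from .som import GridSpec, SOMModel, TrainingSchedule, derive_seed, train_som

logger = logging.getLogger(__name__)


def _as_matrix(ds) -> tuple[np.ndarray, list[str]]:
    """Accept an EEMDataset or a plain (N, P) matrix."""
    if isinstance(ds, EEMDataset):
        X, _ = linearize(ds)
        return X, ds.sample_ids
    X = np.asarray(ds, dtype=float)
    return X, [f"s{i}" for i in range(X.shape[0])]


def loo_subsets(ds) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    """Yield (left_out_id, reduced matrix, kept row indices), in sample order."""
    X, ids = _as_matrix(ds)
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        yield ids[i], X[keep], keep


def _reseeded(schedule: TrainingSchedule, seed: int) -> TrainingSchedule:
    return TrainingSchedule(
        n_epochs=schedule.n_epochs, alpha_start=schedule.alpha_start,
        alpha_end=schedule.alpha_end, radius_quantile=schedule.radius_quantile,
        radius_phase=schedule.radius_phase, seed=seed,
    )


@dataclass
class StabilityReport:
    """Results of the LOO stability analysis."""

    sample_ids: list[str]
    n_runs: int
    radii: tuple[float, ...]
    # quantization
    per_subset_mean: np.ndarray  # mean SSIntra over runs, one per subset
    per_subset_cv: np.ndarray
    ssintra_mean: float
    ssintra_median: float
    outlier_subsets: list[str]  # flagged by the 1.5*IQR rule
    # topology: radius -> (n_subsets, M+1) per-subset histogram counts
    histograms: dict[float, np.ndarray] = field(default_factory=dict)
    pooled_histograms: dict[float, np.ndarray] = field(default_factory=dict)
    group_histograms: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    whole_data_histogram: dict[float, np.ndarray] = field(default_factory=dict)
    random_reference: dict[float, np.ndarray] = field(default_factory=dict)
    # raw BMU histories (kept only on request; not serialised)
    bmu_histories: list[np.ndarray] | None = None
    whole_data_histories: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def arr(a):
            return np.asarray(a).tolist()

        payload = {
            "sample_ids": self.sample_ids,
            "n_runs": self.n_runs,
            "radii": list(self.radii),
            "per_subset_mean": arr(self.per_subset_mean),
            "per_subset_cv": arr(self.per_subset_cv),
            "ssintra_mean": self.ssintra_mean,
            "ssintra_median": self.ssintra_median,
            "outlier_subsets": self.outlier_subsets,
            "histograms": {str(r): arr(h) for r, h in self.histograms.items()},
            "pooled_histograms": {
                str(r): arr(h) for r, h in self.pooled_histograms.items()
            },
            "group_histograms": {
                str(r): {g: arr(h) for g, h in d.items()}
                for r, d in self.group_histograms.items()
            },
            "whole_data_histogram": {
                str(r): arr(h) for r, h in self.whole_data_histogram.items()
            },
            "random_reference": {
                str(r): arr(h) for r, h in self.random_reference.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def histograms_to_csv(self, path: str | Path) -> None:
        rows = []
        for r, groups in self.group_histograms.items():
            for g, counts in groups.items():
                for b, c in enumerate(counts):
                    rows.append(
                        {"radius": r, "group": g,
                         "stability_value": b / self.n_runs, "count": float(c)}
                    )
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Quantization stability
# ---------------------------------------------------------------------------

def quantization_stability(
    ds, grid: GridSpec, schedule: TrainingSchedule, M: int = 50, seed: int = 0
) -> StabilityReport:
    """Per-LOO-subset SSIntra averaged over M runs.

    Seeds are derived deterministically from the master seed per
    (subset, run), so the 50-run averages are fully reproducible.  Subsets
    whose mean SSIntra falls outside the 1.5 * IQR fences are flagged.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    ssintra, histories, ids = _loo_som_runs(ds, grid, schedule, M, seed)
    return _quantization_report(ssintra, ids, M)


def _loo_som_runs(
    ds, grid: GridSpec, schedule: TrainingSchedule, M: int, seed: int
) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    """Train M maps per LOO subset; return SSIntra and BMU histories.

    ``ssintra[i, m]`` is subset i's quantization error in run m;
    ``histories[i]`` is the (M, N-1) BMU matrix of subset i's samples.
    """
    X, ids = _as_matrix(ds)
    n = X.shape[0]
    ssintra = np.empty((n, M))
    histories: list[np.ndarray] = []
    for i, (left_out, Xi, keep) in enumerate(loo_subsets(X)):
        h = np.empty((M, n - 1), dtype=np.int64)
        for m in range(M):
            sched = _reseeded(schedule, derive_seed(seed, i, m))
            model = train_som(Xi, grid, sched)
            h[m] = model.bmu_assignments
            ssintra[i, m] = _ss_from_bmus(Xi, model)
        histories.append(h)
    return ssintra, histories, ids


def _ss_from_bmus(X: np.ndarray, model: SOMModel) -> float:
    diff = X - model.codebook[model.bmu_assignments]
    return float(np.sum(diff * diff))


def _quantization_report(ssintra: np.ndarray, ids: list[str], M: int) -> StabilityReport:
    means = ssintra.mean(axis=1)
    sds = ssintra.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvs = np.where(means > 0, sds / means, 0.0)
    q1, q3 = np.percentile(means, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [ids[i] for i in np.nonzero((means < lo) | (means > hi))[0]]
    return StabilityReport(
        sample_ids=list(ids), n_runs=M, radii=(),
        per_subset_mean=means, per_subset_cv=cvs,
        ssintra_mean=float(means.mean()), ssintra_median=float(np.median(means)),
        outlier_subsets=outliers,
    )


# ---------------------------------------------------------------------------
# Topology stability
# ---------------------------------------------------------------------------

def pair_stability(
    bmu_histories: np.ndarray, radius: float, grid: GridSpec
) -> np.ndarray:
    """Neighbourhood stability q_ij for every unordered sample pair i < j.

    ``q_ij`` is the fraction of runs in which the grid distance between
    the two samples' BMUs is at most ``radius``.  Input is an (M, N)
    matrix of per-run BMU indices; output is the condensed vector of
    C(N, 2) values ordered (0,1), (0,2), ...
    """
    h = np.asarray(bmu_histories, dtype=int)
    if h.ndim != 2 or h.shape[0] < 2 or h.shape[1] < 2:
        raise ValueError("need >= 2 runs and >= 2 samples")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    D = grid.distance_matrix()
    m, n = h.shape
    iu, ju = np.triu_indices(n, k=1)
    q = np.zeros(len(iu))
    for run in range(m):
        b = h[run]
        q += (D[b[iu], b[ju]] <= radius + 1e-12).astype(float)
    return q / m


def random_map_reference(grid: GridSpec, radius: float, M: int) -> np.ndarray:
    """Binomial pmf of q under random, independent BMU placement.

    ``p_r`` is the fraction of ordered unit pairs (u, v), u = v included,
    with grid distance <= r; the reference histogram of q * M over
    {0, ..., M} is Binomial(M, p_r).
    """
    D = grid.distance_matrix()
    p = float(np.mean(D <= radius + 1e-12))
    return stats.binom.pmf(np.arange(M + 1), M, p)


def shuffle_bmu_histories(
    bmu_histories: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute each run's BMUs across samples (null control).

    Per-run unit occupancy is preserved while sample identity is broken,
    so pairwise stabilities revert towards the random-map reference.
    """
    h = np.asarray(bmu_histories, dtype=int).copy()
    for m in range(h.shape[0]):
        rng.shuffle(h[m])
    return h


def stability_histogram(q: np.ndarray, M: int) -> np.ndarray:
    """Counts of q values over the M+1 attainable levels {0, ..., M}/M."""
    return np.bincount(np.rint(np.asarray(q) * M).astype(int), minlength=M + 1).astype(
        float
    )


def topology_stability(
    ds,
    grid: GridSpec,
    schedule: TrainingSchedule,
    radii: tuple[float, ...] = (1.0, 2.0),
    M: int = 50,
    seed: int = 0,
    outlier_ids: list[str] | None = None,
    keep_histories: bool = False,
) -> StabilityReport:
    """Neighbourhood-stability histograms per LOO subset and radius.

    Subset histograms are aggregated into an ``outlier`` group (subsets
    whose left-out sample is in ``outlier_ids``) and a ``regular`` group,
    alongside the pooled histogram, a whole-data (no sample left out)
    histogram and the binomial random-map reference.
    """
    ssintra, histories, ids = _loo_som_runs(ds, grid, schedule, M, seed)
    report = _quantization_report(ssintra, ids, M)
    report.radii = tuple(radii)
    outset = set(outlier_ids or [])

    X, _ = _as_matrix(ds)
    whole = np.empty((M, X.shape[0]), dtype=np.int64)
    for m in range(M):
        sched = _reseeded(schedule, derive_seed(seed, len(ids), m))
        whole[m] = train_som(X, grid, sched).bmu_assignments

    for r in radii:
        per_subset = np.array(
            [stability_histogram(pair_stability(h, r, grid), M) for h in histories]
        )
        report.histograms[r] = per_subset
        report.pooled_histograms[r] = per_subset.sum(axis=0)
        groups = {"outlier": np.zeros(M + 1), "regular": np.zeros(M + 1)}
        for i, sid in enumerate(ids):
            key = "outlier" if sid in outset else "regular"
            groups[key] += per_subset[i]
        report.group_histograms[r] = groups
        report.whole_data_histogram[r] = stability_histogram(
            pair_stability(whole, r, grid), M
        )
        report.random_reference[r] = random_map_reference(grid, r, M)
    if keep_histories:
        report.bmu_histories = histories
        report.whole_data_histories = whole
    return report


def run_stability_analysis(
    ds,
    grid: GridSpec,
    schedule: TrainingSchedule,
    radii: tuple[float, ...] = (1.0, 2.0),
    M: int = 50,
    seed: int = 0,
    outlier_ids: list[str] | None = None,
    keep_histories: bool = False,
) -> StabilityReport:
    """Full LOO stability analysis (quantization + topology in one pass)."""
    return topology_stability(
        ds, grid, schedule, radii=radii, M=M, seed=seed,
        outlier_ids=outlier_ids, keep_histories=keep_histories,
    )


def singleton_cluster_samples(
    model: SOMModel, unit_labels: np.ndarray
) -> list[int]:
    """Indices of samples whose map cluster contains only themselves.

    A sample sits in a singleton cluster when the codebook cluster of its
    BMU hosts exactly one sample; such samples mirror the stand-alone
    "single-neuron" outliers of heterogeneous field data sets.
    """
    if model.bmu_assignments is None:
        raise ValueError("model has no BMU assignments")
    clusters = np.asarray(unit_labels)[model.bmu_assignments]
    out = []
    for i, c in enumerate(clusters):
        if np.sum(clusters == c) == 1:
            out.append(i)
    return out


def histogram_l1_distance(counts: np.ndarray, reference_pmf: np.ndarray) -> float:
    """L1 distance between a normalised histogram and a reference pmf."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    return float(np.abs(counts / total - np.asarray(reference_pmf)).sum())
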