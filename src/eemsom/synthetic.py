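"""Synthetic EEM data sets with planted fluorophores and ground truth.

The generator emulates a heterogeneous riverine DOM survey: every sample
is a non-negative mixture of a small number of overlapping Gaussian
product fluorophores with log-normally distributed, cross-correlated
loadings, additive Gaussian noise, and a few outlier samples that carry a
unique extra peak at high loading (industrial-effluent analogues).  The
default scenario plants four fluorophores in the classical peak regions:
tyrosine-like B, tryptophan-like T, and the humic-like A and C peaks.

Ground truth (dominant fluorophore per wavelength coordinate, the loading
matrix, outlier identities) is returned alongside, so the full two-stage
SOM pipeline can be scored for component recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from .eem_io import EEM, EEMDataset, assemble_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluorophoreSpec:
    """Gaussian-product fluorophore peak (optionally double excitation)."""

    name: str
    ex_center: float
    em_center: float
    ex_sigma: float
    em_sigma: float
    ex2_center: float | None = None
    ex2_sigma: float | None = None
    ex2_height: float = 0.0

    def __post_init__(self) -> None:
        if self.ex_sigma <= 0 or self.em_sigma <= 0:
            raise ValueError("sigmas must be positive")


@dataclass(frozen=True)
class Scenario:
    """Study conditions for a synthetic EEM survey.

    The wavelength grid defaults to excitation 230-410 nm and emission
    310-530 nm at 5-nm steps.  ``loading_corr`` is the correlation matrix
    of the log-loadings across fluorophores; ``noise_sd`` is the Gaussian
    noise standard deviation relative to each sample's maximum signal.
    """

    fluorophores: tuple[FluorophoreSpec, ...]
    ex_range: tuple[float, float, float] = (230.0, 410.0, 5.0)  # lo, hi, step
    em_range: tuple[float, float, float] = (310.0, 530.0, 5.0)
    loading_corr: tuple[tuple[float, ...], ...] | None = None
    loading_sigma_log: float = 0.5
    noise_sd: float = 0.02
    n_outliers: int = 3
    outlier_loading_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi, step in (self.ex_range, self.em_range):
            n = (hi - lo) / step
            if abs(n - round(n)) > 1e-9:
                raise ValueError("step must divide the wavelength range")
        if self.loading_corr is not None:
            c = np.asarray(self.loading_corr, dtype=float)
            if c.shape != (len(self.fluorophores),) * 2:
                raise ValueError("loading_corr shape must match fluorophore count")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("loading_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("loading_corr must be positive semidefinite")

    @property
    def ex_wavelengths(self) -> np.ndarray:
        lo, hi, step = self.ex_range
        return np.arange(lo, hi + step / 2, step)

    @property
    def em_wavelengths(self) -> np.ndarray:
        lo, hi, step = self.em_range
        return np.arange(lo, hi + step / 2, step)

    @property
    def corr_matrix(self) -> np.ndarray:
        if self.loading_corr is None:
            return np.eye(len(self.fluorophores))
        return np.asarray(self.loading_corr, dtype=float)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        data = yaml.safe_load(Path(path).read_text())
        fl = tuple(FluorophoreSpec(**f) for f in data.pop("fluorophores"))
        for key in ("ex_range", "em_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "loading_corr" in data and data["loading_corr"] is not None:
            data["loading_corr"] = tuple(tuple(r) for r in data["loading_corr"])
        return cls(fluorophores=fl, **data)


#: Extra peaks granted to outlier samples; each outlier gets its own.
OUTLIER_PEAKS = (
    FluorophoreSpec("industrial_1", 310.0, 350.0, 8.0, 10.0),
    FluorophoreSpec("industrial_2", 380.0, 420.0, 10.0, 12.0),
    FluorophoreSpec("industrial_3", 240.0, 490.0, 10.0, 15.0),
)


def coble4_scenario(**overrides) -> Scenario:
    """Default four-fluorophore scenario in the classical peak regions.

    B (tyrosine-like, 275/310), T (tryptophan-like, 275/340), A (humic,
    250/430 with a secondary UV excitation at 230) and C (humic, 340/440).
    Log-loading correlations: 0.6 within the humic pair (A, C), 0.5 within
    the protein pair (B, T) and 0.1 across groups -- strong enough to
    mimic common DOM covariation, weak enough to keep the components
    statistically distinct.
    """
    fluorophores = (
        FluorophoreSpec("B", 275.0, 310.0, 12.0, 15.0),
        FluorophoreSpec("T", 275.0, 340.0, 12.0, 20.0),
        FluorophoreSpec("A", 250.0, 430.0, 20.0, 40.0,
                        ex2_center=230.0, ex2_sigma=15.0, ex2_height=0.9),
        FluorophoreSpec("C", 340.0, 440.0, 25.0, 45.0),
    )
    corr = (
        (1.0, 0.5, 0.1, 0.1),
        (0.5, 1.0, 0.1, 0.1),
        (0.1, 0.1, 1.0, 0.6),
        (0.1, 0.1, 0.6, 1.0),
    )
    params = dict(fluorophores=fluorophores, loading_corr=corr)
    params.update(overrides)
    return Scenario(**params)


@dataclass
class GroundTruth:
    """Planted structure of a generated data set."""

    true_coordinate_labels: np.ndarray  # (P,), 0 = background/unassigned
    true_loadings: np.ndarray  # (N, kappa)
    outlier_ids: list[str]
    coordinate_index: np.ndarray

    def to_csv(self, labels_path, loadings_path=None, sample_ids=None) -> None:
        pd.DataFrame(
            {
                "ex": self.coordinate_index[:, 0],
                "em": self.coordinate_index[:, 1],
                "true_label": self.true_coordinate_labels,
            }
        ).to_csv(labels_path, index=False)
        if loadings_path is not None:
            df = pd.DataFrame(self.true_loadings)
            if sample_ids is not None:
                df.insert(0, "sample_id", sample_ids)
            df.to_csv(loadings_path, index=False)


# ---------------------------------------------------------------------------
# Kernels and generation
# ---------------------------------------------------------------------------

def peak_kernel(
    spec: FluorophoreSpec, ex: np.ndarray, em: np.ndarray
) -> np.ndarray:
    """Gaussian-product peak surface, scaled to maximum 1 on the grid.

    ``K(ex, em) = g(ex) * exp(-(em - em0)^2 / (2 sigma_em^2))`` where
    ``g`` is a Gaussian in excitation plus an optional secondary
    excitation peak.  Cells with em <= ex are set to zero (fluorescence
    is Stokes-shifted; emission above excitation only).
    """
    ex = np.asarray(ex, dtype=float)
    em = np.asarray(em, dtype=float)
    gx = np.exp(-((ex - spec.ex_center) ** 2) / (2 * spec.ex_sigma**2))
    if spec.ex2_center is not None and spec.ex2_height > 0:
        s2 = spec.ex2_sigma or spec.ex_sigma
        gx = gx + spec.ex2_height * np.exp(
            -((ex - spec.ex2_center) ** 2) / (2 * s2**2)
        )
    gm = np.exp(-((em - spec.em_center) ** 2) / (2 * spec.em_sigma**2))
    k = np.outer(gx, gm)
    k[em[None, :] <= ex[:, None]] = 0.0
    peak = k.max()
    if peak > 0:
        k = k / peak
    return k


def stokes_mask(ex: np.ndarray, em: np.ndarray) -> np.ndarray:
    """Validity mask: measured only where emission exceeds excitation."""
    return em[None, :] > ex[:, None]


def _correlated_lognormal(
    rng: np.random.Generator, n: int, corr: np.ndarray, sigma_log: float
) -> np.ndarray:
    """Log-normal loadings whose log correlations follow ``corr``.

    Gaussian copula: z ~ MVN(0, corr); loading = exp(sigma_log * z), so
    the log-loadings are exactly jointly Gaussian with the requested
    correlation matrix and median loading 1.
    """
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    z = rng.standard_normal((n, len(corr))) @ L.T
    return np.exp(sigma_log * z)


def generate_dataset(
    scn: Scenario, n_samples: int, seed: int | None = None
) -> tuple[EEMDataset, GroundTruth]:
    """Generate a synthetic EEM survey plus its ground truth.

    Sample n is ``sum_f loading[n, f] * K_f`` plus Gaussian noise with
    standard deviation ``noise_sd`` times the sample's maximum noiseless
    signal, clipped at zero (intensities are physically non-negative).
    ``n_outliers`` sample indices drawn by the seeded RNG additionally
    receive a unique extra peak at a loading of
    ``outlier_loading_factor`` times the median total loading.
    Deterministic for a given seed.
    """
    if n_samples < 5:
        raise ValueError("need at least 5 samples")
    seed = scn.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ex, em = scn.ex_wavelengths, scn.em_wavelengths
    mask = stokes_mask(ex, em)
    kernels = np.array([peak_kernel(f, ex, em) for f in scn.fluorophores])
    loadings = _correlated_lognormal(
        rng, n_samples, scn.corr_matrix, scn.loading_sigma_log
    )

    outlier_idx = (
        np.sort(rng.choice(n_samples, size=scn.n_outliers, replace=False))
        if scn.n_outliers
        else np.array([], dtype=int)
    )
    outlier_load = scn.outlier_loading_factor * float(
        np.median(loadings.sum(axis=1))
    )

    eems = []
    metas = []
    for n in range(n_samples):
        surface = np.tensordot(loadings[n], kernels, axes=1)
        site = "synthetic"
        if n in outlier_idx:
            which = int(np.nonzero(outlier_idx == n)[0][0]) % len(OUTLIER_PEAKS)
            surface = surface + outlier_load * peak_kernel(
                OUTLIER_PEAKS[which], ex, em
            )
            site = "tributary_industrial"
        peak = surface[mask].max()
        noisy = surface + rng.normal(0.0, scn.noise_sd * peak, size=surface.shape)
        # fluorescence intensities are physically non-negative
        noisy = np.clip(noisy, 0.0, None)
        sid = f"syn{n:03d}"
        eems.append(EEM(sid, ex, em, np.where(mask, noisy, np.nan), mask=mask.copy()))
        metas.append(
            {"sample_id": sid, "site_category": site, "flow_category": "na",
             "discharge_Q": np.nan, "DOC": np.nan}
        )
    meta = pd.DataFrame(metas).set_index("sample_id", drop=False)
    ds = assemble_dataset(eems, meta=meta)
    truth = GroundTruth(
        true_coordinate_labels=planted_labels(scn),
        true_loadings=loadings,
        outlier_ids=[f"syn{i:03d}" for i in sorted(outlier_idx)],
        coordinate_index=ds.coordinate_index,
    )
    return ds, truth


def planted_labels(scn: Scenario, threshold: float = 0.05) -> np.ndarray:
    """Dominant-fluorophore label per masked wavelength coordinate.

    A coordinate is labelled with the argmax of the noiseless kernels at
    that point when the largest kernel value reaches ``threshold``;
    background coordinates get 0 and are excluded from recovery scoring.
    Labels follow the coordinate-index (excitation-major) ordering.
    """
    ex, em = scn.ex_wavelengths, scn.em_wavelengths
    mask = stokes_mask(ex, em)
    kernels = np.array([peak_kernel(f, ex, em) for f in scn.fluorophores])
    best = kernels.argmax(axis=0) + 1
    strength = kernels.max(axis=0)
    labels = np.where(strength >= threshold, best, 0)
    return labels[mask]


def recovery_score(
    estimated_labels: np.ndarray, truth: GroundTruth, n_planted: int | None = None
) -> dict[str, float | bool]:
    """Score an estimated coordinate partition against the planted truth.

    Adjusted Rand index over the coordinates with an assigned truth label
    (background excluded), plus whether the estimated component count
    matches the number of planted fluorophores.
    """
    est = np.asarray(estimated_labels)
    tru = np.asarray(truth.true_coordinate_labels)
    if est.shape != tru.shape:
        raise ValueError("label vectors are not on the same coordinate grid")
    keep = tru > 0
    ari = float(adjusted_rand_score(tru[keep], est[keep]))
    if n_planted is None:
        n_planted = int(tru.max())
    k_est = len(np.unique(est))
    return {"ari": ari, "k_match": bool(k_est == n_planted)}


def write_scenario(scn: Scenario, path: str | Path) -> None:
    """Serialise a scenario to YAML (round-trips with ``Scenario.from_yaml``)."""
    data = {
        "ex_range": list(scn.ex_range),
        "em_range": list(scn.em_range),
        "loading_sigma_log": scn.loading_sigma_log,
        "noise_sd": scn.noise_sd,
        "n_outliers": scn.n_outliers,
        "outlier_loading_factor": scn.outlier_loading_factor,
        "seed": scn.seed,
        "loading_corr": None
        if scn.loading_corr is None
        else [list(r) for r in scn.corr_matrix],
        "fluorophores": [
            {k: v for k, v in vars(f).items() if v is not None}
            for f in scn.fluorophores
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
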