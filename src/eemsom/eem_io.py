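"""Data model and file I/O for EEMs, absorbance spectra and sample metadata.

An :class:`EEM` stores one sample's fluorescence landscape ``I(lambda_ex,
lambda_em)`` on a rectangular wavelength grid together with a boolean
validity mask.  The mask, not NaN-filling, is the canonical representation
of non-rectangular coverage (e.g. synchronous-scan geometries): unmeasured
cells are masked and every statistic downstream operates only on jointly
measured coordinates.

A collection of grid-aligned EEMs plus per-sample metadata forms an
:class:`EEMDataset`, which linearises to the N x P data matrix consumed by
the self-organising-map modules.  The canonical coordinate ordering is
excitation-major ascending and is the single linearisation used everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Forward-only processing states of an EEM's intensity units.
UNITS_STATES = ("raw", "corrected", "raman_normalised", "max_normalised")

SITE_CATEGORIES = (
    "headwaters",
    "middle",
    "lowland",
    "tributary_natural",
    "tributary_wwtp",
    "tributary_industrial",
    "synthetic",
)
FLOW_CATEGORIES = ("flood", "baseflow", "drought", "na")

Dialect = Literal["wide_csv", "long_csv"]


def _check_strictly_increasing(values: np.ndarray, name: str) -> None:
    if values.ndim != 1 or len(values) == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.diff(values) > 0):
        raise ValueError(f"{name} must be strictly increasing, got {values!r}")


@dataclass
class EEM:
    """One sample's excitation-emission matrix on a wavelength grid.

    Parameters
    ----------
    sample_id:
        Identifier of the sample.
    ex_wavelengths, em_wavelengths:
        Strictly increasing excitation / emission wavelengths in nm.
    intensity:
        Array of shape ``(n_ex, n_em)``; arbitrary or Raman units.
        Masked cells are stored as NaN.
    mask:
        Boolean array of the same shape; True where the coordinate was
        measured.  Unmeasured cells are masked, never silently zero.
    units_state:
        One of ``raw -> corrected -> raman_normalised -> max_normalised``;
        transitions are forward-only.
    provenance:
        Names of processing stages applied so far, in order.
    """

    sample_id: str
    ex_wavelengths: np.ndarray
    em_wavelengths: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray | None = None
    units_state: str = "raw"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ex_wavelengths = np.asarray(self.ex_wavelengths, dtype=float)
        self.em_wavelengths = np.asarray(self.em_wavelengths, dtype=float)
        _check_strictly_increasing(self.ex_wavelengths, "ex_wavelengths")
        _check_strictly_increasing(self.em_wavelengths, "em_wavelengths")
        self.intensity = np.asarray(self.intensity, dtype=float)
        shape = (len(self.ex_wavelengths), len(self.em_wavelengths))
        if self.intensity.shape != shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid {shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.intensity)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError(f"mask shape {self.mask.shape} does not match grid {shape}")
        if self.units_state not in UNITS_STATES:
            raise ValueError(f"unknown units_state {self.units_state!r}")
        # Masked cells are represented uniformly as NaN.
        self.intensity = np.where(self.mask, self.intensity, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def with_intensity(
        self, intensity: np.ndarray, units_state: str | None = None, stage: str | None = None
    ) -> "EEM":
        """Return a copy with new intensities, advancing ``units_state``.

        ``units_state`` may only move forward along the processing chain.
        """
        new_state = self.units_state if units_state is None else units_state
        if UNITS_STATES.index(new_state) < UNITS_STATES.index(self.units_state):
            raise ValueError(
                f"units_state may not go backwards: {self.units_state} -> {new_state}"
            )
        prov = list(self.provenance) + ([stage] if stage else [])
        return replace(
            self, intensity=np.array(intensity, dtype=float),
            mask=self.mask.copy(), units_state=new_state, provenance=prov,
        )

    def value_at(self, ex: float, em: float, tol: float = 2.0) -> float:
        """Intensity at the grid point nearest (ex, em), within ``tol`` nm.

        Returns NaN when the nearest point is masked; raises if no grid
        point lies within tolerance.
        """
        i = int(np.argmin(np.abs(self.ex_wavelengths - ex)))
        j = int(np.argmin(np.abs(self.em_wavelengths - em)))
        dex = abs(self.ex_wavelengths[i] - ex)
        dem = abs(self.em_wavelengths[j] - em)
        if dex > tol or dem > tol:
            raise ValueError(
                f"no grid point within {tol} nm of (ex={ex}, em={em}); "
                f"nearest is ({self.ex_wavelengths[i]}, {self.em_wavelengths[j]})"
            )
        if dex > 0 or dem > 0:
            logger.debug(
                "value_at(%s, %s): using nearest grid point (%s, %s)",
                ex, em, self.ex_wavelengths[i], self.em_wavelengths[j],
            )
        return float(self.intensity[i, j])


@dataclass
class AbsorbanceSpectrum:
    """Decadic absorbance spectrum for inner-filter correction and SUVA."""

    sample_id: str
    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        _check_strictly_increasing(self.wavelengths, "wavelengths")
        if self.absorbance.shape != self.wavelengths.shape:
            raise ValueError("absorbance and wavelengths must have the same length")
        if not self.pathlength_cm > 0:
            raise ValueError("pathlength must be positive")

    def a1cm(self, wavelength: float | np.ndarray) -> np.ndarray:
        """Absorbance rescaled to a 1-cm path, linearly interpolated."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        w = np.asarray(wavelength, dtype=float)
        if np.any(w < lo) or np.any(w > hi):
            raise ValueError(
                f"requested wavelength outside measured range [{lo}, {hi}] nm"
            )
        return np.interp(w, self.wavelengths, self.absorbance) / self.pathlength_cm


@dataclass
class SampleMeta:
    """Per-sample metadata: site, hydrological condition, discharge, DOC."""

    sample_id: str
    site_category: str = "synthetic"
    flow_category: str = "na"
    discharge_Q: float = np.nan
    DOC: float = np.nan

    def __post_init__(self) -> None:
        if self.site_category not in SITE_CATEGORIES:
            raise ValueError(f"unknown site_category {self.site_category!r}")
        if self.flow_category not in FLOW_CATEGORIES:
            raise ValueError(f"unknown flow_category {self.flow_category!r}")


def flow_category_from_discharge(q: float) -> str:
    """Operational flow class from discharge Q (m3/s).

    flood: Q > 4; drought: Q < 1; baseflow: 1 <= Q <= 4; ``na`` if missing.
    """
    if q is None or not np.isfinite(q):
        return "na"
    if q > 4:
        return "flood"
    if q < 1:
        return "drought"
    return "baseflow"


@dataclass
class EEMDataset:
    """Grid-aligned EEM collection with a shared mask and linearisation.

    ``coordinate_index`` is the (P, 2) array of (ex, em) pairs where the
    shared mask is True, in excitation-major ascending order.  It is the
    single canonical ordering used by every downstream module.
    """

    eems: list[EEM]
    meta: pd.DataFrame | None = None
    mask: np.ndarray | None = None
    coordinate_index: np.ndarray | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.eems]

    @property
    def n_samples(self) -> int:
        return len(self.eems)

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinate_index)

    @property
    def ex_wavelengths(self) -> np.ndarray:
        return self.eems[0].ex_wavelengths

    @property
    def em_wavelengths(self) -> np.ndarray:
        return self.eems[0].em_wavelengths


# ---------------------------------------------------------------------------
# EEM file I/O
# ---------------------------------------------------------------------------

def _read_header_comments(path: Path) -> tuple[dict[str, str], int]:
    """Parse leading ``# key: value`` comment lines; return (meta, n_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n


def read_eem(path: str | Path, dialect: Dialect = "wide_csv") -> EEM:
    """Read one EEM from a CSV file.

    ``wide_csv``: first header cell ``ex\\em``, remaining header cells are
    emission wavelengths; one row per excitation wavelength.  ``long_csv``:
    columns ``ex,em,intensity``; an empty/NA intensity marks a masked cell,
    as does a grid pair absent from the file.

    Leading ``# key: value`` comment lines may carry ``sample_id`` and
    ``units_state``; otherwise the file stem names the sample and the data
    are taken as raw.
    """
    path = Path(path)
    header, n_skip = _read_header_comments(path)
    sample_id = header.get("sample_id", path.stem)
    units_state = header.get("units_state", "raw")

    if dialect == "wide_csv":
        df = pd.read_csv(path, index_col=0, skiprows=n_skip, float_precision="round_trip")
        ex = df.index.to_numpy(dtype=float)
        em = np.array([float(c) for c in df.columns])
        _require_unique(ex, "excitation", path)
        _require_unique(em, "emission", path)
        _check_strictly_increasing(ex, f"{path}: excitation wavelengths")
        _check_strictly_increasing(em, f"{path}: emission wavelengths")
        intensity = df.to_numpy(dtype=float)
        return EEM(sample_id, ex, em, intensity, units_state=units_state)

    if dialect == "long_csv":
        df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
        expected = {"ex", "em", "intensity"}
        if not expected.issubset(df.columns):
            raise ValueError(f"{path}: long_csv needs columns {sorted(expected)}")
        dup = df.duplicated(subset=["ex", "em"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(
                f"{path}: duplicate coordinate (ex={r['ex']}, em={r['em']})"
            )
        ex = np.sort(df["ex"].unique().astype(float))
        em = np.sort(df["em"].unique().astype(float))
        _check_strictly_increasing(ex, f"{path}: excitation wavelengths")
        _check_strictly_increasing(em, f"{path}: emission wavelengths")
        intensity = np.full((len(ex), len(em)), np.nan)
        i = np.searchsorted(ex, df["ex"].to_numpy(dtype=float))
        j = np.searchsorted(em, df["em"].to_numpy(dtype=float))
        intensity[i, j] = df["intensity"].to_numpy(dtype=float)
        return EEM(sample_id, ex, em, intensity, units_state=units_state)

    raise ValueError(f"unknown dialect {dialect!r}")


def _require_unique(values: np.ndarray, axis: str, path: Path) -> None:
    uniq, counts = np.unique(values, return_counts=True)
    if np.any(counts > 1):
        raise ValueError(f"{path}: duplicate {axis} wavelength {uniq[counts > 1][0]}")


def write_eem(eem: EEM, path: str | Path, dialect: Dialect = "wide_csv") -> None:
    """Write an EEM to CSV; lossless round-trip with :func:`read_eem`.

    Masked cells serialise as empty fields, never as 0.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {eem.sample_id}\n")
        fh.write(f"# units_state: {eem.units_state}\n")
        if dialect == "wide_csv":
            fh.write(
                "ex\\em," + ",".join(repr(float(w)) for w in eem.em_wavelengths) + "\n"
            )
            for i, ex in enumerate(eem.ex_wavelengths):
                cells = [
                    repr(float(eem.intensity[i, j])) if eem.mask[i, j] else ""
                    for j in range(len(eem.em_wavelengths))
                ]
                fh.write(repr(float(ex)) + "," + ",".join(cells) + "\n")
        elif dialect == "long_csv":
            fh.write("ex,em,intensity\n")
            for i, ex in enumerate(eem.ex_wavelengths):
                for j, em in enumerate(eem.em_wavelengths):
                    val = repr(float(eem.intensity[i, j])) if eem.mask[i, j] else ""
                    fh.write(f"{float(ex)!r},{float(em)!r},{val}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_absorbance(path: str | Path, pathlength_cm: float = 1.0) -> AbsorbanceSpectrum:
    """Read a two-column (wavelength, absorbance) CSV.

    A ``# pathlength_cm:`` header comment overrides the argument.
    """
    path = Path(path)
    header, n_skip = _read_header_comments(path)
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    pl = float(header.get("pathlength_cm", pathlength_cm))
    cols = list(df.columns)
    return AbsorbanceSpectrum(
        sample_id=header.get("sample_id", path.stem),
        wavelengths=df[cols[0]].to_numpy(dtype=float),
        absorbance=df[cols[1]].to_numpy(dtype=float),
        pathlength_cm=pl,
    )


METADATA_COLUMNS = ["sample_id", "site_category", "flow_category", "discharge_Q", "DOC"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table, indexed by ``sample_id``.

    Missing ``flow_category`` values are derived from discharge with the
    operational cut-offs (flood Q>4, drought Q<1, baseflow otherwise).
    """
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns {sorted(missing)}")
    df = df.set_index("sample_id", drop=False)
    derived = df["discharge_Q"].map(flow_category_from_discharge)
    blank = df["flow_category"].isna() | (df["flow_category"] == "")
    df.loc[blank, "flow_category"] = derived[blank]
    for sid, row in df.iterrows():
        SampleMeta(
            sample_id=str(sid),
            site_category=row["site_category"],
            flow_category=row["flow_category"],
            discharge_Q=row["discharge_Q"],
            DOC=row["DOC"],
        )
    return df


# ---------------------------------------------------------------------------
# Dataset assembly and linearisation
# ---------------------------------------------------------------------------

GRID_TOL_NM = 1e-9


def assemble_dataset(
    eems: Iterable[EEM], meta: pd.DataFrame | None = None
) -> EEMDataset:
    """Align EEMs on their shared grid and build the coordinate index.

    The shared mask is the intersection of per-sample masks; a warning is
    logged when intersecting drops more than 5% of any sample's measured
    cells.  Grids must agree within 1e-9 nm.
    """
    eems = list(eems)
    if len(eems) < 2:
        raise ValueError("a dataset needs at least 2 samples")
    ref = eems[0]
    bad = [
        e.sample_id
        for e in eems[1:]
        if e.shape != ref.shape
        or np.any(np.abs(e.ex_wavelengths - ref.ex_wavelengths) > GRID_TOL_NM)
        or np.any(np.abs(e.em_wavelengths - ref.em_wavelengths) > GRID_TOL_NM)
    ]
    if bad:
        raise ValueError(
            f"wavelength grids do not match {ref.sample_id!r}: offending samples {bad}"
        )
    mask = np.logical_and.reduce([e.mask for e in eems])
    for e in eems:
        own = int(e.mask.sum())
        kept = int((e.mask & mask).sum())
        if own and kept < 0.95 * own:
            logger.warning(
                "sample %s loses %d of %d measured cells to the shared mask",
                e.sample_id, own - kept, own,
            )
    ii, jj = np.nonzero(mask)  # row-major: ex-major ascending, em minor
    coordinate_index = np.column_stack(
        [ref.ex_wavelengths[ii], ref.em_wavelengths[jj]]
    )
    if len(coordinate_index) < 2:
        raise ValueError("fewer than 2 jointly measured coordinates")
    return EEMDataset(eems=eems, meta=meta, mask=mask, coordinate_index=coordinate_index)


def linearize(ds: EEMDataset) -> tuple[np.ndarray, np.ndarray]:
    """Unroll the dataset to an (N, P) matrix over the coordinate index.

    Row n, column p holds sample n's intensity at ``coordinate_index[p]``.
    """
    flat_idx = np.flatnonzero(ds.mask.ravel())
    X = np.empty((ds.n_samples, len(flat_idx)))
    for n, e in enumerate(ds.eems):
        X[n] = e.intensity.ravel()[flat_idx]
    return X, ds.coordinate_index


def delinearize(ds: EEMDataset, X: np.ndarray) -> list[EEM]:
    """Inverse of :func:`linearize`: rebuild EEM grids from matrix rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ds.n_coordinates:
        raise ValueError("column count does not match coordinate_index")
    out = []
    flat_idx = np.flatnonzero(ds.mask.ravel())
    for n in range(X.shape[0]):
        grid = np.full(ds.mask.shape, np.nan)
        grid.ravel()[flat_idx] = X[n]
        sid = ds.eems[n].sample_id if n < ds.n_samples else f"row{n}"
        state = ds.eems[n].units_state if n < ds.n_samples else "raw"
        out.append(
            EEM(sid, ds.ex_wavelengths, ds.em_wavelengths, grid,
                mask=ds.mask.copy(), units_state=state)
        )
    return out
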