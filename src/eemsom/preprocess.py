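"""Correction and normalisation chain for raw EEMs, plus optical indices.

The chain follows standard fluorometric practice for dissolved organic
matter: instrument spectral correction, normalisation by the area under
the water Raman peak (excitation 350 nm, emission 371-428 nm), absorbance
based inner-filter correction, and subtraction of a blank that has been
taken through the same corrections.  A final per-sample division by the
EEM maximum removes concentration effects before SOM analysis so that
only qualitative spectral variation remains.

Three scalar descriptors are computed alongside: the humification index
HIX (ratio of emission areas 435-480 over 330-345 at excitation 254 nm),
the fluorescence index FI (intensity ratio at excitation 370 nm, emission
470 over 520 nm) and SUVA (Napierian absorption coefficient at 254 nm per
unit DOC, L mg-C^-1 m^-1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eem_io import EEM, AbsorbanceSpectrum

logger = logging.getLogger(__name__)

#: Raman-normalisation window: excitation (nm) and emission span (nm).
RAMAN_EX = 350.0
RAMAN_EM_WINDOW = (371.0, 428.0)

HIX_EX = 254.0
HIX_NUM_WINDOW = (435.0, 480.0)
HIX_DEN_WINDOW = (330.0, 345.0)

FI_EX = 370.0
FI_EM_NUM = 470.0
FI_EM_DEN = 520.0

#: Nearest-grid-point tolerance for index wavelengths (nm); tolerates
#: 5-nm-bandwidth instruments without silent extrapolation.
WAVELENGTH_TOL_NM = 2.0


@dataclass(frozen=True)
class CorrectionFunctions:
    """Multiplicative excitation / emission spectral-correction factors."""

    ex_wavelengths: np.ndarray
    ex_factors: np.ndarray
    em_wavelengths: np.ndarray
    em_factors: np.ndarray

    def __post_init__(self) -> None:
        for w, f, name in (
            (self.ex_wavelengths, self.ex_factors, "ex"),
            (self.em_wavelengths, self.em_factors, "em"),
        ):
            if len(np.atleast_1d(w)) != len(np.atleast_1d(f)):
                raise ValueError(f"{name} wavelengths/factors length mismatch")
            if np.any(np.asarray(f) <= 0):
                raise ValueError(f"{name} correction factors must be positive")

    @classmethod
    def identity(cls, ex: np.ndarray, em: np.ndarray) -> "CorrectionFunctions":
        return cls(np.asarray(ex, float), np.ones(len(ex)),
                   np.asarray(em, float), np.ones(len(em)))

    @classmethod
    def from_csv(cls, ex_path: str | Path, em_path: str | Path) -> "CorrectionFunctions":
        """Load two-column (wavelength, factor) CSVs for each axis."""
        exd = pd.read_csv(ex_path, comment="#")
        emd = pd.read_csv(em_path, comment="#")
        return cls(
            exd.iloc[:, 0].to_numpy(float), exd.iloc[:, 1].to_numpy(float),
            emd.iloc[:, 0].to_numpy(float), emd.iloc[:, 1].to_numpy(float),
        )

    def on_grid(self, ex: np.ndarray, em: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Factors linearly interpolated onto a wavelength grid."""
        fex = np.interp(ex, np.atleast_1d(self.ex_wavelengths),
                        np.atleast_1d(self.ex_factors))
        fem = np.interp(em, np.atleast_1d(self.em_wavelengths),
                        np.atleast_1d(self.em_factors))
        return fex, fem


@dataclass
class OpticalIndices:
    """Scalar optical descriptors of DOM character."""

    hix: float = np.nan
    fi: float = np.nan
    suva: float = np.nan
    raman_area: float = np.nan


# ---------------------------------------------------------------------------
# Individual stages
# ---------------------------------------------------------------------------

def apply_spectral_correction(eem: EEM, corr: CorrectionFunctions) -> EEM:
    """Multiply each cell by its excitation and emission correction factor."""
    if eem.units_state != "raw":
        raise ValueError("spectral correction applies to raw EEMs only")
    fex, fem = corr.on_grid(eem.ex_wavelengths, eem.em_wavelengths)
    if np.any(fex <= 0) or np.any(fem <= 0):
        raise ValueError("correction factors must be strictly positive")
    out = eem.intensity * np.outer(fex, fem)
    return eem.with_intensity(out, units_state="corrected", stage="spectral_correction")


def _emission_window_area(
    eem: EEM, ex: float, window: tuple[float, float], method: str = "trapezoid"
) -> float:
    """Integral of I(ex, em) over an emission window.

    The excitation row is the grid point nearest ``ex`` within the
    tolerance; window endpoints off the grid are linearly interpolated.
    ``method='sum'`` adds the raw grid points inside the window instead.
    """
    i = int(np.argmin(np.abs(eem.ex_wavelengths - ex)))
    if abs(eem.ex_wavelengths[i] - ex) > WAVELENGTH_TOL_NM:
        raise ValueError(f"no excitation row within {WAVELENGTH_TOL_NM} nm of {ex} nm")
    lo, hi = window
    em = eem.em_wavelengths
    if em[0] > lo or em[-1] < hi:
        raise ValueError(
            f"emission coverage [{em[0]}, {em[-1]}] nm does not span [{lo}, {hi}] nm"
        )
    row = eem.intensity[i]
    inside = (em >= lo) & (em <= hi)
    if not np.all(np.isfinite(row[inside])):
        raise ValueError("masked cells inside the integration window")
    if method == "sum":
        return float(np.sum(row[inside]))
    pts_w = np.concatenate(([lo], em[inside & (em > lo) & (em < hi)], [hi]))
    pts_w = np.unique(pts_w)
    pts_i = np.interp(pts_w, em[np.isfinite(row)], row[np.isfinite(row)])
    return float(np.trapezoid(pts_i, pts_w))


def raman_area(blank: EEM) -> float:
    """Area under the water Raman peak of a blank EEM.

    Trapezoidal integral of I(350, em) over emission 371-428 nm; the
    quantity by which Raman normalisation divides.
    """
    return _emission_window_area(blank, RAMAN_EX, RAMAN_EM_WINDOW)


def raman_normalize(eem: EEM, area: float) -> EEM:
    """Divide all intensities by the Raman-peak area (-> Raman units)."""
    if not area > 0:
        raise ValueError(f"Raman area must be positive, got {area}")
    if eem.units_state == "raman_normalised":
        raise ValueError("EEM is already Raman-normalised")
    return eem.with_intensity(
        eem.intensity / area, units_state="raman_normalised", stage="raman_normalisation"
    )


def inner_filter_correct(eem: EEM, abs_spec: AbsorbanceSpectrum) -> EEM:
    """Absorbance-based inner-filter correction.

    ``I'(ex, em) = I(ex, em) * 10 ** ((A(ex) + A(em)) / 2)`` with A the
    decadic absorbance rescaled to a 1-cm path and interpolated to the
    EEM wavelengths.  Negative absorbances are clipped to zero with a
    warning; total absorbances above 1.5 trigger a reliability warning.
    """
    a_ex = np.asarray(abs_spec.a1cm(eem.ex_wavelengths), dtype=float)
    a_em = np.asarray(abs_spec.a1cm(eem.em_wavelengths), dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        warnings.warn("negative absorbance clipped to 0", stacklevel=2)
        a_ex = np.clip(a_ex, 0.0, None)
        a_em = np.clip(a_em, 0.0, None)
    total = a_ex[:, None] + a_em[None, :]
    if np.any(total[eem.mask] > 1.5):
        warnings.warn(
            "A(ex)+A(em) exceeds 1.5 at measured coordinates; "
            "inner-filter correction is unreliable there", stacklevel=2,
        )
    out = eem.intensity * 10.0 ** (total / 2.0)
    return eem.with_intensity(out, stage="inner_filter_correction")


def subtract_blank(eem: EEM, blank: EEM) -> EEM:
    """Subtract a blank EEM cell by cell; negatives are kept, not clipped."""
    if eem.shape != blank.shape or np.any(
        eem.ex_wavelengths != blank.ex_wavelengths
    ) or np.any(eem.em_wavelengths != blank.em_wavelengths):
        raise ValueError("sample and blank are not on the same wavelength grid")
    if eem.units_state != blank.units_state:
        raise ValueError(
            f"sample ({eem.units_state}) and blank ({blank.units_state}) "
            "must be in the same units state"
        )
    out = eem.intensity - blank.intensity
    n_neg = int(np.sum(out[eem.mask & blank.mask] < 0))
    if n_neg:
        logger.info(
            "%s: %d cells negative after blank subtraction (retained)",
            eem.sample_id, n_neg,
        )
    return eem.with_intensity(out, stage="blank_subtraction")


def max_normalize(eem: EEM) -> EEM:
    """Divide by the maximum over measured cells (resulting max = 1).

    Removes concentration effects so SOM training sees spectral shape only.
    """
    vals = eem.intensity[eem.mask]
    if vals.size == 0 or not np.nanmax(vals) > 0:
        raise ValueError(f"{eem.sample_id}: non-positive maximum, degenerate sample")
    return eem.with_intensity(
        eem.intensity / np.nanmax(vals), units_state="max_normalised",
        stage="max_normalisation",
    )


# ---------------------------------------------------------------------------
# Optical indices
# ---------------------------------------------------------------------------

def hix(eem: EEM, method: str = "trapezoid") -> float:
    """Humification index: emission area 435-480 over 330-345 at ex 254 nm.

    Returns NaN (logged) when the denominator is non-positive.
    """
    num = _emission_window_area(eem, HIX_EX, HIX_NUM_WINDOW, method=method)
    den = _emission_window_area(eem, HIX_EX, HIX_DEN_WINDOW, method=method)
    if den <= 0:
        logger.warning("%s: HIX undefined (denominator %.3g <= 0)", eem.sample_id, den)
        return float("nan")
    return num / den


def fi(eem: EEM) -> float:
    """Fluorescence index: I(370, 470) / I(370, 520).

    Returns NaN (logged) when either point is masked or the denominator is
    non-positive.
    """
    num = eem.value_at(FI_EX, FI_EM_NUM)
    den = eem.value_at(FI_EX, FI_EM_DEN)
    if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
        logger.warning("%s: FI undefined", eem.sample_id)
        return float("nan")
    return num / den


def suva(abs_spec: AbsorbanceSpectrum, doc_mg_per_l: float) -> float:
    """Specific UV absorbance (L mg-C^-1 m^-1).

    Napierian absorption coefficient at 254 nm, ``ln(10) * A_1cm(254) *
    100`` (per metre), divided by the DOC concentration.
    """
    if not doc_mg_per_l > 0:
        raise ValueError("DOC must be positive")
    a254 = float(abs_spec.a1cm(254.0))
    return np.log(10.0) * a254 * 100.0 / doc_mg_per_l


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class ChainConfig:
    """Stage toggles and parameters for :func:`run_correction_chain`."""

    spectral_correction: bool = True
    raman_normalisation: bool = True
    inner_filter: bool = True
    blank_subtraction: bool = True
    max_normalisation: bool = True
    compute_indices: bool = True
    hix_method: str = "trapezoid"
    doc_mg_per_l: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChainConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_correction_chain(
    eem: EEM,
    blank: EEM | None = None,
    corr: CorrectionFunctions | None = None,
    abs_spec: AbsorbanceSpectrum | None = None,
    config: ChainConfig | None = None,
) -> tuple[EEM, OpticalIndices]:
    """Run the correction chain in its canonical order.

    spectral correction -> Raman normalisation -> inner-filter correction
    -> blank subtraction -> optical indices -> max-normalisation.  The
    blank is taken through the same correction and normalisation stages
    before subtraction.  Each stage can be disabled via ``config``; stage
    provenance is recorded on the returned EEM.  HIX and FI are computed
    before max-normalisation (they are ratios, invariant to it anyway).
    """
    cfg = config or ChainConfig()
    indices = OpticalIndices()
    out = eem
    blk = blank

    if cfg.spectral_correction and corr is not None:
        out = apply_spectral_correction(out, corr)
        if blk is not None:
            blk = apply_spectral_correction(blk, corr)

    if cfg.raman_normalisation:
        if blk is None:
            raise ValueError("Raman normalisation requires a blank EEM")
        area = raman_area(blk)
        indices.raman_area = area
        out = raman_normalize(out, area)
        blk = raman_normalize(blk, area)

    if cfg.inner_filter and abs_spec is not None:
        out = inner_filter_correct(out, abs_spec)

    if cfg.blank_subtraction:
        if blk is None:
            raise ValueError("blank subtraction requires a blank EEM")
        out = subtract_blank(out, blk)

    if cfg.compute_indices:
        try:
            indices.hix = hix(out, method=cfg.hix_method)
        except ValueError as exc:
            logger.warning("%s: HIX not computed (%s)", eem.sample_id, exc)
        try:
            indices.fi = fi(out)
        except ValueError as exc:
            logger.warning("%s: FI not computed (%s)", eem.sample_id, exc)
        if abs_spec is not None and cfg.doc_mg_per_l is not None:
            indices.suva = suva(abs_spec, cfg.doc_mg_per_l)

    if cfg.max_normalisation:
        out = max_normalize(out)

    return out, indices
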