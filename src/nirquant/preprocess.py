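"""Spectral preprocessing operators.

Three scatter/noise corrections standard in NIR chemometrics, plus the
wavelength-wavelength correlation map used to visualize multicollinearity:

* Savitzky-Golay filtering: a moving-window least-squares polynomial fit,
  returning the ``deriv``-th derivative of the local fit *per index step*
  (no division by the wavenumber spacing). Edge points come from the
  first/last full-window fit evaluated off-center, so the output keeps the
  input length.
* SNV (standard normal variate): per-spectrum standardization with the
  sample (n-1) standard deviation.
* MSC (multiplicative scatter correction): per-spectrum affine regression
  on a reference spectrum; the reference defaults to the column mean of
  the set being corrected and is returned so a test set can reuse the
  reference fitted on training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet, ValidationError

METHODS = ("raw", "sg", "snv", "msc")


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing choice and its parameters.

    The Savitzky-Golay defaults (window 17, quadratic fit, first
    derivative) are the settings used throughout the model benchmarks.
    """

    method: str = "sg"
    sg_window: int = 17
    sg_polyorder: int = 2
    sg_deriv: int = 1
    msc_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 3")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ValueError("sg_polyorder must satisfy 0 <= polyorder < window")
        if not 0 <= self.sg_deriv <= self.sg_polyorder:
            raise ValueError("sg_deriv must satisfy 0 <= deriv <= polyorder")


def savitzky_golay(s: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Savitzky-Golay smoothing/derivative along the wavenumber axis.

    The derivative is taken with respect to the point index (``delta=1``),
    matching the common toolchain default for evenly gridded spectra.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.sg_window > s.n_points:
        raise ValueError(
            f"sg_window {cfg.sg_window} exceeds the {s.n_points}-point grid"
        )
    out = savgol_filter(
        s.absorbance,
        window_length=cfg.sg_window,
        polyorder=cfg.sg_polyorder,
        deriv=cfg.sg_deriv,
        delta=1.0,
        axis=1,
        mode="interp",
    )
    return s.with_absorbance(out)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: row-wise (x - mean) / sd with ddof=1."""
    A = s.absorbance
    mean = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd.ravel() == 0.0)[0]
    if zero.size:
        names = [s.sample_ids[i] for i in zero[:5]]
        raise ValidationError(f"zero-variance spectra cannot be SNV-scaled: {names}")
    return s.with_absorbance((A - mean) / sd)


def msc(
    s: SpectraSet, reference: np.ndarray | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction against ``reference``.

    Each spectrum x is regressed as ``x ~ a + b * reference`` by ordinary
    least squares over the points and corrected to ``(x - a) / b``. When
    ``reference`` is None the column mean of ``s`` is used — fit it on
    training rows and pass it explicitly for a test set. Returns the
    corrected set and the reference actually used.
    """
    A = s.absorbance
    if reference is None:
        reference = A.mean(axis=0)
    reference = np.asarray(reference, dtype=np.float64).ravel()
    if reference.size != s.n_points:
        raise ValueError("reference length must equal n_points")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0.0:
        raise ValidationError("constant MSC reference spectrum")
    b = (A - A.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.where(np.abs(b) < 1e-12)[0]
    if small.size:
        names = [s.sample_ids[i] for i in small[:5]]
        raise ValidationError(f"near-zero MSC slope for samples {names}")
    a = A.mean(axis=1) - b * reference.mean()
    corrected = (A - a[:, None]) / b[:, None]
    return s.with_absorbance(corrected), reference


def wavelength_correlation(s: SpectraSet) -> np.ndarray:
    """Pearson correlation between every pair of wavenumber channels across
    samples (the classic wavelength-wavelength correlation heatmap).

    Zero-variance channels have undefined correlations; their rows/columns
    are set to NaN and reported through a warning rather than silently
    zeroed. The diagonal stays 1 by convention.
    """
    if s.n_samples < 3:
        raise ValidationError("need at least 3 samples for a correlation map")
    A = s.absorbance
    sd = A.std(axis=0)
    constant = np.where(sd == 0.0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(A, rowvar=False)
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    if constant.size:
        warnings.warn(
            f"{constant.size} zero-variance channels have undefined "
            f"correlations (indices {constant[:5].tolist()}...)",
            RuntimeWarning,
            stacklevel=2,
        )
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    return r


def apply_method(
    s: SpectraSet, cfg: PreprocessConfig
) -> tuple[SpectraSet, np.ndarray | None]:
    """Dispatch a preprocessing method.

    Returns the transformed set and, for MSC, the reference spectrum that
    was used (fitted from ``s`` when the config carries none) so callers
    can apply the identical correction to held-out data.
    """
    if cfg.method == "raw":
        return s, None
    if cfg.method == "sg":
        return savitzky_golay(s, cfg), None
    if cfg.method == "snv":
        return snv(s), None
    out, ref = msc(s, cfg.msc_reference)
    return out, ref
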