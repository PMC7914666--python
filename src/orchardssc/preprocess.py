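"""Spectral preprocessing: Savitzky-Golay second derivative and windowing.

The modelling window is 729-975 nm (inclusive on both ends); derivative
spectra are computed on the full instrument grid first and cropped
afterwards, so the smoother never runs off the edge of the window of
interest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import spectra_matrix

__all__ = ["restrict_window", "second_derivative", "WINDOW_LOW_NM", "WINDOW_HIGH_NM"]

WINDOW_LOW_NM = 729.0
WINDOW_HIGH_NM = 975.0

_META_COLS = ("sample_id", "year", "temperature_C", "ssc_ref")


def _split(spectra: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    meta = spectra[[c for c in _META_COLS if c in spectra.columns]]
    wavelengths, X = spectra_matrix(spectra)
    if wavelengths.size == 0:
        raise ValueError("no wavelength columns found")
    steps = np.diff(wavelengths)
    if wavelengths.size > 1 and not np.allclose(steps, steps[0]):
        raise ValueError("wavelength grid is not uniform")
    if not np.all(np.isfinite(X)):
        raise ValueError("absorbance values must be finite")
    return meta.reset_index(drop=True), wavelengths, X


def _assemble(meta: pd.DataFrame, wavelengths: np.ndarray, X: np.ndarray) -> pd.DataFrame:
    cols = [str(int(round(v))) for v in wavelengths]
    return pd.concat([meta, pd.DataFrame(X, columns=cols)], axis=1)


def restrict_window(
    spectra: pd.DataFrame,
    low: float = WINDOW_LOW_NM,
    high: float = WINDOW_HIGH_NM,
) -> pd.DataFrame:
    """Keep only wavelengths ``low <= lambda <= high`` (bounds inclusive).

    Grid points are matched exactly; no interpolation is performed.  Raises
    ``ValueError`` if the window is empty or inverted.
    """
    if low >= high:
        raise ValueError(f"window [{low}, {high}] nm is empty")
    meta, wavelengths, X = _split(spectra)
    keep = (wavelengths >= low) & (wavelengths <= high)
    if not keep.any():
        raise ValueError(f"no grid points inside [{low}, {high}] nm")
    return _assemble(meta, wavelengths[keep], X[:, keep])


def second_derivative(
    spectra: pd.DataFrame,
    window_points: int = 9,
    poly_order: int = 2,
    low: float = WINDOW_LOW_NM,
    high: float = WINDOW_HIGH_NM,
) -> pd.DataFrame:
    """Savitzky-Golay second derivative, cropped to the modelling window.

    Parameters
    ----------
    spectra:
        Wide table as produced by :func:`orchardssc.synthetic.generate_spectra`.
    window_points:
        Odd filter length in grid points (default 9, i.e. 27 nm at 3 nm
        sampling).
    poly_order:
        Local polynomial order; must satisfy 2 <= poly_order < window_points.
    low, high:
        Crop bounds in nm (inclusive).

    Returns the same table layout with absorbance replaced by the smoothed
    second derivative (absorbance per nm^2), restricted to [low, high].
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2 for a second derivative")
    if window_points <= poly_order:
        raise ValueError("window_points must exceed poly_order")
    meta, wavelengths, X = _split(spectra)
    if window_points > wavelengths.size:
        raise ValueError("filter window larger than the spectrum")
    step = wavelengths[1] - wavelengths[0]
    d2 = savgol_filter(
        X, window_length=window_points, polyorder=poly_order, deriv=2, delta=step, axis=1
    )
    keep = (wavelengths >= low) & (wavelengths <= high)
    if not keep.any():
        raise ValueError(f"no grid points inside [{low}, {high}] nm")
    return _assemble(meta, wavelengths[keep], d2[:, keep])
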