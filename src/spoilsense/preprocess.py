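"""Spectral preprocessing: truncation, robust normal variate, sensor ratios.

The robust normal variate (RNV) transform is the robust cousin of the
standard normal variate: each spectrum is centred by its median and scaled
by its median absolute deviation (MAD),

    s_rnv = (s - median(s)) / mad(s),        mad(s) = median(|s - median(s)|)

which removes additive offsets and multiplicative scatter from a spectrum
without being dragged by strong bands the way mean/SD scaling is.  The
default scope is per spectrum (row-wise); ensemble-wide (``global``) and
per-wavenumber statistics are available as alternative modes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import FeatureTable, SpectralDataset

__all__ = [
    "mad",
    "RNVParams",
    "RNVScaler",
    "rnv_normalize",
    "truncate_spectra",
    "enose_response",
    "msi_features",
    "MSI_WAVELENGTHS",
]

#: VideometerLab acquisition bands, nm.
MSI_WAVELENGTHS = (
    405, 435, 450, 470, 505, 525, 570, 590, 630,
    645, 660, 700, 850, 870, 890, 910, 940, 970,
)

RNV_MODES = ("per_spectrum", "global", "per_wavenumber")


def mad(values) -> float:
    """Median absolute deviation: median(|x - median(x)|).

    A robust scale estimate: translation-invariant and absolutely
    homogeneous (mad(a*x + c) = |a|*mad(x)).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of empty input is undefined")
    return float(np.median(np.abs(x - np.median(x))))


@dataclass(frozen=True)
class RNVParams:
    mode: str = "per_spectrum"
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.mode not in RNV_MODES:
            raise ValueError(f"mode must be one of {RNV_MODES}, got {self.mode!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class RNVScaler(TransformerMixin, BaseEstimator):
    """Robust normal variate normalization as an sklearn transformer.

    Parameters
    ----------
    mode : {"per_spectrum", "global", "per_wavenumber"}
        Scope of the median/MAD statistics.  ``per_spectrum`` (default)
        is stateless: each row is normalized by its own statistics, which
        is the only mode that cancels per-sample multiplicative scatter.
    epsilon : float
        Smallest admissible MAD; anything at or below it marks a
        degenerate (near-constant) normalization unit and raises.
    """

    def __init__(self, mode: str = "per_spectrum", epsilon: float = 1e-12):
        self.mode = mode
        self.epsilon = epsilon

    def fit(self, X, y=None):
        params = RNVParams(self.mode, self.epsilon)  # validates
        X = check_array(X, dtype=float)
        if params.mode == "global":
            self.center_ = float(np.median(X))
            self.scale_ = mad(X.ravel())
            if self.scale_ <= self.epsilon:
                raise ValueError("global MAD is degenerate (constant data)")
        elif params.mode == "per_wavenumber":
            self.center_ = np.median(X, axis=0)
            self.scale_ = np.array(
                [mad(X[:, j]) for j in range(X.shape[1])]
            )
            if np.any(self.scale_ <= self.epsilon):
                bad = np.flatnonzero(self.scale_ <= self.epsilon)
                raise ValueError(f"degenerate MAD at columns {bad.tolist()}")
        else:
            self.center_ = None
            self.scale_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        if self.mode == "per_spectrum":
            centers = np.median(X, axis=1, keepdims=True)
            scales = np.median(np.abs(X - centers), axis=1, keepdims=True)
            if np.any(scales <= self.epsilon):
                bad = np.flatnonzero(scales.ravel() <= self.epsilon)
                raise ValueError(
                    f"constant spectrum (MAD <= epsilon) at rows {bad.tolist()}"
                )
            return (X - centers) / scales
        return (X - self.center_) / self.scale_


def rnv_normalize(ds: SpectralDataset | FeatureTable, params: RNVParams | None = None):
    """Apply RNV to a dataset, preserving metadata.

    Row-degenerate inputs raise an error naming the offending sample_id.
    """
    params = params or RNVParams()
    values = ds.absorbance if isinstance(ds, SpectralDataset) else ds.values
    scaler = RNVScaler(mode=params.mode, epsilon=params.epsilon).fit(values)
    try:
        out = scaler.transform(values)
    except ValueError as exc:
        # rewrite row indices as sample ids for per-spectrum failures
        if "constant spectrum" in str(exc):
            centers = np.median(values, axis=1, keepdims=True)
            scales = np.median(np.abs(values - centers), axis=1).ravel()
            bad = [ds.records[i].sample_id for i in np.flatnonzero(scales <= params.epsilon)]
            raise ValueError(f"constant spectrum (MAD <= epsilon) for samples {bad}") from None
        raise
    if isinstance(ds, SpectralDataset):
        return SpectralDataset(ds.wavenumbers.copy(), out, list(ds.records))
    return FeatureTable(list(ds.feature_names), out, list(ds.records))


def truncate_spectra(ds: SpectralDataset, low: float, high: float) -> SpectralDataset:
    """Keep wavenumbers in the half-open window [low, high).

    On a 1 cm^-1 grid the analysis window [900, 2700) retains exactly 1800
    variables.  The stored grid order (typically descending acquisition
    order) is preserved; selection is by value.
    """
    if not low < high:
        raise ValueError("low must be < high")
    mask = (ds.wavenumbers >= low) & (ds.wavenumbers < high)
    if not mask.any():
        raise ValueError("truncation removed all variables")
    return SpectralDataset(
        ds.wavenumbers[mask].copy(), ds.absorbance[:, mask].copy(), list(ds.records)
    )


def enose_response(R, R0):
    """Relative resistance change (R - R0) / R0 of a metal-oxide gas sensor."""
    R0 = np.asarray(R0, dtype=float)
    if np.any(R0 == 0):
        raise ValueError("baseline resistance R0 must be non-zero")
    out = (np.asarray(R, dtype=float) - R0) / R0
    return float(out) if out.ndim == 0 else out


def msi_features(pixel_spectra, wavelengths=MSI_WAVELENGTHS):
    """Collapse an ROI's pixelwise spectra to per-band mean and sample SD.

    Parameters
    ----------
    pixel_spectra : array (n_pixels, 18)
        Reflectance of every ROI pixel at the 18 acquisition bands.

    Returns
    -------
    values : array (36,)
        Band means followed by band SDs (ddof=1).
    names : list of str
        ``mean_<nm>`` then ``sd_<nm>``.
    """
    X = np.asarray(pixel_spectra, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(wavelengths):
        raise ValueError(f"expected n_pixels x {len(wavelengths)} matrix, got {X.shape}")
    if X.shape[0] < 2:
        raise ValueError("at least 2 pixels required for a sample SD")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    names = [f"mean_{w}" for w in wavelengths] + [f"sd_{w}" for w in wavelengths]
    return np.concatenate([means, sds]), names
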