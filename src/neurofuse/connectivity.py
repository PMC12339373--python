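"""Functional-connectivity construction for fMRI-like and EEG-like ROI signals.

Two connectivity measures are provided:

* Pearson correlation between ROI time series (the standard resting-state
  fMRI functional-connectivity measure).
* Power-envelope connectivity (PEC) for band-limited EEG source signals:
  each pair of analytic signals is orthogonalized to remove the
  instantaneous zero-phase-lag component (the volume-conduction artifact),
  the squared magnitudes are log-transformed, and the Pearson correlation
  between log power envelopes is taken.

Both measures are passed through the same normalization chain: Fisher
r-to-z (atanh) on the off-diagonal entries, zero diagonal, then z-scoring
of the upper-triangle edge values within subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "BandSpec",
    "CANONICAL_BANDS",
    "compute_fmri_fc",
    "normalize_connectivity",
    "bandpass",
    "analytic_signal",
    "orthogonalize_pair",
    "compute_pec",
    "upper_triangle",
    "edges_to_matrix",
]

_ENV_EPS = 1e-12


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [low_hz, high_hz] in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band {self.name}: [{self.low_hz}, {self.high_hz}]")


#: Canonical EEG frequency bands (Hz).
CANONICAL_BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 31.0, 50.0),
}


@dataclass
class RoiTimeSeries:
    """One subject's T×N regional time series for one modality.

    Rows are time points, columns are ROIs. ``sampling_rate`` (Hz) is
    required for EEG. ``band`` is set after band-pass filtering.
    """

    subject_id: str
    modality: str  # "fmri" | "eeg"
    data: np.ndarray
    sampling_rate: float | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.modality not in ("fmri", "eeg"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be a T×N matrix")
        t, n = self.data.shape
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 ROIs, got {n}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in time series")
        if self.modality == "eeg":
            if self.sampling_rate is None or self.sampling_rate <= 0:
                raise ValueError("eeg time series requires sampling_rate > 0")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N×N connectivity with a record of applied normalizations.

    ``normalization_state`` is the ordered list of transforms applied so
    far, drawn from {"raw_corr", "fisher_z", "zscore"}.
    """

    subject_id: str
    modality: str
    values: np.ndarray
    normalization_state: list[str] = field(default_factory=lambda: ["raw_corr"])
    band: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite connectivity values")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix is not symmetric")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def is_normalized(self) -> bool:
        return self.normalization_state == ["raw_corr", "fisher_z", "zscore"]


def upper_triangle(m: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle in row-major order."""
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return m[iu]


def edges_to_matrix(edges: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`upper_triangle`: rebuild a symmetric matrix."""
    m = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return m


def compute_fmri_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation functional connectivity between all ROI pairs."""
    if ts.modality != "fmri":
        raise ValueError(f"expected fmri time series, got {ts.modality}")
    sd = ts.data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance ROI column(s) at index {bad.tolist()}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(ts.subject_id, "fmri", r, ["raw_corr"])


def normalize_connectivity(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z, zero diagonal, then within-subject edge z-scoring.

    atanh is applied to off-diagonal entries first (values at ±1 are
    clipped to ±(1−1e−7) with a warning), the diagonal is set to 0, and
    the N(N−1)/2 upper-triangle edges are then standardized to mean 0,
    sd 1 and mirrored back.
    """
    if c.normalization_state != ["raw_corr"]:
        raise ValueError(f"expected raw_corr state, got {c.normalization_state}")
    v = c.values.copy()
    n = v.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(v[off]) >= 1.0):
        warnings.warn("|r| == 1 off-diagonal entries clipped before atanh", stacklevel=2)
        v[off] = np.clip(v[off], -1 + 1e-7, 1 - 1e-7)
    z = np.zeros_like(v)
    z[off] = np.arctanh(v[off])
    edges = upper_triangle(z)
    mu, sd = edges.mean(), edges.std()
    if sd == 0:
        raise ValueError("all edges identical; cannot z-score")
    out = edges_to_matrix((edges - mu) / sd, n)
    return ConnectivityMatrix(
        c.subject_id, c.modality, out, ["raw_corr", "fisher_z", "zscore"], c.band
    )


def _band_sos(band: BandSpec, fs: float, order: int = 4):
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band edge {band.high_hz} Hz at or above Nyquist ({nyq} Hz)"
        )
    return butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(ts: RoiTimeSeries, band: BandSpec) -> RoiTimeSeries:
    """Zero-phase (forward-backward) band-pass filter of each ROI column."""
    if ts.modality != "eeg":
        raise ValueError("bandpass expects eeg time series")
    sos = _band_sos(band, ts.sampling_rate)
    filtered = sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=np.ascontiguousarray(filtered), band=band.name)


def analytic_signal(ts: RoiTimeSeries) -> np.ndarray:
    """Per-column analytic signal (signal + i·Hilbert transform)."""
    return hilbert(ts.data, axis=0)


def orthogonalize_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove from ``y`` the instantaneous zero-lag contribution of ``x``.

    For analytic signals x(t), y(t) the orthogonalized signal is
    ``imag(y · conj(x) / |x|) · i · x/|x|``: the component of y in phase
    quadrature to x, recombined with x's instantaneous phase. Its
    envelope fluctuations carry no zero-lag shared signal with x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mag = np.abs(x)
    if np.all(mag == 0):
        raise ValueError("x is identically zero")
    if np.any(mag == 0):
        warnings.warn("zero-magnitude samples in x; using epsilon", stacklevel=2)
        mag = np.where(mag == 0, _ENV_EPS, mag)
    quad = np.imag(y * np.conj(x) / mag)
    return quad * 1j * x / mag


def _log_envelope(z: np.ndarray) -> np.ndarray:
    return np.log(_ENV_EPS + np.abs(z) ** 2)


def compute_pec(
    ts: RoiTimeSeries,
    band: BandSpec,
    *,
    prefiltered: bool = False,
    normalize: bool = True,
) -> ConnectivityMatrix:
    """Power-envelope connectivity of band-limited EEG ROI signals.

    For each ordered ROI pair (i, j): band-pass, analytic signal,
    orthogonalize j with respect to i, square the magnitude, log, and
    correlate the log envelope of j⊥i with the log envelope of i. The
    two directed values are averaged into a symmetric PEC(i, j). With
    ``normalize=True`` the matrix then goes through the same
    Fisher-z + z-score chain as the fMRI connectivity.
    """
    if ts.modality != "eeg":
        raise ValueError("compute_pec expects eeg time series")
    filtered = ts if prefiltered else bandpass(ts, band)
    za = analytic_signal(filtered)
    n = za.shape[1]
    log_env = _log_envelope(za)  # plain (non-orthogonalized) log envelopes
    env_sd = log_env.std(axis=0)

    pec = np.zeros((n, n))
    for i in range(n):
        if env_sd[i] < 1e-10:
            raise ValueError(f"constant power envelope for ROI {i}")
        for j in range(n):
            if i == j:
                continue
            ortho = orthogonalize_pair(za[:, i], za[:, j])
            le = _log_envelope(ortho)
            if le.std() < 1e-8:
                # orthogonalization removed j entirely (shared zero-lag signal)
                pec[i, j] = 0.0
            else:
                pec[i, j] = np.corrcoef(le, log_env[:, i])[0, 1]
    sym = (pec + pec.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    raw = ConnectivityMatrix(ts.subject_id, "eeg", sym, ["raw_corr"], band.name)
    if not normalize:
        return raw
    return normalize_connectivity(raw)
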