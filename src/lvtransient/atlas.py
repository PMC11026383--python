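"""Unsupervised PCA atlas of min-max-normalized volume transients.

Each patient's transient is resampled onto a fixed cycle-fraction grid
and min-max normalized, removing ventricle size and stroke volume;
principal component analysis of the normalized curves yields an atlas:
the population mean curve plus orthonormal "contraction modes" of
variation. A patient's coordinates along the retained modes (those
reconstructing 95% of population variance by default) are continuous,
per-patient biomarkers of contraction dynamics.

The PCA is a deterministic covariance eigendecomposition (via SVD of
the centered data matrix); mode signs follow a fixed convention (the
largest-magnitude loading is made positive) so repeated fits on the
same cohort are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volumes import VolumeTransient, periodic_spline

GRID_POINTS_DEFAULT = 100
VARIANCE_THRESHOLD_DEFAULT = 0.95


class DegenerateInputError(ValueError):
    """Raised for flat transients that cannot be min-max normalized."""


class DimensionError(ValueError):
    """Raised on grid/mode dimension mismatches."""


@dataclass
class NormalizedTransient:
    """Unitless curve on a uniform cycle-fraction grid, min 0 / max 1."""

    values: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def normalize_transient(t: VolumeTransient,
                        grid_points: int = GRID_POINTS_DEFAULT) -> NormalizedTransient:
    """Resample onto ``grid_points`` uniform cycle fractions and min-max map.

    Values become (V - Vmin) / (Vmax - Vmin); the time axis becomes
    cycle fraction u in [0, 1), removing RR-interval length. Raises
    DegenerateInputError when Vmax = Vmin.
    """
    spline = periodic_spline(t)
    u = np.arange(grid_points) / grid_points
    v = spline(u * t.rr_ms)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin < 1e-12 * max(abs(vmax), 1.0):
        raise DegenerateInputError("flat transient cannot be normalized")
    return NormalizedTransient((v - vmin) / (vmax - vmin), t.patient_id)


@dataclass
class ModeWeights:
    patient_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class TransientAtlas:
    """Mean curve + orthonormal PCA modes of a normalized-transient cohort."""

    mean_curve: np.ndarray
    modes: np.ndarray            # (m, G), orthonormal rows
    eigenvalues: np.ndarray      # variance along each retained mode
    variance_fractions: np.ndarray
    cumulative_variance: np.ndarray
    grid_points: int
    n_subjects: int
    variance_threshold: float
    total_variance: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    def to_json(self, path=None) -> str:
        doc = {
            "mean_curve": self.mean_curve.tolist(),
            "modes": self.modes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "cumulative_variance": self.cumulative_variance.tolist(),
            "grid_points": self.grid_points,
            "n_subjects": self.n_subjects,
            "variance_threshold": self.variance_threshold,
            "total_variance": self.total_variance,
            "metadata": self.metadata,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TransientAtlas":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            mean_curve=np.asarray(doc["mean_curve"]),
            modes=np.asarray(doc["modes"]).reshape(-1, doc["grid_points"]),
            eigenvalues=np.asarray(doc["eigenvalues"]),
            variance_fractions=np.asarray(doc["variance_fractions"]),
            cumulative_variance=np.asarray(doc["cumulative_variance"]),
            grid_points=doc["grid_points"],
            n_subjects=doc["n_subjects"],
            variance_threshold=doc["variance_threshold"],
            total_variance=doc["total_variance"],
            metadata=doc.get("metadata", {}),
        )


def fit_atlas(cohort: list[NormalizedTransient],
              variance_threshold: float = VARIANCE_THRESHOLD_DEFAULT,
              metadata: dict | None = None) -> TransientAtlas:
    """Mean-centered PCA of normalized curves.

    Retains the smallest number of modes whose cumulative variance
    fraction reaches ``variance_threshold``. An identical-curve cohort
    yields a valid atlas with zero modes. Mode signs are fixed by making
    each mode's largest-magnitude loading positive.
    """
    if len(cohort) < 2:
        raise ValueError("atlas needs at least 2 subjects")
    if np.unique([c.values.size for c in cohort]).size != 1:
        raise DimensionError("all curves must share the grid")
    X = np.vstack([c.values for c in cohort])
    n, g = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc ** 2).sum() / (n - 1))

    if total_var < 1e-24:
        empty = np.empty((0, g))
        return TransientAtlas(mean, empty, np.empty(0), np.empty(0),
                              np.empty(0), g, n, variance_threshold, 0.0,
                              metadata or {})

    # deterministic SVD of the centered data matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    keep_nonzero = eigvals > 1e-12 * eigvals[0]
    eigvals, vt = eigvals[keep_nonzero], vt[keep_nonzero]
    fractions = eigvals / total_var
    cumulative = np.cumsum(fractions)
    m = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    m = min(m, eigvals.size)

    modes = vt[:m].copy()
    for k in range(m):
        j = int(np.argmax(np.abs(modes[k])))
        if modes[k, j] < 0:
            modes[k] *= -1.0
    return TransientAtlas(
        mean_curve=mean, modes=modes, eigenvalues=eigvals[:m],
        variance_fractions=fractions[:m], cumulative_variance=cumulative[:m],
        grid_points=g, n_subjects=n, variance_threshold=variance_threshold,
        total_variance=total_var, metadata=metadata or {},
    )


def project(atlas: TransientAtlas, nt: NormalizedTransient) -> ModeWeights:
    """Mode weights: inner products of (curve - mean) with each mode."""
    if nt.values.size != atlas.grid_points:
        raise DimensionError("curve not on the atlas grid")
    w = atlas.modes @ (nt.values - atlas.mean_curve)
    return ModeWeights(nt.patient_id, w)


def reconstruct(atlas: TransientAtlas, w: ModeWeights) -> NormalizedTransient:
    """mean_curve + sum_k w_k * mode_k (first len(w) modes).

    Values are not clipped; extreme weights may leave [0, 1].
    """
    ww = np.asarray(w.weights, dtype=float)
    if ww.size > atlas.n_modes:
        raise DimensionError("more weights than retained modes")
    values = atlas.mean_curve + ww @ atlas.modes[:ww.size]
    return NormalizedTransient(values, w.patient_id)


def project_cohort(atlas: TransientAtlas,
                   cohort: list[NormalizedTransient]) -> "pd.DataFrame":
    """Weights of a cohort as a DataFrame with vt_ai_k columns."""
    import pandas as pd

    rows = []
    for nt in cohort:
        w = project(atlas, nt)
        rows.append({"patient_id": nt.patient_id,
                     **{f"vt_ai_{k + 1}": w.weights[k]
                        for k in range(atlas.n_modes)}})
    return pd.DataFrame(rows)


def mode_extreme_traces(atlas: TransientAtlas, cohort_weights: np.ndarray,
                        mode_index: int, lo_pct: float = 10.0,
                        hi_pct: float = 90.0):
    """Percentile traces of one mode for interpretation plots.

    cohort_weights are the cohort's weights along ``mode_index``
    (0-based); returns (lo_trace, hi_trace) = mean + q_pct * mode.
    """
    w = np.asarray(cohort_weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if not 0 <= mode_index < atlas.n_modes:
        raise DimensionError("mode index out of range")
    lo_q, hi_q = np.percentile(w, [lo_pct, hi_pct])
    mode = atlas.modes[mode_index]
    return (NormalizedTransient(atlas.mean_curve + lo_q * mode, f"p{lo_pct:g}"),
            NormalizedTransient(atlas.mean_curve + hi_q * mode, f"p{hi_pct:g}"))
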