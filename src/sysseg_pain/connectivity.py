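"""Functional connectivity, motion QC, and system segregation.

From parcellated BOLD time series and rigid-body motion traces this module
produces: framewise displacement (FD) summaries with the high-motion exclusion
rule, nuisance-cleaned node series (motion + derivatives, low-frequency cosine
drift, optional tissue regressors), Fisher-z connectivity matrices, and the
per-network system-segregation profile

    SyS_net = (W_net - B_net) / W_net

where W_net is the mean Fisher-z connectivity over node pairs inside the
network and B_net the mean over pairs connecting the network to the rest of
the cortex. Negative correlations are truncated to zero before averaging and
self-connections are excluded, so 0 <= W, B and SyS <= 1 whenever W > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import PartitionAtlas

#: Head-radius constant (mm) converting rotation differences to arc length.
POWER_SPHERE_RADIUS_MM = 50.0

#: Clip correlations at +/-(1 - _R_CLIP_EPS) before the arctanh transform.
_R_CLIP_EPS = 1e-7


@dataclass
class RoiTimeSeries:
    """T x N parcel time-series matrix with its repetition time."""

    values: np.ndarray
    tr_seconds: float = 0.8
    node_labels: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x N matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing or non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        t, n = self.values.shape
        if t <= n / 2:
            warnings.warn(
                f"only {t} volumes for {n} nodes; connectivity estimates may be unstable",
                stacklevel=2,
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters: T x 3 rotations (rad), T x 3 translations (mm)."""

    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self):
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        for name, arr in (("rotations", self.rotations), ("translations", self.translations)):
            if arr.shape[1] != 3:
                raise ValueError(f"{name} must have 3 columns, got {arr.shape[1]}")
        if self.rotations.shape[0] != self.translations.shape[0]:
            raise ValueError("rotations and translations must cover the same volumes")

    @property
    def n_volumes(self) -> int:
        return self.rotations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """T x 6 matrix in MCFLIRT column order (rotations first)."""
        return np.hstack([self.rotations, self.translations])


@dataclass
class MotionSummary:
    """Per-subject framewise-displacement summary and exclusion flag."""

    fd_series: np.ndarray
    fd_mean: float
    prop_above_threshold: float
    fd_threshold_mm: float
    excluded: bool = False


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative Fisher-z connectivity with a zero diagonal."""

    z_values: np.ndarray
    node_labels: tuple | None = None

    def __post_init__(self):
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z_values must be symmetric")
        if (z < 0).any():
            raise ValueError("z_values must be nonnegative (negatives are truncated upstream)")
        if np.diagonal(z).any():
            raise ValueError("diagonal must be zero (self-connections excluded)")
        self.z_values = z

    @property
    def n_nodes(self) -> int:
        return self.z_values.shape[0]


@dataclass
class SegregationProfile:
    """Per-network (W, B, SyS) triplets for one subject."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"network", "w_net", "b_net", "sys"}
        if not required <= set(self.table.columns):
            raise ValueError(f"profile table needs columns {sorted(required)}")

    def sys_of(self, network: str) -> float:
        row = self.table.loc[self.table["network"] == network]
        if row.empty:
            raise KeyError(f"unknown network {network!r}")
        return float(row["sys"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------

def framewise_displacement(
    trace: MotionTrace,
    sphere_radius_mm: float = POWER_SPHERE_RADIUS_MM,
    fd_threshold_mm: float = 0.5,
) -> MotionSummary:
    """Framewise displacement per volume transition.

    FD_t = sum |Delta translation_axis| + radius * sum |Delta rotation_axis|,
    i.e. absolute backward differences of the three translations (mm) plus the
    three rotation differences (radians) converted to displacement on the
    surface of a sphere of ``sphere_radius_mm``.
    """
    if trace.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute framewise displacement")
    d_trans = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    fd = d_trans + sphere_radius_mm * d_rot
    prop = float(np.mean(fd > fd_threshold_mm))
    return MotionSummary(
        fd_series=fd,
        fd_mean=float(fd.mean()),
        prop_above_threshold=prop,
        fd_threshold_mm=fd_threshold_mm,
    )


def exclude_high_motion(
    summary: MotionSummary,
    fd_threshold_mm: float = 0.5,
    prop_threshold: float = 0.5,
) -> bool:
    """Exclusion rule: drop the subject iff at least ``prop_threshold`` of the
    frame transitions exceed ``fd_threshold_mm`` of displacement."""
    if not np.isclose(fd_threshold_mm, summary.fd_threshold_mm):
        prop = float(np.mean(summary.fd_series > fd_threshold_mm))
    else:
        prop = summary.prop_above_threshold
    return prop >= prop_threshold


# ---------------------------------------------------------------------------
# Nuisance model
# ---------------------------------------------------------------------------

def dct_drift_basis(n_volumes: int, tr_seconds: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Discrete-cosine drift regressors spanning frequencies below ``cutoff_hz``.

    The k-th column (k = 1..K) is cos(pi * (2t+1) * k / (2T)), the DCT-II basis
    vector at frequency k / (2 * T * TR) Hz; K = floor(2 * T * TR * cutoff).
    The constant term is excluded (an intercept is added by the regression).
    Columns are mutually orthogonal.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    k_max = int(np.floor(2.0 * n_volumes * tr_seconds * cutoff_hz))
    t = np.arange(n_volumes)
    k = np.arange(1, k_max + 1)
    if k_max == 0:
        return np.empty((n_volumes, 0))
    return np.cos(np.pi * np.outer(2 * t + 1, k) / (2.0 * n_volumes))


def motion_regressors(trace: MotionTrace) -> np.ndarray:
    """Six realignment parameters plus their temporal derivatives (T x 12).

    Derivatives are backward differences with a zero-padded first row.
    """
    params = trace.as_matrix()
    deriv = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    return np.hstack([params, deriv])


def nuisance_regress(ts: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Residualize every node series against [intercept | confounds].

    Collinear confound columns are dropped (with a warning) so the projection
    is well defined; residuals are orthogonal to every retained confound.
    """
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.size and confounds.shape[0] != ts.n_volumes:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows but the series has {ts.n_volumes} volumes"
        )
    design = np.hstack([np.ones((ts.n_volumes, 1)), confounds]) if confounds.size else np.ones(
        (ts.n_volumes, 1)
    )
    q, r, piv = _qr_drop_collinear(design)
    if q.shape[1] < design.shape[1]:
        warnings.warn(
            f"dropped {design.shape[1] - q.shape[1]} collinear confound column(s)",
            stacklevel=2,
        )
    resid = ts.values - q @ (q.T @ ts.values)
    return RoiTimeSeries(resid, tr_seconds=ts.tr_seconds, node_labels=ts.node_labels)


def _qr_drop_collinear(design: np.ndarray, rcond: float = 1e-10):
    """Pivoted-QR column selection: orthonormal basis of the full-rank subset."""
    from scipy.linalg import qr

    q, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diagonal(r))
    tol = diag[0] * rcond if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return q[:, :rank], r[:rank], piv[:rank]


# ---------------------------------------------------------------------------
# Connectivity and segregation
# ---------------------------------------------------------------------------

def compute_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson node-by-node correlations, Fisher-z transformed.

    Correlations are clipped to +/-(1 - 1e-7) before arctanh to avoid
    infinities; negative values are set to zero and the diagonal
    (self-correlation) is set to zero.
    """
    values = ts.values
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = (
            [ts.node_labels[i] for i in dead] if ts.node_labels is not None else dead.tolist()
        )
        raise ValueError(f"zero-variance node series: {labels}")
    r = np.corrcoef(values, rowvar=False)
    r = np.clip(r, -1 + _R_CLIP_EPS, 1 - _R_CLIP_EPS)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against round-off
    return ConnectivityMatrix(z, node_labels=ts.node_labels)


def compute_segregation(fc: ConnectivityMatrix, atlas: PartitionAtlas) -> SegregationProfile:
    """Per-network within/between means and the segregation ratio.

    W_net averages z over unordered node pairs inside the network; B_net over
    all (node-in-network, node-outside-network) pairs. Pairs whose correlation
    was truncated to zero still count in the denominators. Networks with
    W_net = 0 get SyS = NaN and an ``undefined`` flag rather than a silent 0.
    """
    if fc.n_nodes != atlas.n_nodes:
        raise ValueError(
            f"connectivity has {fc.n_nodes} nodes but the partition defines {atlas.n_nodes}"
        )
    z = fc.z_values
    rows = []
    for net in atlas.network_names:
        inside = atlas.nodes_of(net)
        outside = np.setdiff1d(np.arange(atlas.n_nodes), inside)
        block = z[np.ix_(inside, inside)]
        iu = np.triu_indices(len(inside), k=1)
        w = float(block[iu].mean())
        b = float(z[np.ix_(inside, outside)].mean())
        if w > 0:
            sys_val, undefined = (w - b) / w, False
        else:
            sys_val, undefined = np.nan, True
        rows.append(
            {"network": net, "w_net": w, "b_net": b, "sys": sys_val, "undefined": undefined}
        )
    return SegregationProfile(pd.DataFrame(rows))
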