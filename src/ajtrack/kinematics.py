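"""Trajectory smoothing and tissue-scale strain-rate estimation.

Raw tracked centroids are noisy because tracking only establishes identity,
never corrects positions.  A constant-velocity linear-Gaussian state-space
model is assumed for each cell: the state ``h_t = (x, y, xdot, ydot)``
evolves as ``h_{t+1} ~ N(A h_t, Sigma_H)`` and the 2D observation (the z
coordinate is dropped: the tissues analysed are nearly planar) as
``o_t ~ N(B h_t, Sigma_O)`` with

    A = [[1, 0, 1, 0],          B = [[1, 0, 0, 0],
         [0, 1, 0, 1],               [0, 1, 0, 0]]
         [0, 0, 1, 0],
         [0, 0, 0, 1]]

(unit time step of one frame interval).  The maximum-a-posteriori state
sequence of this model — what a Viterbi decoding of the continuous-state
chain returns — coincides with the Rauch-Tung-Striebel smoother mean, which
is how it is computed here.

Tissue kinematics are summarised per frame by the strain-rate tensor: the
velocity of cell ``i`` is modelled as the affine field ``pdot_i = J p_i +
pdot_0`` fitted by ordinary least squares over cells.  ``J`` splits into a
symmetric part ``E`` (trace = areal expansion rate) and an antisymmetric
part ``Omega`` (rigid rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KalmanModel",
    "StrainRate",
    "viterbi_smooth",
    "fit_strain_rate",
    "decompose_strain",
]

A_MATRIX = np.array(
    [[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]]
)
B_MATRIX = np.array([[1.0, 0, 0, 0], [0, 1, 0, 0]])


@dataclass
class KalmanModel:
    """Constant-velocity linear-Gaussian model for centroid trajectories.

    Covariances are in um^2 (positions) and (um/frame)^2 (velocities).  The
    defaults assume ~0.1 um centroid localisation noise (sub-voxel, as
    polygon centroids average many vertices) and allow modest frame-to-frame
    velocity changes so that spatially varying flows are not over-smoothed.
    """

    sigma_obs: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(2))
    sigma_state: np.ndarray = field(
        default_factory=lambda: np.diag([1e-4, 1e-4, 0.05, 0.05])
    )
    initial_cov: np.ndarray = field(default_factory=lambda: np.diag([1.0, 1.0, 1.0, 1.0]))

    def __post_init__(self) -> None:
        for name in ("sigma_obs", "sigma_state", "initial_cov"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            if not np.allclose(m, m.T) or np.any(np.linalg.eigvalsh(m) <= 0):
                raise ValueError(f"{name} must be symmetric positive definite")


def viterbi_smooth(observations: np.ndarray, model: KalmanModel | None = None) -> np.ndarray:
    """MAP state sequence of the constant-velocity model (RTS smoother).

    Parameters
    ----------
    observations:
        ``(T, 2)`` array of observed (x, y) centroid positions, T >= 2.

    Returns
    -------
    ``(T, 4)`` array of smoothed states ``(x, y, xdot, ydot)``.  For a
    linear-Gaussian chain the most probable state sequence equals the
    sequence of smoothed means, so this is exactly what a Viterbi decoding
    of the model would return.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be (T, 2)")
    t_len = obs.shape[0]
    if t_len < 2:
        raise ValueError("need at least 2 observations")
    model = model or KalmanModel()
    a, b = A_MATRIX, B_MATRIX
    q, r = model.sigma_state, model.sigma_obs

    mu0 = np.array([obs[0, 0], obs[0, 1], obs[1, 0] - obs[0, 0], obs[1, 1] - obs[0, 1]])
    p0 = model.initial_cov

    means = np.zeros((t_len, 4))
    covs = np.zeros((t_len, 4, 4))
    pred_means = np.zeros((t_len, 4))
    pred_covs = np.zeros((t_len, 4, 4))

    # forward (Kalman filter)
    m_pred, p_pred = mu0, p0
    for t in range(t_len):
        pred_means[t], pred_covs[t] = m_pred, p_pred
        s = b @ p_pred @ b.T + r
        k = p_pred @ b.T @ np.linalg.solve(s, np.eye(2))
        means[t] = m_pred + k @ (obs[t] - b @ m_pred)
        covs[t] = (np.eye(4) - k @ b) @ p_pred
        if t < t_len - 1:
            m_pred = a @ means[t]
            p_pred = a @ covs[t] @ a.T + q

    # backward (RTS smoother)
    smoothed = np.zeros_like(means)
    smoothed[-1] = means[-1]
    cov_s = covs[-1]
    for t in range(t_len - 2, -1, -1):
        g = covs[t] @ a.T @ np.linalg.solve(pred_covs[t + 1], np.eye(4))
        smoothed[t] = means[t] + g @ (smoothed[t + 1] - pred_means[t + 1])
        cov_s = covs[t] + g @ (cov_s - pred_covs[t + 1]) @ g.T
    return smoothed


@dataclass
class StrainRate:
    """Per-frame affine velocity-field fit and its decomposition.

    ``jacobian`` is the 2x2 strain-rate tensor ``J`` (units 1/frame),
    ``intercept`` the mean-drift velocity ``pdot_0`` (um/frame).
    ``expansion = trace(E)`` is the areal expansion rate.  Two rotation
    readouts are reported: ``rotation_acos = acos(Omega_12)``, the literal
    convention, and ``rotation_angle = asin(-Omega_12)``, the frame-to-frame
    rigid rotation angle in radians (positive counter-clockwise); the latter
    is the dimensionally standard rate.  ``rotation_acos`` is NaN when
    ``|Omega_12| > 1``.
    """

    jacobian: np.ndarray
    intercept: np.ndarray
    symmetric: np.ndarray
    antisymmetric: np.ndarray
    expansion: float
    rotation_acos: float
    rotation_angle: float


def fit_strain_rate(positions: np.ndarray, velocities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of ``pdot = J p + pdot_0`` over cells at one frame.

    ``positions`` and ``velocities`` are ``(n, 2)`` with n >= 3 non-collinear
    cells.  Each velocity component is regressed on (x, y, 1).
    Returns ``(J, pdot_0)``.
    """
    p = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if p.shape != v.shape or p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("positions and velocities must both be (n, 2)")
    if p.shape[0] < 3:
        raise ValueError("need >= 3 cells to fit a strain rate")
    design = np.column_stack([p, np.ones(p.shape[0])])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("cell positions are collinear; strain rate undefined")
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    j = coef[:2].T  # rows: velocity component; cols: d/dx, d/dy
    p0 = coef[2]
    return j, p0


def decompose_strain(jacobian: np.ndarray, intercept: np.ndarray | None = None) -> StrainRate:
    """Split ``J`` into symmetric strain and antisymmetric rotation parts."""
    j = np.asarray(jacobian, dtype=float)
    if j.shape != (2, 2) or not np.all(np.isfinite(j)):
        raise ValueError("jacobian must be a finite 2x2 matrix")
    sym = 0.5 * (j + j.T)
    antisym = 0.5 * (j - j.T)
    omega12 = float(antisym[0, 1])
    rotation_acos = float(np.arccos(omega12)) if abs(omega12) <= 1 else float("nan")
    rotation_angle = float(np.arcsin(np.clip(-omega12, -1.0, 1.0)))
    return StrainRate(
        jacobian=j,
        intercept=np.zeros(2) if intercept is None else np.asarray(intercept, dtype=float),
        symmetric=sym,
        antisymmetric=antisym,
        expansion=float(np.trace(sym)),
        rotation_acos=rotation_acos,
        rotation_angle=rotation_angle,
    )
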