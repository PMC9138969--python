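"""Analytic three-shell spherical forward model and the eLORETA inverse.

The forward model solves the quasi-static potential of a current dipole
inside three concentric spherical shells (brain, skull, scalp) by a
truncated Legendre series: per harmonic degree the radial coefficients in
each shell are obtained from the interface continuity conditions (potential
and radial current) plus the insulating boundary at the scalp.  The inverse
is the eLORETA weighted minimum-norm operator, whose defining property is
exact localization of single point sources in the noiseless case.

All geometry lives in a sphere-centred head frame in millimetres; dipole
moments are in nA*m and potentials in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import SensorRecording
from .rois import NetworkTable

#: Default shell radii (mm) and conductivities (S/m): brain, skull, scalp.
DEFAULT_RADII = (80.0, 85.0, 92.0)
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)


@dataclass
class LeadfieldModel:
    """Sensors x (n_grid * 3) gain matrix on a regular source grid.

    ``gain[:, 3*j:3*j+3]`` maps the (x, y, z) dipole moment at grid node j
    (nA*m) to average-referenced sensor potentials (microvolts).
    """

    gain: np.ndarray
    grid: np.ndarray  # (n_grid, 3) node coordinates, mm
    spacing: float
    radii: tuple[float, float, float]
    conductivities: tuple[float, float, float]
    sensor_positions: np.ndarray

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_grid(self) -> int:
        return self.grid.shape[0]

    def gain_at(self, node: int) -> np.ndarray:
        """(n_sensors, 3) gain block of one node."""
        return self.gain[:, 3 * node: 3 * node + 3]

    def nearest_node(self, point: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(self.grid - point, axis=1)))


@dataclass
class InverseOperator:
    """eLORETA transfer matrix with per-node weights and diagnostics."""

    transfer: np.ndarray        # (n_grid * 3, n_sensors)
    weights: np.ndarray         # (n_grid, 3, 3) symmetric positive-definite
    alpha: float
    iterations: int
    final_change: float
    converged: bool


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def make_source_grid(
    spacing: float = 6.0,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    margin: float = 6.0,
    include_points: np.ndarray | None = None,
) -> np.ndarray:
    """Regular grid (mm) strictly inside the brain shell by ``margin``.

    ``include_points`` (e.g. ROI centres, head frame) are appended as extra
    nodes so spherical ROIs are guaranteed an exactly-placed member node.
    """
    rmax = radii[0] - margin
    ax = np.arange(-rmax, rmax + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]
    if include_points is not None:
        extra = np.atleast_2d(np.asarray(include_points, float))
        if np.any(np.linalg.norm(extra, axis=1) > rmax):
            raise ValueError("requested extra grid nodes fall outside the brain shell")
        pts = np.vstack([pts, extra])
    return pts


def fit_sensors_to_scalp(positions: np.ndarray, radius: float) -> np.ndarray:
    """Project sensor positions radially onto the scalp sphere."""
    positions = np.asarray(positions, float)
    norms = np.linalg.norm(positions, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("sensor at the head origin cannot be projected")
    return positions / norms * radius


def _legendre_terms(x: np.ndarray, nmax: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) = sqrt(1-x^2) P_n'(x), n = 0..nmax, vectorized."""
    P = np.zeros((nmax + 1,) + x.shape)
    dP = np.zeros_like(P)
    P[0] = 1.0
    if nmax >= 1:
        P[1] = x
        dP[1] = 1.0
    for n in range(1, nmax):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P, np.sqrt(np.clip(1.0 - x * x, 0.0, None)) * dP


def _radial_responses(
    n_terms: int,
    radii_scaled: tuple[float, float, float],
    sigma: tuple[float, float, float],
) -> np.ndarray:
    """Scalp-surface response per degree n for a unit r^-(n+1) source term.

    Shell coefficients (A1; A2, B2; A3, B3) follow from potential/current
    continuity at the brain-skull and skull-scalp interfaces and zero radial
    current at the scalp surface.  Radii are pre-scaled by the scalp radius
    so powers r^n stay well conditioned for n up to a few hundred.
    """
    R1, R2, R3 = radii_scaled
    s1, s2, s3 = sigma
    ns = np.arange(1, n_terms + 1, dtype=float)
    A = np.zeros((n_terms, 5, 5))
    rhs = np.zeros((n_terms, 5))
    A[:, 0, 0] = R1**ns
    A[:, 0, 1] = -(R1**ns)
    A[:, 0, 2] = -(R1 ** -(ns + 1))
    rhs[:, 0] = -(R1 ** -(ns + 1))
    A[:, 1, 0] = s1 * ns * R1 ** (ns - 1)
    A[:, 1, 1] = -s2 * ns * R1 ** (ns - 1)
    A[:, 1, 2] = s2 * (ns + 1) * R1 ** -(ns + 2)
    rhs[:, 1] = s1 * (ns + 1) * R1 ** -(ns + 2)
    A[:, 2, 1] = R2**ns
    A[:, 2, 2] = R2 ** -(ns + 1)
    A[:, 2, 3] = -(R2**ns)
    A[:, 2, 4] = -(R2 ** -(ns + 1))
    A[:, 3, 1] = s2 * ns * R2 ** (ns - 1)
    A[:, 3, 2] = -s2 * (ns + 1) * R2 ** -(ns + 2)
    A[:, 3, 3] = -s3 * ns * R2 ** (ns - 1)
    A[:, 3, 4] = s3 * (ns + 1) * R2 ** -(ns + 2)
    A[:, 4, 3] = ns * R3 ** (ns - 1)
    A[:, 4, 4] = -(ns + 1) * R3 ** -(ns + 2)
    x = np.linalg.solve(A, rhs[..., None])[..., 0]
    return x[:, 3] * R3**ns + x[:, 4] * R3 ** -(ns + 1)


def dipole_potentials(
    dipole_pos: np.ndarray,
    sensor_positions: np.ndarray,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    n_terms: int = 60,
) -> np.ndarray:
    """(n_sensors, 3) potentials of unit x/y/z dipoles at one position.

    Potentials are in microvolts per nA*m, *not* average-referenced.
    """
    R3 = radii[2]
    scaled = tuple(r / R3 for r in radii)
    b_vec = np.asarray(dipole_pos, float) / R3
    sens = np.asarray(sensor_positions, float) / R3
    b = np.linalg.norm(b_vec)
    if b >= scaled[0]:
        raise ValueError("dipole outside the brain shell")
    rb_hat = b_vec / b if b > 0 else np.array([0.0, 0.0, 1.0])

    rn = np.linalg.norm(sens, axis=1)
    rs_hat = sens / rn[:, None]
    cosg = np.clip(rs_hat @ rb_hat, -1.0, 1.0)
    sing = np.sqrt(np.clip(1.0 - cosg**2, 0.0, None))
    t_hat = rs_hat - cosg[:, None] * rb_hat
    ok = sing > 1e-12
    t_hat[ok] /= sing[ok, None]
    t_hat[~ok] = 0.0

    P, P1 = _legendre_terms(cosg, n_terms)
    F = _radial_responses(n_terms, scaled, conductivities)
    ns = np.arange(1, n_terms + 1, dtype=float)
    radial_series = F * np.where(ns == 1, 1.0, b ** (ns - 1))  # b^(n-1), b=0 safe

    # V = sum_n radial_n * (n q_r P_n + q_t P_n^1) / (4 pi sigma1 R3^2)
    coef_r = np.einsum("n,n,ns->s", radial_series, ns, P[1:])
    coef_t = np.einsum("n,ns->s", radial_series, P1[1:])
    # moment decomposition: q_r = q . rb_hat, q_t = q . t_hat (per sensor)
    pots = coef_r[:, None] * rb_hat[None, :] + coef_t[:, None] * t_hat
    # unit conversion: q in nA*m = 1e-9 A*m, lengths in mm (R3 in m = R3mm*1e-3),
    # V in volts = 1e6 uV  ->  factor 1e-9 / (R3m^2) * 1e6
    scale = 1e-9 / (4 * np.pi * conductivities[0] * (R3 * 1e-3) ** 2) * 1e6
    return pots * scale


def build_spherical_leadfield(
    sensor_positions: np.ndarray,
    grid: np.ndarray | None = None,
    spacing: float = 6.0,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    n_terms: int = 60,
) -> LeadfieldModel:
    """Average-referenced three-shell leadfield on a regular source grid."""
    sensor_positions = np.asarray(sensor_positions, float)
    if sensor_positions.shape[0] < 16:
        raise ValueError("need at least 16 sensors")
    sens = fit_sensors_to_scalp(sensor_positions, radii[2])
    if grid is None:
        grid = make_source_grid(spacing, radii)
    else:
        grid = np.asarray(grid, float)
    bad = np.linalg.norm(grid, axis=1) >= radii[0]
    if np.any(bad):
        raise ValueError(
            f"grid nodes outside the brain shell: indices {np.nonzero(bad)[0].tolist()}"
        )
    gain = np.empty((sens.shape[0], grid.shape[0] * 3))
    for j, pos in enumerate(grid):
        gain[:, 3 * j: 3 * j + 3] = dipole_potentials(
            pos, sens, radii, conductivities, n_terms
        )
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return LeadfieldModel(gain, grid, spacing, radii, conductivities, sens)


# ---------------------------------------------------------------------------
# eLORETA
# ---------------------------------------------------------------------------

def _sym_sqrt_blocks(B: np.ndarray) -> np.ndarray:
    """Symmetric square roots of a stack of symmetric PSD 3x3 blocks."""
    B = (B + B.transpose(0, 2, 1)) / 2
    w, V = np.linalg.eigh(B)
    w = np.clip(w, 0.0, None)
    return np.einsum("nij,nj,nkj->nik", V, np.sqrt(w), V)


def compute_eloreta_operator(
    leadfield: LeadfieldModel,
    alpha_frac: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InverseOperator:
    """eLORETA fixed point: W_j <- sqrtm(K_j^T M K_j), M = (K W^-1 K^T + a H)^+.

    H is the average-reference centering operator; alpha is ``alpha_frac``
    times the mean diagonal of the weighted gram matrix, recomputed per
    iteration.  Non-convergence is recorded in the diagnostics, not raised.
    """
    if alpha_frac <= 0:
        raise ValueError("alpha_frac must be positive")
    K = leadfield.gain
    m, p3 = K.shape
    n = p3 // 3
    Kb = K.reshape(m, n, 3)
    H = np.eye(m) - np.ones((m, m)) / m
    W = np.tile(np.eye(3), (n, 1, 1))
    alpha = np.nan
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        Winv = np.linalg.inv(W)
        # C = K W^-1 K^T
        KW = np.einsum("mnj,njk->mnk", Kb, Winv)
        C = np.einsum("mnk,pnk->mp", KW, Kb)
        alpha = alpha_frac * np.trace(C) / m
        M = np.linalg.pinv(C + alpha * H)
        B = np.einsum("mnj,mp,pnk->njk", Kb, M, Kb)
        W_new = _sym_sqrt_blocks(B)
        # per-node relative Frobenius change is robust to near-zero entries
        num = np.linalg.norm(W_new - W, axis=(1, 2))
        den = np.maximum(np.linalg.norm(W, axis=(1, 2)), 1e-300)
        change = float(np.max(num / den))
        W = W_new
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"eLORETA did not converge in {max_iter} iterations "
            f"(final relative change {change:.2e})",
            RuntimeWarning,
        )
    Winv = np.linalg.inv(W)
    KW = np.einsum("mnj,njk->mnk", Kb, Winv)
    C = np.einsum("mnk,pnk->mp", KW, Kb)
    M = np.linalg.pinv(C + alpha * H)
    transfer = np.einsum("njk,mnk,mp->njp", Winv, Kb, M).reshape(n * 3, m)
    return InverseOperator(transfer, W, float(alpha), it, change, converged)


def localize_single_dipole(
    inverse_op: InverseOperator, sensor_data: np.ndarray
) -> int:
    """Grid node with maximal estimated source power for one topography."""
    moments = inverse_op.transfer @ sensor_data
    power = (moments.reshape(-1, 3) ** 2).sum(axis=1)
    return int(np.argmax(power))


# ---------------------------------------------------------------------------
# ROI time courses
# ---------------------------------------------------------------------------

@dataclass
class ROITimecourses:
    """Scalar time course per ROI with membership metadata."""

    data: np.ndarray            # (n_roi, n_samples)
    rate: float
    names: tuple[str, ...]
    networks: tuple[str, ...]
    centers_head: np.ndarray    # (n_roi, 3) mm
    member_nodes: list[list[int]]


def extract_roi_timecourses(
    rec: SensorRecording,
    leadfield: LeadfieldModel,
    inverse_op: InverseOperator,
    table: NetworkTable,
    sphere_radius: float = 6.0,
) -> ROITimecourses:
    """First-PC scalar time course of each 6-mm spherical ROI.

    Grid nodes within ``sphere_radius`` of the ROI centre contribute; if the
    sphere is empty on a coarse grid the centre snaps to its nearest node.
    The scalar course is the first principal component of the stacked
    3-orientation node moments, sign-aligned with the stack mean.
    """
    if rec.reference != "average":
        raise ValueError("recording must be average-referenced before inversion")
    centers = table.coords_head
    courses = np.empty((len(table), rec.n_samples))
    members: list[list[int]] = []
    for i, c in enumerate(centers):
        d = np.linalg.norm(leadfield.grid - c, axis=1)
        nodes = np.nonzero(d <= sphere_radius)[0].tolist()
        if not nodes:
            nodes = [int(np.argmin(d))]
        members.append(nodes)
        rows = np.concatenate([np.arange(3 * j, 3 * j + 3) for j in nodes])
        stack = inverse_op.transfer[rows] @ rec.data
        U, s, _ = np.linalg.svd(stack, full_matrices=False)
        course = U[:, 0] @ stack
        ref = stack.mean(axis=0)
        if np.dot(course, ref) < 0:
            course = -course
        courses[i] = course
    return ROITimecourses(
        data=courses,
        rate=rec.rate,
        names=table.names,
        networks=table.networks,
        centers_head=centers,
        member_nodes=members,
    )
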