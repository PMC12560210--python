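"""kT-point pulse design in the small-tip-angle approximation.

A kT-point pulse is a short train of rectangular subpulses played at discrete
excitation k-space locations reached by gradient blips.  In the small-tip
regime the flip angle is linear in the per-channel subpulse weights,

    FA(r) = | sum_j tau_j * (sum_ch B_ch(r) b_ch,j) * exp(i k_j . r) | * scale

so the design is a regularized magnitude least-squares problem

    min_b 1/2 || m_d - |A b| ||_ROI^2 + beta/2 ||b||^2

solved by variable exchange (phase adoption): alternate a Tikhonov solve for
b with the target phase fixed, and adoption of the phase of A b as the new
target phase.  k-space locations come from an interleaved greedy placement
on a symmetric Cartesian candidate grid followed by local continuous
refinement; sweeping the regularization parameter beta produces the L-curve
of integrated RF power against flip-angle CV.

The total pulse length is held near 1 ms (which keeps off-resonance phase
accrual negligible and is why Delta-B0 is not modeled): subpulse durations
shrink as points are added, with a fixed 80 us blip between subpulses.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy import linalg as sla

from .synth import B1MapSet

__all__ = [
    "KTPulse",
    "SystemMatrix",
    "LCurve",
    "SolveResult",
    "build_timing",
    "build_system_matrix",
    "solve_weights",
    "tikhonov_sweep",
    "design_kt_pulse",
    "sweep_lcurve",
    "small_tip_fa",
    "shim_to_pulse",
]

#: Flip angle (degrees) produced by a unit relative field driven for 1 ms at
#: unit weight.  The single scale converting relative maps to degrees.
DEFAULT_SCALE_DEG = 10.0

DEFAULT_BLIP_US = 80
DEFAULT_BUDGET_US = 920  # RF-on + blip budget for multi-point pulses
STATIC_SUBPULSE_US = 1000  # single-subpulse (static shim) duration


@dataclasses.dataclass
class KTPulse:
    """A designed kT-point pulse.

    ``weights`` has shape (n_channels, n_kt): one complex amplitude per
    channel and subpulse.  ``k_locations`` (rad/m) are played in order, the
    final point always at the k-space origin.  Inactive channels carry zero
    weight in every subpulse.
    """

    k_locations: np.ndarray  # (n_kt, 3) rad/m
    weights: np.ndarray  # (n_channels, n_kt)
    subpulse_us: int
    blip_us: int = DEFAULT_BLIP_US
    nominal_fa_deg: float = 10.0
    scale_deg: float = DEFAULT_SCALE_DEG

    def __post_init__(self) -> None:
        self.k_locations = np.atleast_2d(np.asarray(self.k_locations, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=np.complex128))
        if self.k_locations.shape != (self.n_kt, 3):
            raise ValueError("k_locations must be (n_kt, 3)")
        if self.weights.shape[1] != self.n_kt:
            raise ValueError("weights must have one column per subpulse")
        if not np.allclose(self.k_locations[-1], 0.0):
            raise ValueError("final k-space location must be the origin")
        if self.total_duration_us > STATIC_SUBPULSE_US + self.n_kt:  # rounding slack
            raise ValueError("pulse exceeds the ~1 ms duration budget")

    @property
    def n_kt(self) -> int:
        return self.weights.shape[1] if self.weights.ndim == 2 else 1

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def total_duration_us(self) -> int:
        return self.n_kt * self.subpulse_us + (self.n_kt - 1) * self.blip_us


@dataclasses.dataclass
class SystemMatrix:
    """Dense small-tip system matrix over ROI voxels.

    Column (j, c) maps weight b_{c,j} of active channel c in subpulse j to
    its flip-angle contribution at each voxel:

        A[i, (j,c)] = scale * (tau_j / 1 ms) * B_c(r_i) * exp(i k_j . r_i)

    Columns are subpulse-major; only active channels get columns (dead
    channels are re-inserted as zeros when weights are expanded).
    """

    a: np.ndarray  # (V, K * C_active)
    coords: np.ndarray  # (V, 3) meters
    k_locations: np.ndarray  # (K, 3)
    subpulse_us: float
    active_channels: np.ndarray  # indices into the full channel list
    n_channels: int
    scale_deg: float

    @property
    def n_kt(self) -> int:
        return self.k_locations.shape[0]

    def expand_weights(self, b: np.ndarray) -> np.ndarray:
        """Flat active-channel solution vector -> (n_channels, n_kt)."""
        k = self.n_kt
        ca = self.active_channels.size
        w = np.zeros((self.n_channels, k), dtype=np.complex128)
        w[self.active_channels, :] = b.reshape(k, ca).T
        return w


@dataclasses.dataclass
class LCurve:
    """(beta, integrated RF power, CV) triples for one design configuration."""

    betas: np.ndarray
    power: np.ndarray
    cv: np.ndarray
    fingerprint: dict

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if np.any(np.diff(self.betas) <= 0):
            raise ValueError("betas must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"beta": self.betas, "power": self.power, "cv": self.cv})


@dataclasses.dataclass
class SolveResult:
    weights: np.ndarray  # flat active-channel vector, subpulse-major
    objective_trace: list
    theta: np.ndarray
    residual: float

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def build_timing(
    n_kt: int,
    blip_us: int = DEFAULT_BLIP_US,
    on_plus_blip_budget_us: int = DEFAULT_BUDGET_US,
) -> int:
    """Integer subpulse duration (us) for an n_kt-point pulse under the
    ~1 ms budget.

    Multi-point pulses share ``on_plus_blip_budget_us`` between RF-on time
    and (n_kt - 1) fixed blips, rounding the per-subpulse duration to the
    nearest microsecond; the single-subpulse static case uses the full 1 ms.
    """
    if n_kt < 1:
        raise ValueError("n_kt must be >= 1")
    if n_kt == 1:
        return STATIC_SUBPULSE_US
    remaining = on_plus_blip_budget_us - (n_kt - 1) * blip_us
    sub = int(round(remaining / n_kt))
    if sub <= 0:
        raise ValueError(
            f"no RF-on time left: {n_kt} subpulses with {blip_us} us blips "
            f"exceed the {on_plus_blip_budget_us} us budget"
        )
    return sub


def small_tip_fa(
    b1: B1MapSet,
    mask: np.ndarray,
    k_locations: np.ndarray,
    weights: np.ndarray,
    subpulse_us: float,
    scale_deg: float = DEFAULT_SCALE_DEG,
) -> np.ndarray:
    """Small-tip flip angle (degrees) at the masked voxels."""
    coords = b1.phantom.coordinates_m()[mask]  # (V, 3)
    m = b1.maps[:, mask].T  # (V, C)
    ks = np.atleast_2d(k_locations)
    w = np.atleast_2d(weights)
    tau_ms = subpulse_us / 1000.0
    acc = np.zeros(m.shape[0], dtype=np.complex128)
    for j in range(ks.shape[0]):
        acc += (m @ w[:, j]) * np.exp(1j * (coords @ ks[j]))
    return np.abs(acc) * tau_ms * scale_deg


def shim_to_pulse(shim) -> KTPulse:
    """View a static shim as the degenerate single-subpulse kT pulse."""
    w = shim.weights if hasattr(shim, "weights") else np.asarray(shim)
    return KTPulse(
        k_locations=np.zeros((1, 3)),
        weights=np.asarray(w, dtype=np.complex128).reshape(-1, 1),
        subpulse_us=STATIC_SUBPULSE_US,
    )


def build_system_matrix(
    b1: B1MapSet,
    roi: np.ndarray,
    k_locations,
    subpulse_us: float,
    scale_deg: float = DEFAULT_SCALE_DEG,
    k_max: float | None = None,
    voxel_subset: np.ndarray | None = None,
) -> SystemMatrix:
    """Assemble the dense small-tip system matrix over the ROI."""
    ks = np.atleast_2d(np.asarray(k_locations, dtype=float))
    if k_max is not None and np.abs(ks).max() > k_max * (1 + 1e-12):
        raise ValueError(f"k-space location beyond configured k_max={k_max}")
    if not np.any(roi):
        raise ValueError("empty ROI")
    coords = b1.phantom.coordinates_m()[roi]
    active = np.flatnonzero(b1.active_mask)
    m = b1.maps[:, roi].T[:, active]  # (V, Ca)
    if voxel_subset is not None:
        coords = coords[voxel_subset]
        m = m[voxel_subset]
    tau_ms = subpulse_us / 1000.0
    cols = []
    for j in range(ks.shape[0]):
        ramp = np.exp(1j * (coords @ ks[j]))
        cols.append(scale_deg * tau_ms * ramp[:, None] * m)
    a = np.concatenate(cols, axis=1)
    return SystemMatrix(
        a=a,
        coords=coords,
        k_locations=ks,
        subpulse_us=float(subpulse_us),
        active_channels=active,
        n_channels=b1.n_channels,
        scale_deg=scale_deg,
    )


def _ridge_solve(g: np.ndarray, beta: float, rhs: np.ndarray) -> np.ndarray:
    n = g.shape[0]
    h = g + beta * np.eye(n)
    try:
        c, low = sla.cho_factor(h, check_finite=False)
        return sla.cho_solve((c, low), rhs, check_finite=False)
    except np.linalg.LinAlgError:
        ridge = 1e-12 * max(np.trace(h).real / n, 1.0)
        warnings.warn(
            "singular normal equations; falling back to a tiny ridge "
            f"({ridge:.1e}) for stability"
        )
        return sla.solve(h + ridge * np.eye(n), rhs, assume_a="her", check_finite=False)


def solve_weights(
    a_mat: SystemMatrix,
    target_fa_deg: float,
    beta: float,
    max_iter: int = 50,
    tol: float = 1e-8,
    theta0: np.ndarray | None = None,
) -> SolveResult:
    """Variable-exchange magnitude least squares with Tikhonov regularization.

    With the target phase theta held fixed each step is the closed-form ridge
    solve b = (A^H A + beta I)^-1 A^H (m_d e^{i theta}); theta is then
    replaced by the phase of A b (phase adoption).  Both steps decrease

        J(b, theta) = 1/2 ||m_d e^{i theta} - A b||^2 + beta/2 ||b||^2

    so the objective trace is monotone non-increasing (asserted).  theta is
    initialized from the zero-phase-shim field unless ``theta0`` is given;
    passing ``theta0`` with ``max_iter=1`` returns the plain fixed-phase
    Tikhonov solution.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    a = a_mat.a
    v, n = a.shape
    m_d = float(target_fa_deg) * np.ones(v)
    g = a.conj().T @ a

    if theta0 is None:
        b0 = np.ones(n) / np.sqrt(n)
        theta = np.angle(a @ b0)
    else:
        theta = np.asarray(theta0, dtype=float)

    b = np.zeros(n, dtype=np.complex128)
    trace: list[float] = []
    prev_obj = np.inf
    for _ in range(max_iter):
        rhs = a.conj().T @ (m_d * np.exp(1j * theta))
        b_new = _ridge_solve(g, beta, rhs)
        z = a @ b_new
        theta = np.angle(z)
        obj = 0.5 * np.sum((m_d - np.abs(z)) ** 2) + 0.5 * beta * np.sum(
            np.abs(b_new) ** 2
        )
        trace.append(float(obj))
        if obj > prev_obj * (1 + 1e-9) + 1e-12:
            raise RuntimeError("variable-exchange objective increased")
        step = np.linalg.norm(b_new - b) / max(np.linalg.norm(b_new), 1e-300)
        b = b_new
        prev_obj = obj
        if step < tol:
            break
    residual = float(np.linalg.norm(m_d - np.abs(a @ b)))
    return SolveResult(weights=b, objective_trace=trace, theta=theta, residual=residual)


def tikhonov_sweep(
    a_mat: SystemMatrix,
    target_fa_deg: float,
    betas,
    theta: np.ndarray | None = None,
):
    """Fixed-phase Tikhonov solves across a beta grid.

    Returns (betas, weight_norms, residuals).  With the k-space locations and
    the target phase fixed this is a pure ridge family: ||b|| is monotone
    non-increasing and the residual monotone non-decreasing in beta.
    """
    a = a_mat.a
    v, n = a.shape
    if theta is None:
        theta = np.angle(a @ (np.ones(n) / np.sqrt(n)))
    m = float(target_fa_deg) * np.exp(1j * np.asarray(theta))
    g = a.conj().T @ a
    rhs = a.conj().T @ m
    betas = np.asarray(betas, dtype=float)
    norms = np.empty_like(betas)
    residuals = np.empty_like(betas)
    for i, beta in enumerate(betas):
        if beta < 0:
            raise ValueError("beta must be >= 0")
        b = _ridge_solve(g, beta, rhs)
        norms[i] = np.linalg.norm(b)
        residuals[i] = np.linalg.norm(m - a @ b)
    return betas, norms, residuals


class _DesignProblem:
    """Gram-space workspace for greedy placement and local refinement.

    Works on a (possibly subsampled) set of ROI voxels; all candidate scoring
    goes through Gram blocks tau^2 B^H diag(e^{i (k - k') . r}) B so the tall
    matrix is never rebuilt per candidate.
    """

    def __init__(self, b1, roi, n_kt, target_fa_deg, scale_deg, max_voxels, rng):
        self.active = np.flatnonzero(b1.active_mask)
        roi_idx = np.flatnonzero(roi.ravel())
        coords = b1.phantom.coordinates_m().reshape(-1, 3)[roi_idx]
        m = b1.maps.reshape(b1.n_channels, -1)[:, roi_idx].T[:, self.active]
        if max_voxels is not None and coords.shape[0] > max_voxels:
            sub = np.sort(rng.choice(coords.shape[0], size=max_voxels, replace=False))
            coords, m = coords[sub], m[sub]
        self.coords = coords
        self.subpulse_us = build_timing(n_kt)
        self.tau_ms = self.subpulse_us / 1000.0
        self.b = scale_deg * self.tau_ms * m  # (V, Ca), tau folded in
        self.btb = self.b.conj().T @ self.b
        self.m_d = float(target_fa_deg) * np.ones(coords.shape[0])
        self.n_kt = n_kt
        self.ca = self.active.size

    def ramps(self, ks: np.ndarray) -> np.ndarray:
        return np.exp(1j * (self.coords @ np.atleast_2d(ks).T))  # (V, K)

    def gram(self, ks: np.ndarray) -> np.ndarray:
        k = np.atleast_2d(ks).shape[0]
        p = self.ramps(ks)
        g = np.empty((k * self.ca, k * self.ca), dtype=np.complex128)
        for j in range(k):
            for l in range(j, k):
                if j == l:
                    blk = self.btb
                else:
                    d = np.conj(p[:, j]) * p[:, l]
                    blk = self.b.conj().T @ (d[:, None] * self.b)
                g[j * self.ca:(j + 1) * self.ca, l * self.ca:(l + 1) * self.ca] = blk
                if l != j:
                    g[l * self.ca:(l + 1) * self.ca, j * self.ca:(j + 1) * self.ca] = (
                        blk.conj().T
                    )
        return g

    def rhs(self, ks: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = self.ramps(ks)
        parts = [self.b.conj().T @ (np.conj(p[:, j]) * y) for j in range(p.shape[1])]
        return np.concatenate(parts)

    def field(self, ks: np.ndarray, b: np.ndarray) -> np.ndarray:
        p = self.ramps(ks)
        k = p.shape[1]
        z = np.zeros(self.coords.shape[0], dtype=np.complex128)
        for j in range(k):
            z += p[:, j] * (self.b @ b[j * self.ca:(j + 1) * self.ca])
        return z

    def solve_ve(self, ks, beta, theta=None, max_iter=200, tol=1e-10):
        """Variable-exchange solve in Gram space; returns (b, theta, obj)."""
        ks = np.atleast_2d(ks)
        g = self.gram(ks)
        n = g.shape[0]
        if theta is None:
            theta = np.angle(self.field(ks, np.ones(n) / np.sqrt(n)))
        b = np.zeros(n, dtype=np.complex128)
        obj = np.inf
        for _ in range(max_iter):
            rhs = self.rhs(ks, self.m_d * np.exp(1j * theta))
            b_new = _ridge_solve(g, beta, rhs)
            z = self.field(ks, b_new)
            theta = np.angle(z)
            obj_new = 0.5 * np.sum((self.m_d - np.abs(z)) ** 2) + 0.5 * beta * np.sum(
                np.abs(b_new) ** 2
            )
            if abs(obj - obj_new) < tol * max(obj_new, 1.0) or np.linalg.norm(
                b_new - b
            ) < tol * max(np.linalg.norm(b_new), 1e-300):
                b, obj = b_new, obj_new
                break
            b, obj = b_new, obj_new
        return b, theta, float(obj)

    def score_candidates(self, ks_existing, cands, beta, theta, chunk=64):
        """Objective after adding each candidate location (2 VE iterations)."""
        ks_existing = np.atleast_2d(ks_existing)
        n_exist = ks_existing.shape[0]
        p_exist = self.ramps(ks_existing)
        g_old = self.gram(ks_existing)
        objs = np.empty(cands.shape[0])
        y0 = self.m_d * np.exp(1j * theta)
        for start in range(0, cands.shape[0], chunk):
            kc = cands[start:start + chunk]
            pc = self.ramps(kc)  # (V, nc)
            nc = kc.shape[0]
            # Cross blocks old_j x candidate: B^H diag(conj(p_j) p_c) B
            cross = np.empty((nc, n_exist, self.ca, self.ca), dtype=np.complex128)
            for j in range(n_exist):
                w = self.b.conj() * np.conj(p_exist[:, j])[:, None]  # (V, Ca)
                cross[:, j] = np.einsum("va,vc,vb->cab", w, pc, self.b, optimize=True)
            rhs_cand = np.einsum(
                "va,vc->ca", self.b.conj(), pc.conj() * y0[:, None], optimize=True
            )
            rhs_old = self.rhs(ks_existing, y0)
            for c in range(nc):
                n_tot = (n_exist + 1) * self.ca
                g = np.empty((n_tot, n_tot), dtype=np.complex128)
                g[: n_exist * self.ca, : n_exist * self.ca] = g_old
                for j in range(n_exist):
                    blk = cross[c, j]
                    g[j * self.ca:(j + 1) * self.ca, n_exist * self.ca:] = blk
                    g[n_exist * self.ca:, j * self.ca:(j + 1) * self.ca] = blk.conj().T
                g[n_exist * self.ca:, n_exist * self.ca:] = self.btb
                ks_all = np.vstack([ks_existing, kc[c]])
                th = theta
                b = None
                for _ in range(2):  # short warm-started VE during scoring
                    rhs = (
                        np.concatenate([rhs_old, rhs_cand[c]])
                        if th is theta
                        else self.rhs(ks_all, self.m_d * np.exp(1j * th))
                    )
                    b = _ridge_solve(g, beta, rhs)
                    z = self.field(ks_all, b)
                    th = np.angle(z)
                objs[start + c] = 0.5 * np.sum(
                    (self.m_d - np.abs(z)) ** 2
                ) + 0.5 * beta * np.sum(np.abs(b) ** 2)
        return objs


def _candidate_grid(b1, roi, n_per_axis=7, k_max=None):
    """Symmetric Cartesian candidate grid spanning +-k_max per axis."""
    coords = b1.phantom.coordinates_m()[roi]
    if k_max is None:
        extent = coords.max(axis=0) - coords.min(axis=0)
        extent = np.maximum(extent, 1e-3)
        k_max = np.pi / (2.0 * extent)  # per-axis
    else:
        k_max = np.broadcast_to(np.asarray(k_max, dtype=float), (3,))
    axes = [np.linspace(-k, k, n_per_axis) for k in k_max]
    grid = np.array(list(itertools.product(*axes)))
    return grid, np.asarray(k_max, dtype=float)


def design_kt_pulse(
    b1: B1MapSet,
    roi: np.ndarray,
    n_kt: int,
    beta: float,
    n_starts: int = 100,
    candidate_grid: np.ndarray | None = None,
    seed: int = 0,
    target_fa_deg: float = 10.0,
    scale_deg: float = DEFAULT_SCALE_DEG,
    local_iters: int = 30,
    max_voxels: int = 3000,
    power_target: float | None = None,
    warm_k: np.ndarray | None = None,
    warm_theta: np.ndarray | None = None,
    grid_points_per_axis: int = 7,
    n_keep: int = 3,
) -> tuple[KTPulse, dict]:
    """Design an n_kt-point pulse by interleaved greedy + local optimization.

    Greedy phase: starting from the k-space origin, repeatedly add the
    candidate grid location whose re-solved weights most reduce the
    regularized magnitude least-squares objective (ties broken toward
    smaller ||k||) until ``n_kt`` points are placed; the origin point is kept
    and played last.  Local phase: continuous finite-difference refinement of
    the non-origin locations, re-solving weights after every accepted move,
    with an adaptive multiplicative beta update every 50 iterations toward
    ``power_target`` when one is set.

    The variable-exchange solve has many local basins in the target phase,
    so ``n_starts`` pseudo-random starting phases (plus the zero-phase
    initialization) are screened on the cheap origin-only problem and the
    best ``n_keep`` seed the full greedy + local pipeline; the best final
    objective wins.  Deterministic for a fixed seed.

    ``warm_k`` skips the greedy phase and refines from the given locations
    (used by the L-curve sweep); metrics are recomputed on the full ROI from
    the returned pulse.
    """
    if n_kt < 1:
        raise ValueError("n_kt must be >= 1")
    rng = np.random.default_rng(seed)
    prob = _DesignProblem(b1, roi, n_kt, target_fa_deg, scale_deg, max_voxels, rng)

    if candidate_grid is None:
        cands, k_max = _candidate_grid(b1, roi, grid_points_per_axis)
    else:
        cands = np.atleast_2d(np.asarray(candidate_grid, dtype=float))
        if cands.size == 0:
            raise ValueError("empty candidate grid")
        k_max = np.abs(cands).max(axis=0)
    if cands.shape[0] == 0:
        raise ValueError("empty candidate grid")
    if n_kt - 1 > cands.shape[0]:
        raise ValueError("n_kt exceeds candidate grid size")

    origin = np.zeros(3)
    beta0 = float(beta)
    best = None

    if warm_theta is not None:
        thetas: list[np.ndarray | None] = [np.asarray(warm_theta, dtype=float)]
    else:
        cand_thetas: list[np.ndarray | None] = [None]  # zero-phase-field init
        for _ in range(max(n_starts - 1, 0)):
            b_init = np.exp(1j * rng.uniform(-np.pi, np.pi, size=prob.ca))
            cand_thetas.append(
                np.angle(prob.field(origin[None], b_init / np.sqrt(prob.ca)))
            )
        if len(cand_thetas) > n_keep:
            scored = []
            for th in cand_thetas:
                _, th_out, obj = prob.solve_ve(origin[None], beta0, th,
                                               max_iter=60)
                scored.append((obj, th_out))
            scored.sort(key=lambda t: t[0])
            thetas = [th for _, th in scored[:n_keep]]
        else:
            thetas = cand_thetas

    for theta in thetas:
        beta_s = beta0

        if warm_k is not None:
            ks = np.atleast_2d(np.asarray(warm_k, dtype=float)).copy()
            if ks.shape[0] != n_kt:
                raise ValueError("warm_k must provide n_kt locations")
            ks[-1] = origin  # final point pinned to the k-space origin
            b, theta, obj = prob.solve_ve(ks, beta_s, theta, max_iter=200)
        else:
            ks = origin[None].copy()
            b, theta, obj = prob.solve_ve(ks, beta_s, theta, max_iter=200)
            while ks.shape[0] < n_kt:
                objs = prob.score_candidates(ks, cands, beta_s, theta)
                # ties toward smaller ||k||
                knorm = np.linalg.norm(cands, axis=1)
                order = np.lexsort((knorm, np.round(objs / max(objs.min(), 1e-300), 12)))
                pick = cands[order[0]]
                ks = np.vstack([pick, ks])  # origin stays last
                b, theta, obj = prob.solve_ve(ks, beta_s, theta, max_iter=60)

        # Local continuous refinement of non-origin points.
        if n_kt > 1 and local_iters > 0:
            step = 0.1 * float(np.mean(k_max))
            h = 0.01 * np.mean(k_max)
            for it in range(local_iters):
                if power_target is not None and it > 0 and it % 50 == 0:
                    power = _pulse_power(b, prob)
                    beta_s = float(
                        np.clip(beta_s * (power / power_target) ** 0.7, 1e-12, 1e6)
                    )
                    b, theta, obj = prob.solve_ve(ks, beta_s, theta, max_iter=30)
                grad = np.zeros((n_kt - 1, 3))
                for j in range(n_kt - 1):
                    for ax in range(3):
                        for sgn, sign in ((1.0, 0), (-1.0, 1)):
                            ks_p = ks.copy()
                            ks_p[j, ax] += sgn * h
                            _, _, o = prob.solve_ve(ks_p, beta_s, theta, max_iter=3)
                            grad[j, ax] += sgn * o / (2 * h)
                gnorm = np.linalg.norm(grad)
                if gnorm < 1e-12:
                    break
                improved = False
                s = step
                for _ in range(4):
                    ks_try = ks.copy()
                    ks_try[:-1] -= s * grad / gnorm
                    ks_try[:-1] = np.clip(ks_try[:-1], -k_max, k_max)
                    b_t, th_t, o_t = prob.solve_ve(ks_try, beta_s, theta, max_iter=8)
                    if o_t < obj:
                        ks, b, theta, obj = ks_try, b_t, th_t, o_t
                        step = min(s * 1.5, 0.5 * float(np.mean(k_max)))
                        improved = True
                        break
                    s *= 0.4
                if not improved:
                    step *= 0.4
                    if step < 1e-4 * np.mean(k_max):
                        break

        b, theta, obj = prob.solve_ve(ks, beta_s, theta, max_iter=300)
        if best is None or obj < best[0]:
            best = (obj, ks.copy(), b.copy(), theta.copy(), beta_s)

    obj, ks, b, theta, beta_final = best
    weights = np.zeros((b1.n_channels, n_kt), dtype=np.complex128)
    weights[prob.active, :] = b.reshape(n_kt, prob.ca).T
    pulse = KTPulse(
        k_locations=ks,
        weights=weights,
        subpulse_us=prob.subpulse_us,
        nominal_fa_deg=target_fa_deg,
        scale_deg=scale_deg,
    )

    fa = small_tip_fa(b1, roi, ks, weights, prob.subpulse_us, scale_deg)
    metrics = {
        "objective": float(obj),
        "beta": float(beta_final),
        "cv": float(fa.std() / fa.mean()),
        "fa_mean_deg": float(fa.mean()),
        "integrated_power": float(
            (np.abs(weights) ** 2).sum() * prob.subpulse_us * 1e-6
        ),
        "theta": theta,
    }
    return pulse, metrics


def _pulse_power(b: np.ndarray, prob: _DesignProblem) -> float:
    return float((np.abs(b) ** 2).sum() * prob.subpulse_us * 1e-6)


def sweep_lcurve(
    b1: B1MapSet,
    roi: np.ndarray,
    n_kt: int,
    beta_grid=None,
    seed: int = 0,
    n_starts: int = 100,
    local_iters: int = 10,
    max_voxels: int = 3000,
    target_fa_deg: float = 10.0,
    scale_deg: float = DEFAULT_SCALE_DEG,
    grid_points_per_axis: int = 7,
) -> LCurve:
    """L-curve over the regularization parameter for one configuration.

    Betas default to 27 log-spaced values in [1e-10, 1e3].  Designs run in
    descending beta order, each warm-started from the previous solution's
    k-locations and target phase; every stored (power, cv) pair is recomputed
    on the full ROI from the stored pulse, not taken from optimizer internals.
    """
    if beta_grid is None:
        beta_grid = np.logspace(-10, 3, 27)
    betas = np.sort(np.asarray(beta_grid, dtype=float))
    if np.any(betas < 0):
        raise ValueError("beta must be >= 0")

    power = np.empty_like(betas)
    cv = np.empty_like(betas)
    warm_k = None
    warm_theta = None
    for i in range(betas.size - 1, -1, -1):
        pulse, metrics = design_kt_pulse(
            b1,
            roi,
            n_kt,
            betas[i],
            n_starts=n_starts if warm_k is None else 1,
            seed=seed,
            target_fa_deg=target_fa_deg,
            scale_deg=scale_deg,
            local_iters=local_iters,
            max_voxels=max_voxels,
            warm_k=warm_k,
            warm_theta=warm_theta,
            grid_points_per_axis=grid_points_per_axis,
        )
        warm_k = pulse.k_locations
        # same seed -> identical design-voxel subsample, so theta transfers
        warm_theta = metrics["theta"]
        fa = small_tip_fa(b1, roi, pulse.k_locations, pulse.weights,
                          pulse.subpulse_us, scale_deg)
        cv[i] = fa.std() / fa.mean()
        power[i] = (np.abs(pulse.weights) ** 2).sum() * pulse.subpulse_us * 1e-6
    return LCurve(
        betas=betas,
        power=power,
        cv=cv,
        fingerprint={"n_kt": n_kt, "n_channels_active": int(b1.active_mask.sum()),
                     "seed": seed},
    )
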