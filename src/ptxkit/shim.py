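"""Static pTx shimming: phase-only and magnitude+phase complex weights.

One complex weight b_ch = a_ch * exp(i*phi_ch) per transmit channel scales a
common pulse shape.  The shim is chosen to minimize

    cost = CV - cost_weight * eta

over the ROI, where CV = std/mean of the superposed field magnitude
|sum_ch B_ch b_ch| (the homogeneity metric) and eta is the transmit
efficiency, the mean constructive-interference fraction
|sum_ch B_ch b_ch| / sum_ch |B_ch b_ch|.  Both metrics are invariant under a
global phase and under positive rescaling of the weights, so solutions are
reported at a fixed total power and with the first active channel's phase
zeroed.

The optimizer is a multi-start quasi-Newton descent over phases (and
log-magnitudes in magnitude+phase mode) with an analytic gradient; 100
pseudo-random phase starts with equal amplitudes by default.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize

from .synth import B1MapSet

__all__ = [
    "ShimWeights",
    "ShimMetrics",
    "compute_cv",
    "compute_efficiency",
    "zero_phase_weights",
    "optimize_static_shim",
]

#: Duration (s) of the common rectangular pulse a static shim scales.
STATIC_PULSE_S = 1.0e-3


@dataclasses.dataclass
class ShimWeights:
    """Per-channel complex shim weights.

    ``mode`` is ``"phase_only"`` (equal magnitudes on active channels) or
    ``"mag_phase"``.  Inactive channels carry exactly zero weight.
    ``power_norm`` is the total sum |b|^2 the vector is normalized to, the
    common scale used when comparing configurations.
    """

    weights: np.ndarray
    mode: str
    power_norm: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.complex128)
        if self.mode not in ("phase_only", "mag_phase", "zero_phase"):
            raise ValueError(f"unknown shim mode {self.mode!r}")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass(frozen=True)
class ShimMetrics:
    cv: float
    efficiency: float
    integrated_power: float  # sum |b|^2 * tau, relative units * seconds


def _superposed(b1: B1MapSet, roi: np.ndarray, weights: np.ndarray) -> np.ndarray:
    if weights.shape[0] != b1.n_channels:
        raise ValueError("weight vector length must match channel count")
    m = b1.roi_matrix(roi)  # (V, C)
    if m.shape[0] == 0:
        raise ValueError("empty ROI")
    return m @ weights


def compute_cv(b1: B1MapSet, roi: np.ndarray, weights) -> float:
    """Coefficient of variation (population std / mean) of |sum_ch B_ch b_ch|
    over the ROI voxels."""
    w = weights.weights if isinstance(weights, ShimWeights) else np.asarray(weights)
    mag = np.abs(_superposed(b1, roi, w))
    mean = mag.mean()
    if mean <= 0:
        raise ValueError("all-destructive shim: superposed field has zero mean")
    return float(mag.std() / mean)


def compute_efficiency(b1: B1MapSet, roi: np.ndarray, weights) -> float:
    """Transmit efficiency: ROI mean of the per-voxel constructive fraction
    |sum_ch B_ch b_ch| / sum_ch |B_ch b_ch|.  Equals 1 iff the channel fields
    are co-phased at every voxel."""
    w = weights.weights if isinstance(weights, ShimWeights) else np.asarray(weights)
    m = b1.roi_matrix(roi)
    num = np.abs(m @ w)
    den = (np.abs(m) * np.abs(w)[None, :]).sum(axis=1)
    ok = den > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"efficiency: excluded {n_excluded} zero-denominator voxels")
    if not ok.any():
        raise ValueError("efficiency undefined: zero field at every ROI voxel")
    return float((num[ok] / den[ok]).mean())


def zero_phase_weights(b1: B1MapSet, power_norm: float = 1.0) -> ShimWeights:
    """Equal magnitude, zero phase on all active channels — the baseline shim
    that exhibits destructive-interference dropouts."""
    w = b1.active_mask.astype(np.complex128)
    w *= np.sqrt(power_norm / (np.abs(w) ** 2).sum())
    return ShimWeights(w, "zero_phase", power_norm)


def _cost_and_grad(params, m, absm, mode, cost_weight):
    """cost = cv - cost_weight * eta and its gradient.

    ``params`` is phi (phase_only) or [log a; phi] (mag_phase), over active
    channels only.  ``m`` is the (V, C_active) map matrix at the voxels used
    for optimization, ``absm`` its magnitude.
    """
    c = m.shape[1]
    if mode == "mag_phase":
        loga, phi = params[:c], params[c:]
        a = np.exp(loga)
    else:
        phi = params
        a = np.ones(c)
    w = a * np.exp(1j * phi)

    s = m @ w  # (V,)
    mag = np.abs(s)
    mag = np.maximum(mag, 1e-300)
    u = s.conj() / mag
    g = u[:, None] * m * w[None, :]  # dmag/dphi = -Im g ; dmag/dloga = Re g

    v = mag.shape[0]
    mu = mag.mean()
    var = np.mean(mag**2) - mu**2
    sigma = np.sqrt(max(var, 0.0))
    cv = sigma / mu

    # d cv / d mag_i
    if sigma > 1e-14 * mu:
        dcv = (mag - mu) / (v * sigma * mu) - sigma / (v * mu**2)
    else:
        dcv = np.zeros(v)

    cost = cv
    t = dcv
    grad_extra_loga = None
    if cost_weight != 0.0:
        den = absm @ a
        ok = den > 0
        inv_den = np.where(ok, 1.0 / np.where(ok, den, 1.0), 0.0)
        eta = float(np.mean(np.where(ok, mag * inv_den, 0.0)))
        cost = cv - cost_weight * eta
        # d eta / d mag_i = 1/(V den_i)
        t = dcv - cost_weight * inv_den / v
        if mode == "mag_phase":
            # d eta / d log a_c through the denominator
            grad_extra_loga = cost_weight * np.einsum(
                "v,vc->c", mag * inv_den**2 / v, absm
            ) * a

    grad_phi = -np.einsum("v,vc->c", t, np.imag(g))
    if mode == "mag_phase":
        grad_loga = np.einsum("v,vc->c", t, np.real(g))
        if grad_extra_loga is not None:
            grad_loga += grad_extra_loga
        return cost, np.concatenate([grad_loga, grad_phi])
    return cost, grad_phi


def optimize_static_shim(
    b1: B1MapSet,
    roi: np.ndarray,
    mode: str = "phase_only",
    n_starts: int = 100,
    cost_weight: float = 0.0,
    seed: int = 0,
    power_norm: float = 1.0,
    init_weights: np.ndarray | None = None,
    max_voxels: int = 4000,
    maxiter: int = 200,
) -> tuple[ShimWeights, ShimMetrics]:
    """Best-of-starts minimization of ``cv - cost_weight * eta`` over the ROI.

    Start 0 is the zero-phase shim (equal amplitude, zero phase); remaining
    starts draw pseudo-random phases.  ``init_weights`` injects one extra
    start (e.g. seeding magnitude+phase with the phase-only solution, which
    guarantees the nested feasible set can only improve the cost).  If the
    ROI exceeds ``max_voxels`` a seeded voxel subsample is used inside the
    optimizer; reported metrics are always recomputed on the full ROI from
    the returned weights.  Deterministic for a fixed seed.
    """
    if mode not in ("phase_only", "mag_phase"):
        raise ValueError("mode must be 'phase_only' or 'mag_phase'")
    active = np.flatnonzero(b1.active_mask)
    if active.size < 2:
        raise ValueError("static shimming needs at least 2 active channels")

    rng = np.random.default_rng(seed)
    m_full = b1.roi_matrix(roi)[:, active]
    if m_full.shape[0] == 0:
        raise ValueError("empty ROI")
    if m_full.shape[0] > max_voxels:
        idx = rng.choice(m_full.shape[0], size=max_voxels, replace=False)
        m_opt = m_full[np.sort(idx)]
    else:
        m_opt = m_full
    absm = np.abs(m_opt)
    c = active.size

    starts: list[np.ndarray] = [np.zeros(c)]
    starts += [rng.uniform(-np.pi, np.pi, size=c) for _ in range(max(n_starts - 1, 0))]

    def pack(phases, mags=None):
        if mode == "mag_phase":
            logm = np.zeros(c) if mags is None else np.log(np.maximum(mags, 1e-12))
            return np.concatenate([logm, phases])
        return phases

    x0s = [pack(p) for p in starts]
    if init_weights is not None:
        w0 = np.asarray(init_weights, dtype=np.complex128)[active]
        mags = np.abs(w0)
        mags = mags / max(mags.mean(), 1e-300)
        x0s.append(pack(np.angle(w0), mags if mode == "mag_phase" else None))

    best = None
    diagnostics = []
    for i, x0 in enumerate(x0s):
        res = minimize(
            _cost_and_grad,
            x0,
            args=(m_opt, absm, mode, cost_weight),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        diagnostics.append((i, float(res.fun), bool(res.success)))
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(f"shim optimization failed on all starts: {diagnostics}")

    x = best[1]
    if mode == "mag_phase":
        a = np.exp(x[:c])
        phi = x[c:]
    else:
        a = np.ones(c)
        phi = x
    w_active = a * np.exp(1j * phi)
    # Canonical gauge: first active channel real-positive; common power.
    w_active = w_active * np.exp(-1j * np.angle(w_active[0]))
    w = np.zeros(b1.n_channels, dtype=np.complex128)
    w[active] = w_active
    w *= np.sqrt(power_norm / (np.abs(w) ** 2).sum())

    shim = ShimWeights(w, mode, power_norm)
    metrics = ShimMetrics(
        cv=compute_cv(b1, roi, shim),
        efficiency=compute_efficiency(b1, roi, shim),
        integrated_power=float((np.abs(w) ** 2).sum() * STATIC_PULSE_S),
    )
    return shim, metrics
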