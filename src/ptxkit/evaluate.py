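"""Flip-angle prediction, RF power / local SAR metrics, channel grouping,
and the comparative channel-count / kT-point analyses.

The fast predictor is the same small-tip model the design uses; the Bloch
oracle integrates rigid rotations at a 1 us raster and is the independent
check that the linearization is accurate at the 10 degree nominal flip.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ktpoints import (
    DEFAULT_SCALE_DEG,
    KTPulse,
    LCurve,
    SolveResult,
    SystemMatrix,
    _ridge_solve,
    shim_to_pulse,
    small_tip_fa,
    sweep_lcurve,
)
from .shim import ShimWeights, optimize_static_shim
from .synth import B1MapSet, VOPSet

__all__ = [
    "FAMap",
    "GroupingScheme",
    "predict_fa_smalltip",
    "bloch_oracle",
    "integrated_rf_power",
    "peak_local_sar",
    "group_channels",
    "default_grouping",
    "cv_at_power",
    "power_at_cv",
    "shim_power_at_fa",
    "check_channel_power",
    "solve_weights_sar",
    "compare_configurations",
]


@dataclasses.dataclass
class FAMap:
    """Flip-angle map (degrees) on the phantom grid, zero outside ``mask``."""

    fa_deg: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fa_deg < 0):
            raise ValueError("flip angles must be nonnegative")

    def roi_stats(self, roi: np.ndarray | None = None) -> dict:
        m = self.mask if roi is None else (self.mask & roi)
        vals = self.fa_deg[m]
        mean = float(vals.mean())
        std = float(vals.std())
        return {"mean": mean, "std": std, "cv": std / mean, "min": float(vals.min())}


@dataclasses.dataclass
class GroupingScheme:
    """Assignment of transmit elements to driven groups (zero intra-group
    phase), used to emulate 8/16/20-channel systems on the 32-element array."""

    mapping: np.ndarray  # group id per element, 0-based
    n_groups: int

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=int)
        if self.mapping.min() < 0 or self.mapping.max() >= self.n_groups:
            raise ValueError("group ids must lie in [0, n_groups)")
        counts = np.bincount(self.mapping, minlength=self.n_groups)
        if np.any(counts == 0):
            raise ValueError("every group must contain at least one element")


def default_grouping(n_groups: int, ring_sizes=(10, 12, 10)) -> GroupingScheme:
    """Ring-adjacent default groupings for 8/16/20/32 driven channels.

    Elements are numbered ring by ring.  16 channels pairs ring-adjacent
    elements (5/6/5 pairs); 8 channels splits the outer rings into two arcs
    of five and the inner ring into four arcs of three; 20 channels pairs the
    inner ring and part of each outer ring.  32 is the identity.  These are
    schematic, editable defaults.
    """
    n_el = int(sum(ring_sizes))
    offsets = np.cumsum([0] + list(ring_sizes))
    mapping = np.empty(n_el, dtype=int)
    if n_groups == n_el:
        mapping = np.arange(n_el)
    elif n_groups == 16:
        g = 0
        for r, size in enumerate(ring_sizes):
            for i in range(0, size, 2):
                mapping[offsets[r] + i] = g
                mapping[offsets[r] + min(i + 1, size - 1)] = g
                g += 1
    elif n_groups == 8:
        g = 0
        for r, size in enumerate(ring_sizes):
            arcs = 2 if size == 10 else 4
            per = size // arcs
            for a in range(arcs):
                for i in range(per):
                    mapping[offsets[r] + a * per + i] = g
                g += 1
    elif n_groups == 20:
        g = 0
        for r, size in enumerate(ring_sizes):
            if size == 12:  # inner ring: six pairs
                for i in range(0, size, 2):
                    mapping[offsets[r] + i] = g
                    mapping[offsets[r] + i + 1] = g
                    g += 1
            else:  # outer rings: three pairs + four singles
                for i in range(0, 6, 2):
                    mapping[offsets[r] + i] = g
                    mapping[offsets[r] + i + 1] = g
                    g += 1
                for i in range(6, size):
                    mapping[offsets[r] + i] = g
                    g += 1
    else:
        raise ValueError(f"no default grouping for {n_groups} groups")
    return GroupingScheme(mapping, n_groups)


def _as_pulse(pulse) -> KTPulse:
    if isinstance(pulse, KTPulse):
        return pulse
    if isinstance(pulse, ShimWeights):
        return shim_to_pulse(pulse)
    raise TypeError("expected a KTPulse or ShimWeights")


def predict_fa_smalltip(
    pulse,
    b1: B1MapSet,
    mask: np.ndarray | None = None,
    scale_deg: float | None = None,
) -> FAMap:
    """Small-tip flip-angle map over ``mask`` (default: the body)."""
    p = _as_pulse(pulse)
    scale = p.scale_deg if scale_deg is None else scale_deg
    if scale is None or scale <= 0:
        raise ValueError("flip-angle unit scale unset")
    m = b1.phantom.body_mask if mask is None else mask
    fa = np.zeros(b1.phantom.grid_shape)
    fa[m] = small_tip_fa(b1, m, p.k_locations, p.weights, p.subpulse_us, scale)
    return FAMap(fa, m)


def bloch_oracle(
    pulse,
    b1: B1MapSet,
    mask: np.ndarray | None = None,
    raster_us: int = 1,
    scale_deg: float | None = None,
    return_magnetization: bool = False,
):
    """Brute-force rigid-rotation flip-angle map (the validation oracle).

    Piecewise-constant RF is integrated at ``raster_us`` steps; gradient
    blips act as instantaneous z-rotations by (k_j - k_{j+1}) . r; off-
    resonance is zero.  The flip angle is the angle between the final and
    initial magnetization.  Independent of the small-tip linearization: at a
    90 degree flip it reproduces the sin(theta)/theta shortfall the linear
    model misses.
    """
    p = _as_pulse(pulse)
    scale = p.scale_deg if scale_deg is None else scale_deg
    if p.subpulse_us % raster_us != 0:
        raise ValueError("raster must divide the subpulse duration")
    if raster_us > p.subpulse_us:
        raise ValueError("raster longer than the shortest subpulse")
    m = b1.phantom.body_mask if mask is None else mask

    coords = b1.phantom.coordinates_m()[m]
    maps = b1.maps[:, m].T  # (V, C)
    v = coords.shape[0]
    mag = np.zeros((v, 3))
    mag[:, 2] = 1.0

    n_steps = p.subpulse_us // raster_us
    rad_per_unit_ms = np.deg2rad(scale)
    for j in range(p.n_kt):
        c = maps @ p.weights[:, j]  # complex effective field per voxel
        theta_step = rad_per_unit_ms * np.abs(c) * (raster_us / 1000.0)
        xi = np.angle(c)
        ux, uy = np.cos(xi), np.sin(xi)
        cos_t, sin_t = np.cos(theta_step), np.sin(theta_step)
        for _ in range(n_steps):
            x, y, z = mag[:, 0], mag[:, 1], mag[:, 2]
            udotv = ux * x + uy * y
            cx = uy * z
            cy = -ux * z
            cz = ux * y - uy * x
            mag = np.stack(
                [
                    x * cos_t + cx * sin_t + ux * udotv * (1 - cos_t),
                    y * cos_t + cy * sin_t + uy * udotv * (1 - cos_t),
                    z * cos_t + cz * sin_t,
                ],
                axis=1,
            )
        if j < p.n_kt - 1:
            alpha = coords @ (p.k_locations[j] - p.k_locations[j + 1])
            ca_, sa_ = np.cos(alpha), np.sin(alpha)
            x, y = mag[:, 0].copy(), mag[:, 1].copy()
            mag[:, 0] = x * ca_ - y * sa_
            mag[:, 1] = x * sa_ + y * ca_

    fa = np.zeros(b1.phantom.grid_shape)
    fa[m] = np.degrees(np.arccos(np.clip(mag[:, 2], -1.0, 1.0)))
    out = FAMap(fa, m)
    if return_magnetization:
        return out, mag
    return out


def integrated_rf_power(pulse) -> float:
    """sum_ch sum_j |b_ch,j|^2 * tau_j in relative units * seconds.

    Gradient blips carry no RF and contribute nothing; the metric is
    invariant under a global phase rotation of the weights.
    """
    p = _as_pulse(pulse)
    return float((np.abs(p.weights) ** 2).sum() * p.subpulse_us * 1e-6)


def peak_local_sar(pulse, vops: VOPSet, duty_cycle: float = 1.0) -> float:
    """Relative peak local SAR: max over VOPs of the subpulse-duration-
    weighted time average of b_j^H Q b_j, scaled by the duty cycle."""
    p = _as_pulse(pulse)
    if vops.n_channels != p.n_channels:
        raise ValueError("VOP channel count does not match the pulse")
    w = p.weights  # (C, K), equal subpulse durations
    q = np.einsum("vab,ak,bk->v", vops.matrices, w.conj(), w).real / p.n_kt
    return float(q.max() * duty_cycle)


def group_channels(b1: B1MapSet, scheme: GroupingScheme) -> B1MapSet:
    """Drive element groups with identical phase: the group map is the exact
    complex sum of its (active) members, and group power budgets are the sum
    of member budgets so total available RF power stays constant."""
    if scheme.mapping.size != b1.n_channels:
        raise ValueError("scheme must assign every element")
    maps = np.zeros((scheme.n_groups,) + tuple(b1.phantom.grid_shape), dtype=np.complex128)
    budget = np.zeros(scheme.n_groups)
    active = np.zeros(scheme.n_groups, dtype=bool)
    for g in range(scheme.n_groups):
        members = np.flatnonzero((scheme.mapping == g) & b1.active_mask)
        if members.size == 0:
            raise ValueError(f"group {g} is empty after dead-channel removal")
        maps[g] = b1.maps[members].sum(axis=0)
        budget[g] = np.asarray(b1.power_budget)[members].sum()
        active[g] = True
    return B1MapSet(maps, b1.phantom, active, budget)


def cv_at_power(lcurve: LCurve, power: float) -> float:
    """Interpolate the L-curve CV at a given integrated RF power."""
    order = np.argsort(lcurve.power)
    p = lcurve.power[order]
    c = lcurve.cv[order]
    return float(np.interp(np.log(power), np.log(p), c))


def power_at_cv(lcurve: LCurve, cv: float) -> float:
    """Interpolate the L-curve integrated power at a given CV."""
    order = np.argsort(lcurve.cv)
    c = lcurve.cv[order]
    p = lcurve.power[order]
    return float(np.exp(np.interp(cv, c, np.log(p))))


def shim_power_at_fa(
    b1: B1MapSet, roi: np.ndarray, shim: ShimWeights, target_fa_deg: float = 10.0,
    scale_deg: float = DEFAULT_SCALE_DEG,
) -> float:
    """Integrated RF power of a static shim rescaled to hit the nominal mean
    flip angle in the ROI — the reference power used when comparing
    configurations ("same RF power as for phase shimming")."""
    fa = small_tip_fa(b1, roi, np.zeros((1, 3)), shim.weights.reshape(-1, 1),
                      1000.0, scale_deg)
    s = target_fa_deg / fa.mean()
    return float((s**2) * (np.abs(shim.weights) ** 2).sum() * 1e-3)


def check_channel_power(
    pulse,
    tr_s: float,
    watts_per_unit: float = 1.0,
    limit_w_10s: float = 6.6,
    limit_w_6min: float = 3.3,
):
    """Per-channel average-power compliance check.

    Converts the pulse energy per repetition to a per-channel average power
    at repetition time ``tr_s`` and compares against the short- and long-
    window limits (defaults mirror a 6.6 W / 10 s and 3.3 W / 6 min
    supervision policy, in watts per relative power unit).
    """
    import pandas as pd

    p = _as_pulse(pulse)
    energy = (np.abs(p.weights) ** 2).sum(axis=1) * p.subpulse_us * 1e-6
    avg_w = energy / tr_s * watts_per_unit
    return pd.DataFrame(
        {
            "channel": np.arange(1, p.n_channels + 1),
            "avg_power_w": avg_w,
            "ok_10s": avg_w <= limit_w_10s,
            "ok_6min": avg_w <= limit_w_6min,
        }
    )


def solve_weights_sar(
    a_mat: SystemMatrix,
    target_fa_deg: float,
    sar_weight: float,
    vops: VOPSet,
    smoothing: float = 20.0,
    max_iter: int = 30,
    tol: float = 1e-8,
) -> SolveResult:
    """Magnitude least squares with a peak-local-SAR penalty.

    Replaces the Tikhonov term by sar_weight * softmax-weighted combination
    of the VOP quadratic forms (a log-sum-exp smoothing of max_v b^H Q_v b),
    re-weighted from the current iterate each outer step, inside the usual
    variable-exchange loop.
    """
    a = a_mat.a
    v, n = a.shape
    ca = a_mat.active_channels.size
    k = a_mat.n_kt
    qs = vops.matrices[:, a_mat.active_channels][:, :, a_mat.active_channels]
    m_d = float(target_fa_deg) * np.ones(v)
    g = a.conj().T @ a
    theta = np.angle(a @ (np.ones(n) / np.sqrt(n)))
    s = np.ones(vops.count) / vops.count
    b = np.zeros(n, dtype=np.complex128)
    trace: list[float] = []
    for _ in range(max_iter):
        qbar = np.tensordot(s, qs, axes=1)  # (Ca, Ca)
        penalty = np.kron(np.eye(k), qbar)
        rhs = a.conj().T @ (m_d * np.exp(1j * theta))
        b_new = _ridge_solve(g + sar_weight * penalty, 0.0, rhs)
        z = a @ b_new
        theta = np.angle(z)
        bm = b_new.reshape(k, ca)
        qvals = np.einsum("vab,ka,kb->v", qs, bm.conj(), bm).real / k
        x = smoothing * (qvals - qvals.max())
        s = np.exp(x)
        s /= s.sum()
        obj = 0.5 * np.sum((m_d - np.abs(z)) ** 2) + 0.5 * sar_weight * float(
            (s * qvals).sum()
        )
        trace.append(float(obj))
        if np.linalg.norm(b_new - b) < tol * max(np.linalg.norm(b_new), 1e-300):
            b = b_new
            break
        b = b_new
    residual = float(np.linalg.norm(m_d - np.abs(a @ b)))
    return SolveResult(weights=b, objective_trace=trace, theta=theta, residual=residual)


def compare_configurations(
    b1: B1MapSet,
    roi: np.ndarray,
    n_kt_list,
    schemes,
    beta_grid=None,
    seed: int = 0,
    reference_power: float | None = None,
    target_fa_deg: float = 10.0,
    **design_kwargs,
) -> dict:
    """Full factorial of L-curves over channel groupings and kT-point counts.

    ``schemes`` maps a label (e.g. ``"32ch"``) to a GroupingScheme or to an
    integer group count (resolved with :func:`default_grouping`).  The
    summary table reports each configuration's CV interpolated at the
    reference power (default: the power a full-array phase shim needs to hit
    the nominal flip angle), pairwise CV improvement factors at that power,
    and power ratios at the matched reference CV.
    """
    import pandas as pd

    if not n_kt_list or not schemes:
        raise ValueError("need at least one n_kt and one scheme")

    if reference_power is None:
        shim, _ = optimize_static_shim(
            b1, roi, mode="phase_only", n_starts=8, seed=seed
        )
        reference_power = shim_power_at_fa(b1, roi, shim, target_fa_deg)

    lcurves: dict = {}
    rows = []
    for label, scheme in schemes.items():
        if isinstance(scheme, int):
            scheme = default_grouping(scheme)
        grouped = b1 if scheme.n_groups == b1.n_channels else group_channels(b1, scheme)
        for n_kt in n_kt_list:
            lc = sweep_lcurve(
                grouped, roi, n_kt, beta_grid=beta_grid, seed=seed,
                target_fa_deg=target_fa_deg, **design_kwargs,
            )
            lcurves[(label, n_kt)] = lc
            rows.append(
                {
                    "scheme": label,
                    "n_kt": n_kt,
                    "cv_at_ref_power": cv_at_power(lc, reference_power),
                    "min_cv": float(lc.cv.min()),
                }
            )
    summary = pd.DataFrame(rows)

    improvements = []
    for n_kt in n_kt_list:
        sub = summary[summary.n_kt == n_kt].set_index("scheme")["cv_at_ref_power"]
        for a_label in sub.index:
            for b_label in sub.index:
                improvements.append(
                    {
                        "n_kt": n_kt,
                        "scheme_from": a_label,
                        "scheme_to": b_label,
                        "cv_improvement_factor": float(sub[a_label] / sub[b_label]),
                    }
                )
    ref_cv = None
    power_rows = []
    for (label, n_kt), lc in lcurves.items():
        if ref_cv is None:
            ref_cv = float(np.median(summary["cv_at_ref_power"]))
        power_rows.append(
            {
                "scheme": label,
                "n_kt": n_kt,
                "power_at_ref_cv": power_at_cv(lc, ref_cv),
            }
        )
    return {
        "lcurves": lcurves,
        "summary": summary,
        "improvement_factors": pd.DataFrame(improvements),
        "power_at_matched_cv": pd.DataFrame(power_rows),
        "reference_power": float(reference_power),
    }
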