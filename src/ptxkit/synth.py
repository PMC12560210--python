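"""Synthetic phantoms, transmit-array field maps, calibration stacks and VOPs.

Everything downstream (relative-map estimation, static shimming, kT-point
design, SAR evaluation) is exercised on data produced here.  The field model
is geometric decay plus a complex propagation phase, not a full-wave EM
simulation: it reproduces the interference structure that matters for the
analysis — RF-wavelength-scale phase variation across the torso, destructive
zero-phase dropouts in a liver-like ROI, and the benefit of many independent
transmit channels — while staying desk-scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "Phantom",
    "B1MapSet",
    "CalibrationStack",
    "VOPSet",
    "RingSpec",
    "generate_phantom",
    "generate_b1_maps",
    "apply_channel_failures",
    "default_receive_profile",
    "simulate_calibration_stack",
    "generate_vops",
]

#: Dead transmit elements observed on the 32-channel system (1-based).
DEFAULT_DEAD_CHANNELS = (11, 20, 24, 32)


@dataclasses.dataclass(frozen=True)
class Phantom:
    """Voxelized body with a liver-like region of interest.

    Coordinates are isocenter-origin, right-handed, in meters; voxel centers
    lie on the grid.  The body is an elliptic cylinder (transversal ellipse
    extruded along z), the ROI an ellipsoid offset toward the subject's right,
    standing in for a manually drawn liver ROI.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    body_mask: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel_size_mm must be positive")
        if not self.roi_mask.any():
            raise ValueError("empty ROI")
        if np.any(self.roi_mask & ~self.body_mask):
            raise ValueError("roi_mask must be contained in body_mask")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def coordinates_m(self) -> np.ndarray:
        """Voxel-center coordinates, shape ``grid_shape + (3,)``, meters."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * (vs * 1e-3)
            for n, vs in zip(self.grid_shape, self.voxel_size_mm)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


@dataclasses.dataclass
class B1MapSet:
    """Channel-wise complex transmit sensitivities on the phantom grid.

    ``maps`` has shape ``(n_channels,) + grid_shape`` in relative units.
    Channels flagged inactive are identically zero.  ``power_budget`` carries
    the per-channel available RF power in relative units; grouping channels
    sums the budgets so total available power is conserved.
    """

    maps: np.ndarray
    phantom: Phantom
    active_mask: np.ndarray
    power_budget: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.maps.shape[0] != self.active_mask.shape[0]:
            raise ValueError("active_mask length must match channel count")
        if self.maps.shape[1:] != tuple(self.phantom.grid_shape):
            raise ValueError("maps must share the phantom grid")
        if self.power_budget is None:
            self.power_budget = np.ones(self.maps.shape[0])

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def roi_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Maps sampled at masked voxels, shape (n_voxels, n_channels)."""
        m = self.phantom.roi_mask if mask is None else mask
        return self.maps[:, m].T.copy()


@dataclasses.dataclass
class CalibrationStack:
    """Small-flip-angle GRE image series used for relative B1+ mapping.

    ``scheme`` orders the measurements: ``all_on`` (every channel at equal
    magnitude, zero phase), ``all_off`` (noise only), then one image per
    single transmitting channel — n_channels + 2 images in total.
    """

    images: np.ndarray  # (n_measurements,) + grid_shape, complex
    scheme: tuple[str, ...]
    noise_sigma: float
    receive_profile: np.ndarray
    phantom: Phantom

    def __post_init__(self) -> None:
        if len(self.scheme) != self.images.shape[0]:
            raise ValueError("scheme length must match image count")
        expected = ["all_on", "all_off"] + [
            f"ch_{i}" for i in range(1, len(self.scheme) - 1)
        ]
        if list(self.scheme) != expected:
            raise ValueError("scheme must be all_on, all_off, ch_1..ch_N in order")

    @property
    def n_channels(self) -> int:
        return len(self.scheme) - 2

    def image(self, label: str) -> np.ndarray:
        return self.images[self.scheme.index(label)]


@dataclasses.dataclass
class VOPSet:
    """Virtual observation points: Hermitian PSD channel-space matrices.

    The relative peak local SAR of a weight vector b is max_v b^H Q_v b.
    """

    matrices: np.ndarray  # (n_vops, n_channels, n_channels)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.complex128)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_vops, C, C)")

    @property
    def count(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def validate(self, herm_tol: float = 1e-12, eig_tol: float = -1e-10) -> None:
        for q in self.matrices:
            if np.linalg.norm(q - q.conj().T) > herm_tol * max(np.linalg.norm(q), 1e-300):
                raise ValueError("VOP matrix not Hermitian within tolerance")
            if np.linalg.eigvalsh(q).min() < eig_tol:
                raise ValueError("VOP matrix not PSD within tolerance")


@dataclasses.dataclass(frozen=True)
class RingSpec:
    """Element layout of a remote cylindrical transmit array.

    Defaults give three rings of 10/12/10 elements at a bore-scale radius,
    i.e. a remote whole-body array rather than a local surface array.
    """

    elements_per_ring: tuple[int, ...] = (10, 12, 10)
    ring_z_mm: tuple[float, ...] = (-110.0, 0.0, 110.0)
    radius_mm: float = 320.0

    @property
    def n_elements(self) -> int:
        return int(sum(self.elements_per_ring))

    def element_positions_m(self) -> np.ndarray:
        """Element center positions, shape (n_elements, 3), meters."""
        pos = []
        for n_el, z in zip(self.elements_per_ring, self.ring_z_mm):
            ang = 2.0 * np.pi * np.arange(n_el) / n_el
            r = self.radius_mm * 1e-3
            for a in ang:
                pos.append((r * np.cos(a), r * np.sin(a), z * 1e-3))
        return np.asarray(pos)


def generate_phantom(
    grid_shape=(48, 48, 40),
    voxel_size_mm=(4.0, 4.0, 4.0),
    body_semiaxes_mm=(80.0, 60.0),
    roi_spec=None,
    seed: int = 0,
) -> Phantom:
    """Build an elliptic-cylinder body with a right-offset ellipsoidal ROI.

    Parameters
    ----------
    grid_shape, voxel_size_mm
        Voxel grid; the default 48x48x40 at 4 mm isotropic matches the
        relative-mapping resolution used throughout.
    body_semiaxes_mm
        Transversal (x, y) semiaxes of the body ellipse.
    roi_spec
        Mapping with ``semiaxes_mm`` (3-vector) and ``center_mm`` (3-vector)
        of the liver-like ROI ellipsoid.  Defaults emulate a liver volume of
        roughly 0.4 L offset to the subject's right.  The ROI center is
        jittered by up to +-3 mm per axis (seeded) to emulate subject-to-
        subject variability.
    seed
        Seeds the ROI-center jitter only; masks are otherwise analytic.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if roi_spec is None:
        roi_spec = {"semiaxes_mm": (38.0, 42.0, 55.0), "center_mm": (35.0, 0.0, 0.0)}
    semi = np.asarray(roi_spec["semiaxes_mm"], dtype=float)
    center = np.asarray(roi_spec["center_mm"], dtype=float)
    if np.any(semi <= 0):
        raise ValueError("empty ROI: all roi semiaxes must be positive")

    rng = np.random.default_rng(seed)
    center = center + rng.uniform(-3.0, 3.0, size=3)

    ax, ay = float(body_semiaxes_mm[0]), float(body_semiaxes_mm[1])
    # Conservative axis-aligned containment check (names the offending axis).
    names = "xyz"
    body_half = (ax, ay, grid_shape[2] * voxel_size_mm[2] / 2.0)
    for i in range(3):
        if abs(center[i]) + semi[i] > body_half[i] + 1e-9:
            raise ValueError(
                f"ROI outside body: semiaxis {names[i]}={semi[i]:.1f} mm at "
                f"center {center[i]:.1f} mm exceeds body half-extent "
                f"{body_half[i]:.1f} mm"
            )

    axes = [
        (np.arange(n) - (n - 1) / 2.0) * vs
        for n, vs in zip(grid_shape, voxel_size_mm)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    body = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    roi = (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
        <= 1.0
    )
    roi &= body
    phantom = Phantom(grid_shape, voxel_size_mm, body, roi)

    requested = 4.0 / 3.0 * np.pi * float(np.prod(semi))
    got = roi.sum() * phantom.voxel_volume_mm3
    if abs(got - requested) > 0.10 * requested:
        raise ValueError(
            f"ROI voxel volume {got:.0f} mm^3 deviates >10% from requested "
            f"{requested:.0f} mm^3; refine the grid or shrink the ROI"
        )
    return phantom


def generate_b1_maps(
    phantom: Phantom,
    ring_spec: RingSpec | None = None,
    rf_wavelength_mm: float = 130.0,
    attenuation_mm: float = 220.0,
    decay_exponent: float = 1.0,
    phase_jitter_rad: float = 1.0,
    roughness: float = 0.7,
    roughness_corr_mm: float = 15.0,
    seed: int = 0,
    normalize: bool = True,
) -> B1MapSet:
    """Synthesize channel-wise complex B1+ maps for a remote ring array.

    Each element e at position ``p_e`` contributes, at voxel position r,

        map_e(r) = A * d^(-decay_exponent) * exp(-d / attenuation)
                   * exp(-i * 2*pi * d / rf_wavelength + i * phi_e)
                   * s_e(r)

    with d = |r - p_e|.  The default in-tissue wavelength of ~130 mm
    (proton Larmor frequency at 7 T) makes the phase wind by several cycles
    across the torso, so the equal-magnitude zero-phase combination shows
    destructive-interference dropouts inside the ROI — the baseline behavior
    static shimming is meant to repair.  ``phi_e`` is a seeded per-element
    phase offset (cable/feed variation).

    ``s_e(r) = exp(roughness * (g_re + i g_im))`` is a per-element smooth
    complex modulation (seeded Gaussian fields with ``roughness_corr_mm``
    correlation length) emulating the scattering / standing-wave structure
    that makes measured in-tissue maps differ between elements on the
    half-wavelength scale.  Without it the element fields are so regular
    that a static shim co-phases them almost perfectly everywhere, which
    measured torso maps do not allow; ``roughness=0`` recovers the smooth
    limit.

    With ``normalize`` the whole set is scaled by one common factor so the
    root-sum-of-squares over the ROI has median 1 (relative units).
    """
    if rf_wavelength_mm <= 0:
        raise ValueError("rf_wavelength_mm must be positive")
    ring_spec = ring_spec or RingSpec()
    if ring_spec.n_elements < 2:
        raise ValueError("need at least 2 array elements")

    rng = np.random.default_rng(seed)
    phi = rng.uniform(-np.pi, np.pi, size=ring_spec.n_elements) * phase_jitter_rad

    coords = phantom.coordinates_m()  # (nx, ny, nz, 3)
    pos = ring_spec.element_positions_m()
    wavelength = rf_wavelength_mm * 1e-3
    atten = attenuation_mm * 1e-3

    sigma_vox = None
    if roughness > 0:
        from scipy.ndimage import gaussian_filter

        sigma_vox = tuple(
            roughness_corr_mm / vs for vs in phantom.voxel_size_mm
        )

    maps = np.empty((ring_spec.n_elements,) + tuple(phantom.grid_shape), dtype=np.complex128)
    for e in range(ring_spec.n_elements):
        d = np.linalg.norm(coords - pos[e], axis=-1)
        amp = d ** (-decay_exponent) * np.exp(-d / atten) if atten < np.inf else d ** (-decay_exponent)
        maps[e] = amp * np.exp(1j * (-2.0 * np.pi * d / wavelength + phi[e]))
        if sigma_vox is not None:
            from scipy.ndimage import gaussian_filter

            g = rng.normal(size=phantom.grid_shape + (2,))
            g_re = gaussian_filter(g[..., 0], sigma_vox)
            g_im = gaussian_filter(g[..., 1], sigma_vox)
            # renormalize filtered fields to unit variance
            g_re /= max(g_re.std(), 1e-12)
            g_im /= max(g_im.std(), 1e-12)
            maps[e] *= np.exp(roughness * (g_re + 1j * g_im))

    if normalize:
        rsos = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        scale = np.median(rsos[phantom.roi_mask])
        maps /= scale

    return B1MapSet(maps, phantom, np.ones(ring_spec.n_elements, dtype=bool))


def apply_channel_failures(b1: B1MapSet, channels) -> B1MapSet:
    """Zero out failed transmit channels (1-based indices, as on the scanner).

    Returns a new set; unaffected channels are bit-identical.  Failing all
    channels is an error.
    """
    channels = sorted(set(int(c) for c in channels))
    for c in channels:
        if not 1 <= c <= b1.n_channels:
            raise ValueError(f"channel index {c} out of range 1..{b1.n_channels}")
    maps = b1.maps.copy()
    active = b1.active_mask.copy()
    for c in channels:
        maps[c - 1] = 0.0
        active[c - 1] = False
    if not active.any():
        raise ValueError("no active channels remain after failures")
    return B1MapSet(maps, b1.phantom, active, np.array(b1.power_budget, copy=True))


def default_receive_profile(phantom: Phantom) -> np.ndarray:
    """Smooth positive receive sensitivity (anterior/posterior array flavor)."""
    coords = phantom.coordinates_m()
    y = coords[..., 1]
    extent = max(phantom.grid_shape[1] * phantom.voxel_size_mm[1] * 1e-3 / 2.0, 1e-6)
    # Two broad lobes from front and back receive arrays.
    prof = 0.4 + np.exp(-((y - extent) ** 2) / (2 * (0.6 * extent) ** 2)) + np.exp(
        -((y + extent) ** 2) / (2 * (0.6 * extent) ** 2)
    )
    return prof


def simulate_calibration_stack(
    b1: B1MapSet,
    receive_profile: np.ndarray | None = None,
    flip_scale: float = 0.087,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CalibrationStack:
    """Forward-simulate the (n_channels + 2)-measurement relative-mapping scan.

    Measurement order: all channels on at equal magnitude and zero phase,
    all channels off, then one image per single transmitting channel.  Each
    image is

        I(r) = receive(r) * sin(flip_scale * |B(r)|) * exp(i * arg B(r)) + n(r)

    where B is the relevant complex field superposition and n is complex
    Gaussian noise with standard deviation ``noise_sigma`` per real/imaginary
    component.  ``flip_scale`` is radians of flip per relative field unit;
    the default puts the all-on ROI-median flip near 5 deg, well inside the
    small-flip-angle regime where the single-channel images add linearly.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if receive_profile is None:
        receive_profile = default_receive_profile(b1.phantom)
    receive_profile = np.asarray(receive_profile, dtype=float)
    if receive_profile.shape != tuple(b1.phantom.grid_shape):
        raise ValueError("receive_profile must live on the phantom grid")

    all_on = b1.maps.sum(axis=0)
    fields = [all_on, np.zeros_like(all_on)] + [b1.maps[c] for c in range(b1.n_channels)]

    peak_alpha = flip_scale * max(np.abs(all_on)[b1.phantom.body_mask].max(), 1e-300)
    if abs(np.sin(peak_alpha) - peak_alpha) > 0.01 * peak_alpha:
        raise ValueError(
            f"flip_scale too large: peak flip {np.degrees(peak_alpha):.1f} deg "
            "violates the small-flip-angle regime (sin(a) ~ a within 1%)"
        )

    rng = np.random.default_rng(seed)
    shape = (len(fields),) + tuple(b1.phantom.grid_shape)
    images = np.empty(shape, dtype=np.complex128)
    for m, field in enumerate(fields):
        mag = np.abs(field)
        signal = receive_profile * np.sin(flip_scale * mag) * np.exp(1j * np.angle(field))
        signal = np.where(mag > 0, signal, 0.0)
        images[m] = signal
    if noise_sigma > 0:
        noise = rng.normal(scale=noise_sigma, size=shape + (2,))
        images = images + noise[..., 0] + 1j * noise[..., 1]

    scheme = tuple(["all_on", "all_off"] + [f"ch_{i}" for i in range(1, b1.n_channels + 1)])
    return CalibrationStack(images, scheme, float(noise_sigma), receive_profile, b1.phantom)


def generate_vops(n_channels: int, n_vops: int, rank: int = 3, seed: int = 0) -> VOPSet:
    """Random Hermitian PSD VOP matrices standing in for EM-derived ones.

    Each Q_v = sum_k e_k e_k^H from ``rank`` random complex vectors, then
    scaled so the median of b^H Q_v b over random unit-norm b equals 1, so
    relative SAR values across configurations are on a common scale.
    """
    if n_vops < 1:
        raise ValueError("n_vops must be >= 1")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    mats = np.empty((n_vops, n_channels, n_channels), dtype=np.complex128)
    probes = rng.normal(size=(256, n_channels, 2))
    probes = probes[..., 0] + 1j * probes[..., 1]
    probes /= np.linalg.norm(probes, axis=1, keepdims=True)
    for v in range(n_vops):
        e = rng.normal(size=(rank, n_channels, 2))
        e = e[..., 0] + 1j * e[..., 1]
        q = e.conj().T @ e  # sum_k e_k e_k^H
        q = 0.5 * (q + q.conj().T)  # exact hermitization against roundoff
        vals = np.einsum("bi,ij,bj->b", probes.conj(), q, probes).real
        med = np.median(vals)
        if med <= 0:
            warnings.warn("degenerate VOP scaling; leaving matrix unscaled")
        else:
            q = q / med
        mats[v] = q
    return VOPSet(mats)
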