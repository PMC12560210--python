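"""Relative channel-wise B1+ map estimation from a calibration stack.

The estimator forms, per voxel, the ratio of each single-channel image to the
sum of all single-channel images.  Any common multiplicative factor — in
particular the unknown receive profile, which every measurement shares —
cancels exactly, which is what makes relative mapping feasible without a
separate receive calibration.  The price is that maps are *relative*: they
carry the spatial shape and inter-channel phases/magnitudes but no absolute
scale, which is all the shim/pulse optimizations need.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synth import B1MapSet, CalibrationStack, Phantom

__all__ = [
    "RelativeB1MapSet",
    "estimate_relative_maps",
    "rsos_map",
    "flag_dead_channels",
    "rsos_basis",
]


@dataclasses.dataclass
class RelativeB1MapSet(B1MapSet):
    """Relative maps plus the validity bookkeeping of the ratio estimator.

    At every valid voxel the maps sum to 1 + 0i by construction (each map is
    a share of the channel sum).  ``validity_mask`` is False where the
    denominator magnitude is below the noise floor, i.e. where the ratio is
    dominated by noise.
    """

    reference_label: str = "channel_sum"
    validity_mask: np.ndarray | None = None
    #: expected per-component noise std of the ratio (sigma_hat / |denominator|)
    ratio_noise_level: float | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.phantom.grid_shape, dtype=bool)


def estimate_relative_maps(
    stack: CalibrationStack,
    noise_floor_factor: float = 3.0,
    smooth_sigma_vox: float = 0.0,
) -> RelativeB1MapSet:
    """Estimate relative maps as per-channel shares of the channel sum.

        map_ch(r) = (I_ch(r) - bias) / sum_ch' (I_ch'(r) - bias)

    ``bias`` is the complex spatial mean of the all-off image: for zero-mean
    noise it is ~0, and it removes any DC offset the chain might add; for a
    noiseless stack it is exactly 0, so the ratio is invariant (to rounding)
    under multiplication of every image by any common nonzero complex
    profile.  Voxels where |denominator| < noise_floor_factor *
    sigma_hat(I_off) are flagged invalid and set to zero.

    ``smooth_sigma_vox`` applies an isotropic complex Gaussian pre-filter to
    every image before the ratio.  B1+ fields vary on the RF-wavelength
    scale, coarser than the mapping grid, so ~0.6 voxels suppresses
    noise where the channel sum interferes destructively at negligible bias;
    the default 0 keeps the ratio exact.
    """
    n_ch = stack.n_channels
    if n_ch < 1:
        raise ValueError("stack contains no single-channel measurements")

    off = stack.image("all_off")
    bias = complex(off.mean())
    # Per-component noise std from the all-off image.
    resid = off - bias
    sigma_hat = float(np.sqrt(0.5 * np.mean(np.abs(resid) ** 2)))

    singles = np.stack([stack.image(f"ch_{i}") for i in range(1, n_ch + 1)]) - bias
    if smooth_sigma_vox > 0:
        from scipy.ndimage import gaussian_filter

        sig = (smooth_sigma_vox,) * 3
        singles = np.stack(
            [
                gaussian_filter(s.real, sig) + 1j * gaussian_filter(s.imag, sig)
                for s in singles
            ]
        )
        # smoothing averages noise down accordingly
        sigma_hat *= 1.0 / max((2 * np.sqrt(np.pi) * smooth_sigma_vox) ** 1.5, 1.0)
    denom = singles.sum(axis=0)
    valid = np.abs(denom) >= noise_floor_factor * sigma_hat
    if not valid.any():
        raise ValueError("all voxels fall below the noise floor")

    maps = np.zeros_like(singles)
    np.divide(singles, denom[None], out=maps, where=valid[None])

    ratio_noise = sigma_hat / max(float(np.median(np.abs(denom[valid]))), 1e-300)
    return RelativeB1MapSet(
        maps=maps,
        phantom=stack.phantom,
        active_mask=np.ones(n_ch, dtype=bool),
        reference_label="channel_sum",
        validity_mask=valid,
        ratio_noise_level=ratio_noise,
    )


def rsos_map(data) -> np.ndarray:
    """Root sum of squares over channels; the anatomical reference image.

    Accepts a ``B1MapSet``, a ``CalibrationStack`` (its single-channel
    images), or a plain complex array with channels on axis 0.
    """
    if isinstance(data, B1MapSet):
        arr = data.maps
    elif isinstance(data, CalibrationStack):
        arr = data.images[2:]
    else:
        arr = np.asarray(data)
    if arr.ndim < 1 or arr.shape[0] == 0:
        raise ValueError("rsos_map needs at least one channel")
    return np.sqrt((np.abs(arr) ** 2).sum(axis=0))


def flag_dead_channels(
    maps: RelativeB1MapSet,
    roi: np.ndarray | None = None,
    noise_floor_factor: float = 3.0,
    rel_threshold: float = 0.1,
) -> RelativeB1MapSet:
    """Mark channels whose relative maps are indistinguishable from the ratio
    noise floor as inactive (how unstable elements are detected).

    A transmitting channel contributes a share of the channel sum well above
    the noise; a dead channel's "map" is pure noise over the denominator,
    with ROI-median magnitude ~1.18 * ratio_noise_level.  The threshold is
    ``noise_floor_factor`` times that level when the estimator recorded it,
    falling back to ``rel_threshold`` of the cross-channel median otherwise.
    """
    mask = maps.phantom.roi_mask if roi is None else roi
    mask = mask & maps.validity_mask
    if not mask.any():
        raise ValueError("no valid ROI voxels for dead-channel detection")
    med = np.array([np.median(np.abs(maps.maps[c][mask])) for c in range(maps.n_channels)])
    if maps.ratio_noise_level is not None and maps.ratio_noise_level > 0:
        threshold = noise_floor_factor * maps.ratio_noise_level
    else:
        threshold = rel_threshold * np.median(med)
    active = med >= threshold
    if not active.any():
        raise ValueError("dead-channel detection flagged every channel")
    out_maps = maps.maps.copy()
    out_maps[~active] = 0.0
    return RelativeB1MapSet(
        maps=out_maps,
        phantom=maps.phantom,
        active_mask=active,
        power_budget=np.array(maps.power_budget, copy=True),
        reference_label=maps.reference_label,
        validity_mask=maps.validity_mask.copy(),
        ratio_noise_level=maps.ratio_noise_level,
    )


def rsos_basis(maps: B1MapSet) -> B1MapSet:
    """Re-express maps with the per-voxel root-sum-of-squares as reference.

    Sum-normalized relative maps satisfy sum_ch map_ch = 1 everywhere, so
    their equal-weight combination is flat *by construction* and shimming on
    them directly would homogenize the wrong quantity (the true field is
    map_ch times the structured, dropout-carrying channel sum).  Dividing
    each channel by the pointwise RSoS instead — a pure change of reference,
    no new unknowns — yields B_ch / RSoS(B), whose denominator is smooth and
    interference-free, so all relative interference structure survives.
    This is the basis the shim and pulse designs consume.
    """
    rs = rsos_map(maps)
    ok = rs > 0
    out = np.zeros_like(maps.maps)
    np.divide(maps.maps, np.where(ok, rs, 1.0)[None], out=out, where=ok[None])
    if isinstance(maps, RelativeB1MapSet):
        return RelativeB1MapSet(
            maps=out,
            phantom=maps.phantom,
            active_mask=maps.active_mask.copy(),
            power_budget=np.array(maps.power_budget, copy=True),
            reference_label="rsos",
            validity_mask=maps.validity_mask & ok,
            ratio_noise_level=maps.ratio_noise_level,
        )
    return B1MapSet(out, maps.phantom, maps.active_mask.copy(),
                    np.array(maps.power_budget, copy=True))
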