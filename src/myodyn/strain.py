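"""Strain-tensor pipeline for phase-contrast velocity data.

The chain implemented here turns a cine series of three-directional tissue
velocities (one stimulation cycle of an electrically evoked calf
contraction) into principal-strain maps:

1. temporal integration of velocity into a voxelwise displacement field,
   with a forward/backward blend that pins the displacement to zero at the
   start and end of the cycle and exactly nulls any constant velocity
   offset (eddy-current-like drift);
2. spatial differentiation of the displacement with a separable 3-D
   Savitzky-Golay derivative filter (local least-squares polynomial fit,
   noise-robust);
3. algebraic assembly of the strain tensor, Green-Lagrange by default
   (E = 1/2 (F^T F - I), F = I + grad u), invariant under rigid rotation;
4. eigendecomposition; the largest positive eigenvalue is the "first
   positive eigenvalue" map, interpreted as the maximal local lengthening;
5. ROI averaging over a labelled muscle restricted to the axial span
   between the two stimulation-electrode centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io import RoiMask, VelocitySeries

__all__ = [
    "DisplacementSeries",
    "StrainTensorSeries",
    "PrincipalStrainSeries",
    "StrainCurve",
    "integrate_velocity",
    "spatial_gradient_sg",
    "strain_tensor",
    "principal_strains",
    "roi_strain_curve",
]

# cm/s * ms -> mm  (1 cm/s = 0.01 mm/ms)
_CM_PER_S_TIMES_MS_TO_MM = 0.01


@dataclass
class DisplacementSeries:
    """Voxelwise displacement over one stimulation cycle.

    data : (3, T, X, Y, Z) array, mm. Component order matches the
        velocity series it was integrated from.
    frame_times : ms, one per frame (uniform spacing).
    cycle_duration : ms; the periodic closure point t = T where the
        blended displacement returns to zero exactly.
    """

    data: np.ndarray
    frame_times: np.ndarray
    voxel_spacing: tuple[float, float, float]
    cycle_duration: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class StrainTensorSeries:
    """Symmetric 3x3 strain tensor per voxel per frame.

    data : (T, X, Y, Z, 3, 3), dimensionless.
    convention : 'green_lagrange' or 'infinitesimal'.
    valid : boolean (X, Y, Z) map; False inside the filter boundary band
        where derivative kernels are edge-biased.
    """

    data: np.ndarray
    convention: str
    frame_times: np.ndarray
    valid: np.ndarray


@dataclass
class PrincipalStrainSeries:
    """Principal strains (eigenvalues sorted descending) per voxel per frame.

    eigenvalues : (T, X, Y, Z, 3), lambda1 >= lambda2 >= lambda3.
    first_positive : (T, X, Y, Z) map of max(lambda1, 0).
    nonpositive_flag : boolean map, True where lambda1 <= 0 (clamped).
    valid : boolean (X, Y, Z) map inherited from the tensor series, with
        non-finite voxels removed.
    """

    eigenvalues: np.ndarray
    first_positive: np.ndarray
    nonpositive_flag: np.ndarray
    valid: np.ndarray
    frame_times: np.ndarray


@dataclass
class StrainCurve:
    """ROI-mean first-positive-eigenvalue time course."""

    times: np.ndarray  # ms
    values: np.ndarray  # dimensionless mean lambda1
    n_voxels: np.ndarray  # voxels averaged per frame
    label: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")


def integrate_velocity(v: VelocitySeries) -> DisplacementSeries:
    """Displacement from velocity by blended forward/backward integration.

    Velocities are cumulatively integrated (trapezoidal rule) forward from
    u(0) = 0 and backward from u(T) = 0, where T = n_frames * frame_interval
    is the periodic closure of the cycle (v(T) := v(0)).  The two estimates
    are blended linearly in time::

        u(t) = (1 - t/T) * u_fwd(t) + (t/T) * u_bwd(t)

    which leaves u(0) = u(T) = 0 exactly and cancels any constant velocity
    offset identically: for v = c, u_fwd = c*t, u_bwd = -c*(T - t), and the
    blend is (1 - t/T)ct - (t/T)c(T - t) = 0.

    Returns displacement in mm at the input frame times.
    """
    data = np.asarray(v.data, dtype=float)
    if data.shape[0] != 3:
        raise ValueError("velocity data must have 3 components on axis 0")
    n = data.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 frames, got {n}")
    dt = float(v.frame_interval)
    if dt <= 0:
        raise ValueError("frame_interval must be positive")
    T = n * dt
    t = np.arange(n) * dt

    # periodic extension: sample at t = T equals sample at t = 0
    vper = np.concatenate([data, data[:, :1]], axis=1)  # (3, n+1, ...)
    seg = 0.5 * (vper[:, :-1] + vper[:, 1:]) * dt  # trapezoid per interval

    shape_tail = (1,) * (data.ndim - 2)
    u_fwd = np.zeros_like(data)
    np.cumsum(seg[:, :-1], axis=1, out=u_fwd[:, 1:])
    total = u_fwd[:, -1] + seg[:, -1]  # integral over the full cycle
    # u_bwd(t_k) = -(integral from t_k to T) = u_fwd(t_k) - total
    u_bwd = u_fwd - total[:, None]

    w = (t / T).reshape((1, n) + shape_tail)
    u = (1.0 - w) * u_fwd + w * u_bwd
    u *= _CM_PER_S_TIMES_MS_TO_MM

    return DisplacementSeries(
        data=u,
        frame_times=t,
        voxel_spacing=tuple(v.voxel_spacing),
        cycle_duration=T,
        provenance={
            "method": "trapezoidal forward/backward blend",
            "frame_interval_ms": dt,
            "venc_cm_s": v.venc,
        },
    )


def _sg_kernels(window: int, poly_order: int) -> None:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < poly_order + 1:
        raise ValueError("window must be >= poly_order + 1")


def spatial_gradient_sg(
    u: DisplacementSeries,
    window: int = 5,
    poly_order: int = 2,
) -> np.ndarray:
    """Displacement-gradient field by separable 3-D Savitzky-Golay filtering.

    For each derivative direction the SG first-derivative kernel is applied
    along that axis and the SG smoothing (zeroth-derivative) kernel along
    the two orthogonal axes; all kernels share ``window`` and
    ``poly_order``, so polynomials up to the fit order are differentiated
    exactly at interior voxels.  Mirror padding is used at volume edges;
    voxels within ceil(window/2) of an edge should be excluded from
    statistics (see :func:`strain_tensor`'s validity map).

    Parameters are in voxels; the output is made dimensionless by dividing
    by the voxel spacing (mm displacement / mm coordinate).

    Returns an array of shape (T, X, Y, Z, 3, 3) with
    ``grad[..., i, j] = d u_i / d x_j``.
    """
    _sg_kernels(window, poly_order)
    data = u.data  # (3, T, X, Y, Z)
    if any(window > s for s in data.shape[2:]):
        raise ValueError(
            f"window {window} exceeds volume extent {data.shape[2:]}"
        )
    spacing = u.voxel_spacing
    n_frames = data.shape[1]
    out = np.empty(data.shape[1:] + (3, 3), dtype=float)
    for i in range(3):  # displacement component
        for j in range(3):  # derivative axis
            # data[i] is (T, X, Y, Z): spatial axis j lives at array axis 1+j
            g = savgol_filter(
                data[i], window, poly_order, deriv=1,
                delta=spacing[j], axis=1 + j, mode="mirror",
            )
            for k in range(3):  # smooth the orthogonal axes
                if k == j:
                    continue
                g = savgol_filter(
                    g, window, poly_order, deriv=0, axis=1 + k, mode="mirror"
                )
            out[..., i, j] = g
    if not np.isfinite(out).all():
        warnings.warn("non-finite gradients produced", RuntimeWarning)
    assert out.shape[0] == n_frames
    return out


def edge_validity_mask(shape: Sequence[int], window: int) -> np.ndarray:
    """Boolean mask excluding the SG edge-biased band (ceil(window/2))."""
    band = int(np.ceil(window / 2))
    valid = np.zeros(tuple(shape), dtype=bool)
    sl = tuple(slice(band, s - band) for s in shape)
    if all(s.stop > s.start for s in sl):
        valid[sl] = True
    return valid


def strain_tensor(
    grad: np.ndarray,
    convention: Literal["green_lagrange", "infinitesimal"] = "green_lagrange",
    frame_times: np.ndarray | None = None,
    window: int = 5,
) -> StrainTensorSeries:
    """Strain tensor from the displacement gradient.

    green_lagrange (default): E = 1/2 (G + G^T + G^T G) with G = grad u,
    i.e. E = 1/2 (F^T F - I) for F = I + G -- exactly zero for rigid
    rotations.  infinitesimal: eps = 1/2 (G + G^T).
    """
    grad = np.asarray(grad, dtype=float)
    if grad.shape[-2:] != (3, 3):
        raise ValueError("gradient field must end in 3x3 tensors")
    gt = np.swapaxes(grad, -1, -2)
    if convention == "green_lagrange":
        E = 0.5 * (grad + gt + gt @ grad)
    elif convention == "infinitesimal":
        E = 0.5 * (grad + gt)
    else:
        raise ValueError(f"unknown strain convention {convention!r}")
    E = 0.5 * (E + np.swapaxes(E, -1, -2))  # exact symmetry
    if frame_times is None:
        frame_times = np.arange(grad.shape[0], dtype=float)
    valid = edge_validity_mask(grad.shape[1:4], window)
    return StrainTensorSeries(
        data=E, convention=convention, frame_times=np.asarray(frame_times),
        valid=valid,
    )


def principal_strains(E: StrainTensorSeries) -> PrincipalStrainSeries:
    """Eigen-decompose the strain field; build the first-positive map.

    Eigenvalues are sorted descending per voxel.  Voxels with non-finite
    tensor entries are marked invalid and excluded downstream.  Where the
    largest eigenvalue is not positive the map is clamped to 0 and the
    voxel flagged (the field's convention reports the largest *positive*
    eigenvalue; the flag preserves the information that none was).
    """
    data = E.data
    finite = np.isfinite(data).all(axis=(-2, -1))  # (T, X, Y, Z)
    work = np.where(finite[..., None, None], data, 0.0)
    lam = np.linalg.eigvalsh(work)[..., ::-1]  # descending
    lam = np.where(finite[..., None], lam, np.nan)
    lam1 = lam[..., 0]
    first_positive = np.where(np.isfinite(lam1), np.maximum(lam1, 0.0), np.nan)
    nonpos = np.isfinite(lam1) & (lam1 <= 0.0)
    valid = E.valid & finite.all(axis=0)
    return PrincipalStrainSeries(
        eigenvalues=lam,
        first_positive=first_positive,
        nonpositive_flag=nonpos,
        valid=valid,
        frame_times=E.frame_times,
    )


def roi_strain_curve(
    P: PrincipalStrainSeries,
    mask: RoiMask,
    label: int,
    electrode_centers: Sequence[Sequence[float]] | None = None,
    axis: int = 2,
) -> StrainCurve:
    """ROI-mean first-positive-eigenvalue time curve.

    Averages the first-positive eigenvalue over the voxels carrying
    ``label``, restricted to the span along ``axis`` (superior-inferior by
    default) between the two stimulation-electrode centers, the segment of
    muscle the stimulation actually recruits.  Invalid voxels (non-finite
    or in the filter edge band) are excluded.
    """
    lab = np.asarray(mask.label_volume)
    if lab.shape != P.first_positive.shape[1:]:
        raise ValueError("mask shape does not match strain maps")
    roi = (lab == label) & P.valid
    if not roi.any():
        raise ValueError(f"label {label} selects no valid voxels")
    if electrode_centers is not None:
        (c0, c1) = electrode_centers
        lo, hi = sorted((float(c0[axis]), float(c1[axis])))
        coords = np.arange(lab.shape[axis], dtype=float)
        span = (coords >= lo) & (coords <= hi)
        if not span.any():
            raise ValueError("electrode span selects no slices")
        shape = [1, 1, 1]
        shape[axis] = -1
        roi = roi & span.reshape(shape)
        if not roi.any():
            raise ValueError("electrode span does not intersect the ROI")
    fp = P.first_positive[:, roi]  # (T, n_roi)
    ok = np.isfinite(fp)
    n_vox = ok.sum(axis=1)
    if (n_vox == 0).any():
        raise ValueError("some frames have no valid ROI voxels")
    values = np.where(ok, fp, 0.0).sum(axis=1) / n_vox
    return StrainCurve(
        times=P.frame_times, values=values, n_voxels=n_vox, label=label
    )
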