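"""Synthetic phantoms with analytic ground truth for pipeline validation.

Everything downstream of image acquisition is testable against phantoms
generated here: a cylindrical calf geometry with labelled muscle
compartments, an affine deformation with a sigmoid-family temporal
envelope (exact Green-Lagrange strain known in closed form), velocity
series derived from it (the inverse of the displacement-integration
stage), dual-compartment multi-echo spin-echo signals, Dixon echo stacks,
and two-group subject tables with configurable group effects.

The default study conditions mirror the acquisition being emulated:
periodic stimulation of 750 ms contraction + 750 ms release, Venc
15 cm/s, peak principal strains of order 0.1-0.35, muscle water T2 near
35 ms with fat fractions of a few percent, and a 14 + 10 subject cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from . import relaxometry
from .io import DEFAULT_LABEL_MAP, RoiMask, VelocitySeries
from .strain import DisplacementSeries

__all__ = [
    "PhantomGeometry",
    "DeformationModel",
    "AcquisitionSpec",
    "AnalyticDeformation",
    "make_phantom_geometry",
    "analytic_displacement",
    "velocities_from_displacement",
    "simulate_mese_signal",
    "simulate_mese_volume",
    "simulate_dixon_volume",
    "make_subject_table",
    "COHORT_TARGETS",
]

MM_PER_MS_TO_CM_PER_S = 100.0  # 1 mm/ms = 100 cm/s

LABEL_SOLEUS = 1
LABEL_MEDIAL_GASTROC = 2
LABEL_LATERAL_GASTROC = 3
LABEL_SUBCUT_FAT = 4
MUSCLE_LABELS = (LABEL_SOLEUS, LABEL_MEDIAL_GASTROC, LABEL_LATERAL_GASTROC)


@dataclass
class PhantomGeometry:
    """Labelled calf phantom: 0 background, 1 soleus, 2/3 gastrocnemii,
    4 subcutaneous fat; electrode centers bound the analysed axial span."""

    label_volume: np.ndarray
    voxel_spacing: tuple[float, float, float]
    electrode_centers: tuple[tuple[float, float, float],
                             tuple[float, float, float]]

    def __post_init__(self) -> None:
        labs = set(np.unique(self.label_volume).tolist())
        if not labs <= {0, 1, 2, 3, 4}:
            raise ValueError(f"unexpected labels {sorted(labs)}")
        shape = self.label_volume.shape
        for c in self.electrode_centers:
            if not all(0 <= c[i] < shape[i] for i in range(3)):
                raise ValueError("electrode center outside the volume")

    def center_mm(self) -> np.ndarray:
        return (np.array(self.label_volume.shape, dtype=float) - 1) / 2 * \
            np.asarray(self.voxel_spacing)


@dataclass
class DeformationModel:
    """Affine deformation u(x, t) = g(t) A (x - center) with a periodic
    sigmoid-family envelope g (logistic rise then logistic fall).

    amplitude_tensor : symmetric 3x3 displacement-gradient amplitude.
    steepness_up/down : logistic steepness in 1/s; the rise is centered in
        the contraction phase, the fall in the release phase.
    """

    amplitude_tensor: np.ndarray
    center: np.ndarray | None = None  # mm; phantom center if None
    contraction_duration: float = 750.0  # ms
    release_duration: float = 750.0  # ms
    steepness_up: float = 15.0  # 1/s
    steepness_down: float = 15.0  # 1/s

    def __post_init__(self) -> None:
        A = np.asarray(self.amplitude_tensor, dtype=float)
        if A.shape != (3, 3) or not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("amplitude tensor must be symmetric 3x3")
        self.amplitude_tensor = A

    @property
    def cycle_duration(self) -> float:
        return self.contraction_duration + self.release_duration

    def envelope(self, t_ms: np.ndarray) -> np.ndarray:
        """Temporal envelope g(t) in [0, 1] with g(0) = g(T) = 0 exactly.

        Product of a rising and a falling logistic; a linear ramp between
        the raw endpoint values is subtracted to pin the periodic zeros,
        then the result is rescaled to peak at 1.
        """
        t = np.asarray(t_ms, dtype=float)
        T = self.cycle_duration
        ku = self.steepness_up / 1000.0  # 1/ms
        kd = self.steepness_down / 1000.0
        tu = self.contraction_duration / 2.0
        td = self.contraction_duration + self.release_duration / 2.0

        def raw(x: np.ndarray) -> np.ndarray:
            up = 1.0 / (1.0 + np.exp(-ku * (x - tu)))
            down = 1.0 / (1.0 + np.exp(kd * (x - td)))
            return up * down

        r0 = raw(np.array(0.0))
        rT = raw(np.array(T))
        g = raw(t) - ((1.0 - t / T) * r0 + (t / T) * rT)
        tt = np.linspace(0.0, T, 2049)
        gmax = np.max(raw(tt) - ((1.0 - tt / T) * r0 + (tt / T) * rT))
        return np.clip(g / gmax, 0.0, None)

    def strain_true(self, t_ms: np.ndarray) -> np.ndarray:
        """Closed-form Green-Lagrange strain E(t) = 1/2 (F^T F - I),
        F = I + g(t) A, valid on the untapered muscle interior."""
        g = np.atleast_1d(self.envelope(t_ms))
        A = self.amplitude_tensor
        F = np.eye(3)[None] + g[:, None, None] * A[None]
        return 0.5 * (np.swapaxes(F, 1, 2) @ F - np.eye(3)[None])


@dataclass(frozen=True)
class AcquisitionSpec:
    """Phase-contrast / MESE / Dixon acquisition parameters for simulation."""

    venc: float = 15.0  # cm/s
    n_frames: int = 32
    noise_sd_velocity: float = 0.0  # cm/s
    mese_echo_times: tuple[float, ...] = tuple(
        round(10.9 * (i + 1), 1) for i in range(17)
    )
    mese_tr: float = 4100.0
    dixon_echo_times: tuple[float, ...] = (1.7, 3.2, 4.7, 6.2, 7.7, 9.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames per cycle")
        for name in ("mese_echo_times", "dixon_echo_times"):
            te = np.asarray(getattr(self, name))
            if np.any(np.diff(te) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def mese_protocol(self) -> relaxometry.MeseProtocol:
        return relaxometry.MeseProtocol(echo_times=self.mese_echo_times,
                                        tr=self.mese_tr)


@dataclass
class AnalyticDeformation:
    """Displacement series with its closed-form strain ground truth."""

    displacement: DisplacementSeries
    strain_true: np.ndarray  # (T, 3, 3), valid on interior_mask
    interior_mask: np.ndarray  # (X, Y, Z) bool, untapered muscle interior
    taper: np.ndarray  # (X, Y, Z) in [0, 1]
    envelope: np.ndarray  # g(t) per frame


def make_phantom_geometry(
    shape: Sequence[int] = (32, 32, 48),
    spacing: Sequence[float] = (2.3, 2.3, 2.5),
) -> PhantomGeometry:
    """Nested-cylinder calf phantom.

    A circular leg outline in the axial (x, y) plane, a subcutaneous fat
    rim, and the interior split into a posterior soleus and two anterior
    gastrocnemius compartments, extruded along z.  Electrode centers sit
    on the muscle axis at 25% and 75% of the z extent.  Deterministic:
    the same arguments always produce the same volume.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(
            f"shape {shape} too small: need >= 16 voxels per axis to fit "
            "the leg outline, fat rim and three muscle compartments"
        )
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(x - cx, y - cy)
    leg_r = 0.46 * min(nx, ny)
    fat_inner_r = leg_r - max(2.0, 0.08 * leg_r)

    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[r <= leg_r] = LABEL_SUBCUT_FAT
    muscle = r <= fat_inner_r
    ang = np.arctan2(y - cy, x - cx)  # posterior = +x by convention
    soleus = muscle & (np.cos(ang) >= 0)
    med = muscle & (np.cos(ang) < 0) & (ang > 0)
    lat = muscle & (np.cos(ang) < 0) & (ang <= 0)
    plane[soleus] = LABEL_SOLEUS
    plane[med] = LABEL_MEDIAL_GASTROC
    plane[lat] = LABEL_LATERAL_GASTROC

    vol = np.repeat(plane[:, :, None], nz, axis=2)
    for lab in (1, 2, 3, 4):
        if not (vol == lab).any():
            raise ValueError(f"shape {shape} too small: label {lab} empty")
    electrodes = ((cx, cy, round(0.25 * (nz - 1))),
                  (cx, cy, round(0.75 * (nz - 1))))
    return PhantomGeometry(
        label_volume=vol,
        voxel_spacing=tuple(float(s) for s in spacing),
        electrode_centers=electrodes,
    )


def _muscle_taper(geom: PhantomGeometry, rim: float = 3.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Cosine taper over a `rim`-voxel band inside each muscle label.

    Returns (taper in [0,1], untapered-interior mask).  Tapering keeps the
    synthetic displacement continuous at muscle boundaries; ground-truth
    strain holds only on the interior where taper == 1.
    """
    taper = np.zeros(geom.label_volume.shape, dtype=float)
    interior = np.zeros(geom.label_volume.shape, dtype=bool)
    for lab in MUSCLE_LABELS:
        m = geom.label_volume == lab
        if not m.any():
            continue
        d = distance_transform_edt(m)
        t = np.where(d >= rim, 1.0,
                     0.5 * (1.0 - np.cos(np.pi * d / rim)))
        taper[m] = t[m]
        interior |= m & (d >= rim + 1)  # strictly inside the flat region
    return taper, interior


def analytic_displacement(
    geom: PhantomGeometry,
    model: DeformationModel,
    frame_times: np.ndarray,
) -> AnalyticDeformation:
    """Evaluate u(x, t) = g(t) taper(x) A (x - center) on the phantom.

    Displacement (mm) is affine inside the untapered muscle interior, so
    the Green-Lagrange strain there is exactly
    E(t) = 1/2 ((I + gA)^T (I + gA) - I), returned per frame.
    """
    t = np.asarray(frame_times, dtype=float)
    A = model.amplitude_tensor
    center = (np.asarray(model.center, dtype=float)
              if model.center is not None else geom.center_mm())
    g = model.envelope(t)

    spacing = np.asarray(geom.voxel_spacing)
    shape = geom.label_volume.shape
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                  indexing="ij"), axis=0).astype(float)
    xmm = coords * spacing[:, None, None, None] - center[:, None, None, None]
    ax = np.einsum("ij,jxyz->ixyz", A, xmm)  # A (x - c), mm

    taper, interior = _muscle_taper(geom)
    ax *= taper[None]

    u = g[None, :, None, None, None] * ax[:, None]  # (3, T, X, Y, Z)
    disp = DisplacementSeries(
        data=u,
        frame_times=t,
        voxel_spacing=geom.voxel_spacing,
        cycle_duration=model.cycle_duration,
        provenance={"generator": "analytic_displacement"},
    )
    return AnalyticDeformation(
        displacement=disp,
        strain_true=model.strain_true(t),
        interior_mask=interior,
        taper=taper,
        envelope=g,
    )


def velocities_from_displacement(
    u_series: DisplacementSeries,
    noise_sd: float = 0.0,
    seed: int = 0,
    venc: float = 15.0,
) -> tuple[VelocitySeries, list[str]]:
    """Velocities (cm/s) by central temporal differences of displacement.

    The cycle is treated as periodic (u wraps around), matching the
    stimulation paradigm; Gaussian noise of ``noise_sd`` cm/s is added per
    component when requested.  Velocities exceeding ``venc`` are reported
    as phase-wrap risks in the returned warning list.
    """
    u = u_series.data
    if u.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    t = u_series.frame_times
    dt = float(t[1] - t[0])
    v = (np.roll(u, -1, axis=1) - np.roll(u, 1, axis=1)) / (2 * dt)
    v = v * MM_PER_MS_TO_CM_PER_S

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)

    wrap_warnings: list[str] = []
    vmax_per_frame = np.abs(v).max(axis=(0, 2, 3, 4))
    for i in np.where(vmax_per_frame > venc)[0]:
        wrap_warnings.append(
            f"frame {i}: |v| max {vmax_per_frame[i]:.2f} cm/s exceeds "
            f"venc {venc} cm/s (phase-wrap risk)"
        )
    series = VelocitySeries(
        data=v, venc=venc, frame_interval=dt,
        voxel_spacing=u_series.voxel_spacing,
    )
    return series, wrap_warnings


def simulate_mese_signal(
    ff: float,
    wt2: float,
    fat_t2: float,
    spec: AcquisitionSpec = AcquisitionSpec(),
    refocusing_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_bins: int | None = None,
) -> np.ndarray:
    """Dual-compartment MESE echo magnitudes with Rician noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sig = relaxometry.dual_compartment_signal(
        ff, wt2, fat_t2, spec.mese_protocol(), refocusing_scale,
        n_bins=n_bins,
    )
    if noise_sd == 0:
        return sig
    rng = np.random.default_rng(seed)
    re = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    im = rng.normal(0.0, noise_sd, size=sig.shape)
    return np.hypot(re, im)


def simulate_mese_volume(
    geom: PhantomGeometry,
    wt2_by_label: Mapping[int, float] | None = None,
    ff_by_label: Mapping[int, float] | None = None,
    fat_t2: float = 150.0,
    spec: AcquisitionSpec = AcquisitionSpec(),
    refocusing_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """MESE stack (X, Y, Z, n_echoes) over the phantom labels.

    Defaults: muscle wT2 35 ms / ff 4%; subcutaneous fat ff 90%.
    """
    wt2_by_label = dict(wt2_by_label or {1: 35.0, 2: 35.0, 3: 35.0, 4: 35.0})
    ff_by_label = dict(ff_by_label or {1: 0.04, 2: 0.04, 3: 0.04, 4: 0.90})
    protocol = spec.mese_protocol()
    stack = np.zeros(geom.label_volume.shape + (protocol.n_echoes,))
    for lab in sorted(set(np.unique(geom.label_volume)) - {0}):
        sig = relaxometry.dual_compartment_signal(
            ff_by_label.get(lab, 0.04), wt2_by_label.get(lab, 35.0),
            fat_t2, protocol, refocusing_scale,
        )
        stack[geom.label_volume == lab] = sig
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        re = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        im = rng.normal(0.0, noise_sd, size=stack.shape)
        stack = np.hypot(re, im)
    return stack


def simulate_dixon_volume(
    ff_volume: np.ndarray,
    psi_hz: float | np.ndarray = 0.0,
    s0: float | np.ndarray = 1.0,
    protocol: relaxometry.DixonProtocol = relaxometry.DixonProtocol(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Complex Dixon echo stack for a given fat-fraction volume."""
    ff_volume = np.asarray(ff_volume, dtype=float)
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), ff_volume.shape)
    psi = np.broadcast_to(np.asarray(psi_hz, dtype=float), ff_volume.shape)
    sig = relaxometry.dixon_forward(
        s0 * (1.0 - ff_volume), s0 * ff_volume, psi, protocol
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape) \
            + 1j * rng.normal(0.0, noise_sd, size=sig.shape)
    return sig


def phantom_roi_mask(geom: PhantomGeometry) -> RoiMask:
    """RoiMask view of the phantom labels."""
    return RoiMask(label_volume=geom.label_volume,
                   label_map=dict(DEFAULT_LABEL_MAP))


# --------------------------------------------------------------------------
# Synthetic subject tables
# --------------------------------------------------------------------------

# Default per-group (median, q1, q3) targets per muscle and variable,
# matching the reported cohort summaries of the study being emulated.
# Units: strain dimensionless, rates 1/s, fat_fraction %, water_t2 ms,
# mvf N (constant within subject).
COHORT_TARGETS: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "soleus": {
        "strain": {"hc": (0.26, 0.17, 0.31), "patient": (0.19, 0.12, 0.21)},
        "buildup_rate": {"hc": (0.045, 0.041, 0.061),
                         "patient": (0.031, 0.030, 0.042)},
        "release_rate": {"hc": (0.013, 0.011, 0.014),
                         "patient": (0.012, 0.010, 0.013)},
        "fat_fraction": {"hc": (3.7, 3.3, 4.5), "patient": (3.8, 3.1, 4.6)},
        "water_t2": {"hc": (35.5, 35.0, 36.2), "patient": (35.0, 34.6, 36.6)},
    },
    "medial_gastrocnemius": {
        "strain": {"hc": (0.22, 0.14, 0.33), "patient": (0.20, 0.13, 0.22)},
        "buildup_rate": {"hc": (0.044, 0.030, 0.078),
                         "patient": (0.036, 0.032, 0.062)},
        "release_rate": {"hc": (0.010, 0.008, 0.012),
                         "patient": (0.011, 0.009, 0.012)},
        "fat_fraction": {"hc": (3.4, 2.9, 3.9), "patient": (3.5, 2.7, 4.6)},
        "water_t2": {"hc": (36.0, 34.7, 36.4), "patient": (34.3, 33.9, 36.0)},
    },
    "lateral_gastrocnemius": {
        "strain": {"hc": (0.25, 0.16, 0.31), "patient": (0.18, 0.13, 0.25)},
        "buildup_rate": {"hc": (0.034, 0.025, 0.049),
                         "patient": (0.035, 0.030, 0.040)},
        "release_rate": {"hc": (0.009, 0.008, 0.014),
                         "patient": (0.009, 0.007, 0.011)},
        "fat_fraction": {"hc": (3.5, 3.4, 4.0), "patient": (3.4, 3.0, 5.0)},
        "water_t2": {"hc": (36.0, 34.6, 36.5), "patient": (35.4, 33.9, 36.4)},
    },
}
MVF_TARGETS = {"hc": (80.0, 36.0, 100.0), "patient": (78.0, 57.0, 89.0)}

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

VARIABLES = ("strain", "buildup_rate", "release_rate", "fat_fraction",
             "water_t2")


def _lognormal_params(median: float, q1: float, q3: float
                      ) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR."""
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2 * _Z75)
    return mu, max(sigma, 1e-6)


def make_subject_table(
    n_hc: int = 14,
    n_pat: int = 10,
    effects: Mapping[str, float] | None = None,
    seed: int = 0,
    ff_outlier_patients: int = 3,
) -> pd.DataFrame:
    """Synthetic per-subject, per-muscle biomarker table.

    Variables are drawn from log-normal distributions parameterized by
    target medians and IQRs per muscle and group (skewed, matching the
    non-normal distributions such biomarkers show).  ``effects`` optionally
    overrides the patient/HC contrast per variable as a *relative median
    shift*: patient median = HC median * (1 + effect); an all-zero effects
    mapping yields the no-group-difference null.  A few patients receive a
    pathologically elevated fat fraction (> 10%) in one muscle, emulating
    focal fatty replacement; set ``ff_outlier_patients=0`` to disable.
    Bit-reproducible for a fixed seed.
    """
    if n_hc < 2 or n_pat < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    rows = []
    muscles = tuple(COHORT_TARGETS)
    outlier_subjects: dict[int, str] = {}
    if ff_outlier_patients and effects is None:
        k = min(ff_outlier_patients, n_pat)
        subj = rng.choice(n_pat, size=k, replace=False)
        musc = rng.choice(len(muscles), size=k)
        outlier_subjects = {int(s): muscles[int(m)]
                            for s, m in zip(subj, musc)}

    for group, n in (("hc", n_hc), ("patient", n_pat)):
        gcode = 0 if group == "hc" else 1
        mu, sg = _lognormal_params(*MVF_TARGETS[group])
        mvf = np.exp(rng.normal(mu, sg, size=n))
        for s in range(n):
            sid = f"{'HC' if gcode == 0 else 'PAT'}{s + 1:03d}"
            for muscle in muscles:
                row = {"subject_id": sid, "group": gcode, "muscle": muscle,
                       "mvf": mvf[s]}
                for var in VARIABLES:
                    m_hc, q1_hc, q3_hc = COHORT_TARGETS[muscle][var]["hc"]
                    if group == "hc":
                        med, q1, q3 = m_hc, q1_hc, q3_hc
                    elif effects is not None:
                        scale = 1.0 + float(effects.get(var, 0.0))
                        med, q1, q3 = (m_hc * scale, q1_hc * scale,
                                       q3_hc * scale)
                    else:
                        med, q1, q3 = COHORT_TARGETS[muscle][var][group]
                    mu, sg = _lognormal_params(med, q1, q3)
                    row[var] = float(np.exp(rng.normal(mu, sg)))
                if (gcode == 1 and s in outlier_subjects
                        and outlier_subjects[s] == muscle):
                    row["fat_fraction"] = float(rng.uniform(10.5, 25.0))
                rows.append(row)
    cols = ["subject_id", "group", "muscle", *VARIABLES, "mvf"]
    return pd.DataFrame(rows)[cols]
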