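"""Seeded synthetic cohorts of synchronized tri-modal 5 s snippets.

The generator emulates the recording geometry of the study setup — a
supine infant viewed from above (pose key points at 50 Hz), lying on a
32 x 32 pressure mat (100 Hz), wearing six IMUs (60 Hz) — with a
controllable two-class structure. Both classes move with slow
large-amplitude baseline oscillations (0.1-0.5 Hz); the FM+ class
additionally carries a small-amplitude moderate-frequency component
(1-3 Hz by default), the synthetic stand-in for fidgety movements. All
three modalities are rendered from shared latent limb/trunk
trajectories, so the class signal is naturally correlated across
sensors; a ``split_signal`` mode instead injects three independent
fidgety components, one per modality, to probe fusion gains.

Everything is reproducible from one master seed; per-snippet substreams
are derived with ``SeedSequence`` spawn keys so any snippet can be
regenerated in isolation. The generator aims for controllable class
structure, not biomechanically valid infant kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .snippets import (
    FM_MINUS,
    FM_PLUS,
    HIP_INDICES,
    IMU_FRAMES,
    IMU_RATE,
    MAT_FRAMES,
    MAT_RATE,
    SHOULDER_INDICES,
    VID_FRAMES,
    VID_RATE,
    Dataset,
    IMUSnippet,
    KeypointSnippet,
    PressureSnippet,
    SnippetMeta,
    SnippetTriple,
)

__all__ = ["SimConfig", "simulate_snippet", "generate_dataset"]

# Canonical supine skeleton, pixels relative to the hip midpoint, y up.
_BASE_OFFSETS = np.array([
    (0, 210), (-12, 222), (12, 222),          # nose, eyes
    (-40, 150), (40, 150),                    # shoulders
    (-75, 105), (75, 105),                    # elbows
    (-100, 55), (100, 55),                    # wrists
    (-25, 0), (25, 0),                        # hips
    (-38, -75), (38, -75),                    # knees
    (-48, -150), (48, -150),                  # ankles
], dtype=float)
_IMAGE_CENTER = np.array([960.0, 400.0])

# Per-key-point movement amplitude weights: distal limbs move most.
_KP_WEIGHTS = np.array(
    [0.3, 0.3, 0.3, 0.25, 0.25, 0.6, 0.6, 1.0, 1.0,
     0.2, 0.2, 0.6, 0.6, 1.0, 1.0])

_N_BASE_COMPONENTS = 3
_N_FID_COMPONENTS = 2

# Pressure rendering: two Gaussian load blobs on the mat grid.
_MAT_TOP_CENTER = (6.0, 15.0)      # (row, col), inside the top crop region
_MAT_BOTTOM_CENTER = (20.0, 15.0)  # inside the bottom crop region
_MAT_BLOB_SIGMA = 3.0
_MAT_BLOB_INTENSITY = 10.0
_MAT_CELLS_PER_PIXEL = 0.08
_MAT_INTENSITY_REF_PX = 50.0       # trunk displacement giving 100% modulation
# Ground-reaction coupling: pressure redistributes with limb acceleration
# (px/s^2), which amplifies the fidgety band by its squared angular frequency.
_MAT_ACCEL_TO_CELLS = 5e-4
_MAT_ACCEL_TO_INTENSITY = 1e-4

# IMU rendering constants (units are arbitrary; the pipeline z-scores them).
_GRAVITY_MAGNITUDE = 500.0
# sensor index -> (attachment key point, segment proximal key point or None)
_IMU_ATTACHMENTS = (
    (3, None), (4, None),          # shoulder sensors; segment to hip center
    (9, 11), (10, 12),             # hip sensors; thigh segment hip -> knee
    (13, 11), (14, 12),            # foot sensors; shank segment ankle -> knee
)

_NYQUIST_SLOWEST = VID_RATE / 2.0

# Damping of the IMU-only fidgety component in split-signal mode (see
# simulate_snippet): keeps the three per-modality signals comparably weak.
_SPLIT_IMU_DAMPING = 0.22
_SPLIT_MAT_DAMPING = 0.62


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Amplitudes are in pixels of the latent key-point space; pressure and
    IMU signals are rendered from the same latent trajectories. The
    fidgety amplitude is deliberately small relative to the baseline
    amplitude — the class difference is a subtle extra frequency band,
    not a gross change of movement.
    """

    n_infants: int = 36
    snippets_per_infant: int = 20
    p_fm_plus: float = 0.56
    baseline_amp: float = 40.0
    baseline_band: tuple = (0.1, 0.5)
    fidgety_amp: float = 12.0
    fidgety_band: tuple = (1.0, 3.0)
    keypoint_noise_sd: float = 1.5
    outlier_rate: float = 0.002
    outlier_magnitude: float = 120.0
    pressure_noise_sd: float = 0.5
    imu_noise_sd: float = 40.0
    infant_effect_sd: float = 0.2
    missing_modality_rate: float = 0.0
    split_signal: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("p_fm_plus", "outlier_rate", "missing_modality_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_amp", "fidgety_amp", "keypoint_noise_sd",
                     "outlier_magnitude", "pressure_noise_sd", "imu_noise_sd",
                     "infant_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("baseline_band", "fidgety_band"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo < hi <= _NYQUIST_SLOWEST:
                raise ValueError(
                    f"{name} must lie within (0, {_NYQUIST_SLOWEST}] Hz, got {(lo, hi)}")
        if self.n_infants < 1 or self.snippets_per_infant < 1:
            raise ValueError("n_infants and snippets_per_infant must be >= 1")

    def to_dict(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for k in ("baseline_band", "fidgety_band"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def _draw_components(rng, band, amp, n_comp):
    """Random-phase sinusoid parameters, (15, 2, n_comp) each."""
    shape = (15, 2, n_comp)
    return {
        "amp": amp * _KP_WEIGHTS[:, None, None] * rng.uniform(0.4, 1.0, shape),
        "freq": rng.uniform(band[0], band[1], shape),
        "phase": rng.uniform(0.0, 2.0 * np.pi, shape),
    }


def _eval_components(params, t):
    """Displacement (len(t), 15, 2) of a sinusoid sum."""
    arg = (2.0 * np.pi * params["freq"][None] * t[:, None, None, None]
           + params["phase"][None])
    return (params["amp"][None] * np.sin(arg)).sum(axis=-1)


def _keypoint_trajectories(base, fid, fid_mult, t):
    disp = _eval_components(base, t)
    if fid_mult != 0.0:
        disp = disp + fid_mult * _eval_components(fid, t)
    return _BASE_OFFSETS[None] + _IMAGE_CENTER[None, None] + disp


def _render_pressure(base, fid, fid_mult, rng, noise_sd):
    t = np.arange(MAT_FRAMES) / MAT_RATE
    disp = _eval_components(base, t)
    if fid_mult != 0.0:
        disp = disp + fid_mult * _eval_components(fid, t)
    sc = disp[:, SHOULDER_INDICES, :].mean(axis=1)      # shoulder midpoint motion
    hc = disp[:, HIP_INDICES, :].mean(axis=1)
    # limbs resting near each mat region transmit their acceleration as a
    # ground-reaction load shift: wrists to the top blob, ankles to the bottom
    arm_acc = np.gradient(np.gradient(disp[:, (7, 8), :].mean(axis=1), axis=0),
                          axis=0) * MAT_RATE ** 2
    leg_acc = np.gradient(np.gradient(disp[:, (13, 14), :].mean(axis=1), axis=0),
                          axis=0) * MAT_RATE ** 2

    rows = np.arange(32, dtype=float)[None, :, None]
    cols = np.arange(32, dtype=float)[None, None, :]
    frames = np.zeros((MAT_FRAMES, 32, 32))
    for (r0, c0), track, acc in ((_MAT_TOP_CENTER, sc, arm_acc),
                                 (_MAT_BOTTOM_CENTER, hc, leg_acc)):
        r = (r0 - _MAT_CELLS_PER_PIXEL * track[:, 1]    # y up -> row down
             - _MAT_ACCEL_TO_CELLS * acc[:, 1])
        c = (c0 + _MAT_CELLS_PER_PIXEL * track[:, 0]
             + _MAT_ACCEL_TO_CELLS * acc[:, 0])
        # load modulated by trunk motion and limb load shifts; the floor
        # keeps total pressure positive
        intensity = _MAT_BLOB_INTENSITY * np.maximum(
            0.2, 1.0 + (track[:, 0] + track[:, 1]) / _MAT_INTENSITY_REF_PX
            + _MAT_ACCEL_TO_INTENSITY * (acc[:, 0] + acc[:, 1]))
        frames += intensity[:, None, None] * np.exp(
            -((rows - r[:, None, None]) ** 2 + (cols - c[:, None, None]) ** 2)
            / (2.0 * _MAT_BLOB_SIGMA ** 2))
    frames += rng.normal(0.0, noise_sd, frames.shape)
    # float32 keeps a 720-snippet cohort's raw pressure under ~1.5 GiB
    return np.clip(frames, 0.0, None).astype(np.float32)


def _render_imu(base, fid, fid_mult, rng, noise_sd, gravity, gyro_axes):
    t = np.arange(IMU_FRAMES) / IMU_RATE
    disp = _eval_components(base, t)
    if fid_mult != 0.0:
        disp = disp + fid_mult * _eval_components(fid, t)
    points = _BASE_OFFSETS[None] + disp                 # (T, 15, 2)
    hip_mid = points[:, HIP_INDICES, :].mean(axis=1)

    values = np.empty((IMU_FRAMES, 6, 6))
    for s, (kp, proximal) in enumerate(_IMU_ATTACHMENTS):
        traj = points[:, kp, :]
        # acceleration: second finite difference x rate^2, plus constant gravity
        acc_xy = np.gradient(np.gradient(traj, axis=0), axis=0) * IMU_RATE ** 2
        acc_z = 0.5 * (acc_xy[:, 0] + acc_xy[:, 1])
        acc = np.column_stack([acc_xy, acc_z]) + gravity[s][None, :]
        # angular velocity: first difference of the segment angle x rate,
        # distributed over the three gyro axes by a fixed per-sensor axis
        ref = hip_mid if proximal is None else points[:, proximal, :]
        seg = traj - ref
        theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
        omega = np.gradient(theta) * IMU_RATE
        gyro = omega[:, None] * gyro_axes[s][None, :]
        values[:, s, :3] = acc
        values[:, s, 3:] = gyro
    values += rng.normal(0.0, noise_sd, values.shape)
    return values


def simulate_snippet(config: SimConfig, infant_effect: float, label: int,
                     rng: np.random.Generator, meta: SnippetMeta) -> SnippetTriple:
    """Render one synchronized tri-modal snippet from latent trajectories.

    ``infant_effect`` multiplies all movement amplitudes (a per-infant
    random effect). The fidgety component parameters are drawn for both
    classes (identical generator path); the component enters the rendered
    signals only for FM+ snippets, so ``fidgety_amp=0`` makes the two
    classes identically distributed.
    """
    amp = config.baseline_amp * infant_effect
    fid_amp = config.fidgety_amp * infant_effect
    base = _draw_components(rng, config.baseline_band, amp, _N_BASE_COMPONENTS)
    # One shared fidgety component set, or three independent per-modality
    # sets when the class signal should be split across modalities. In
    # split mode the IMU component is damped: differentiation amplifies
    # the fidgety band by its squared angular frequency, and the split
    # cohort is meant to give each modality a comparably weak signal.
    if config.split_signal:
        fid_vid, fid_mat, fid_imu = (
            _draw_components(rng, config.fidgety_band, fid_amp * scale,
                             _N_FID_COMPONENTS)
            for scale in (1.0, _SPLIT_MAT_DAMPING, _SPLIT_IMU_DAMPING))
    else:
        fid_vid = fid_mat = fid_imu = _draw_components(
            rng, config.fidgety_band, fid_amp, _N_FID_COMPONENTS)
    fid_mult = 1.0 if label == FM_PLUS else 0.0

    # --- video key points -------------------------------------------------
    t_vid = np.arange(VID_FRAMES) / VID_RATE
    kp = _keypoint_trajectories(base, fid_vid, fid_mult, t_vid)
    kp = kp + rng.normal(0.0, config.keypoint_noise_sd, kp.shape)
    spike_mask = rng.random((VID_FRAMES, 15)) < config.outlier_rate
    spike_sign = rng.integers(0, 2, (VID_FRAMES, 15, 2)) * 2.0 - 1.0
    kp = kp + spike_mask[:, :, None] * spike_sign * config.outlier_magnitude

    # --- pressure mat ------------------------------------------------------
    pressure = _render_pressure(base, fid_mat, fid_mult, rng, config.pressure_noise_sd)

    # --- IMU ---------------------------------------------------------------
    gdir = rng.normal(size=(6, 3))
    gravity = _GRAVITY_MAGNITUDE * gdir / np.linalg.norm(gdir, axis=1, keepdims=True)
    adir = rng.normal(size=(6, 3))
    gyro_axes = adir / np.linalg.norm(adir, axis=1, keepdims=True)
    imu = _render_imu(base, fid_imu, fid_mult, rng, config.imu_noise_sd,
                      gravity, gyro_axes)

    return SnippetTriple(
        meta=meta,
        keypoints=KeypointSnippet(values=kp, meta=meta),
        pressure=PressureSnippet(values=pressure, meta=meta),
        imu=IMUSnippet(values=imu, meta=meta),
    )


def generate_dataset(config: SimConfig) -> Dataset:
    """Generate ``n_infants x snippets_per_infant`` synchronized triples.

    Labels are i.i.d. Bernoulli(``p_fm_plus``); each infant carries a
    multiplicative LogNormal(0, ``infant_effect_sd``) amplitude effect;
    each modality of each snippet is independently deleted with
    ``missing_modality_rate``. Bit-exact reproducible from ``seed``.
    """
    triples = []
    for i in range(config.n_infants):
        infant_id = f"inf{i:02d}"
        rng_inf = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0, i)))
        infant_effect = float(np.exp(rng_inf.normal(0.0, config.infant_effect_sd)))
        for j in range(config.snippets_per_infant):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(1, i, j)))
            label = FM_PLUS if rng.random() < config.p_fm_plus else FM_MINUS
            # draw the session stream identically for both classes
            fid_session = f"T{5 + rng.integers(0, 3)}"
            session = fid_session if label == FM_PLUS else "T1"
            meta = SnippetMeta(
                snippet_id=f"{infant_id}_s{j:03d}",
                infant_id=infant_id,
                session=session,
                label=label,
            )
            triple = simulate_snippet(config, infant_effect, label, rng, meta)
            if config.missing_modality_rate > 0.0:
                drop = rng.random(3) < config.missing_modality_rate
                triple = SnippetTriple(
                    meta=meta,
                    keypoints=None if drop[0] else triple.keypoints,
                    pressure=None if drop[1] else triple.pressure,
                    imu=None if drop[2] else triple.imu,
                )
            triples.append(triple)
    return Dataset(triples=tuple(triples))
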