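"""Digital DCE-MRI phantoms with known ground truth.

The phantom forward-simulates the full acquisition described by the
quantification module: an SPGR dynamic series whose voxel T1 evolves
with a known gamma-variate contrast-agent concentration, a VFA series
for T1 estimation, and an AFI pair encoding a known flip-angle error
map.  Ground-truth concentration curves, iAUC90 and MRT (computed from
the closed-form curve by fine quadrature) are returned alongside so the
inverse pipeline can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dce import (
    DEFAULT_R1_RELAXIVITY,
    DCEStudy,
    afi_signals_exact,
    spgr_signal,
)


def gamma_variate(t, peak_mM, t0_s, alpha, beta_s):
    """Peak-normalized gamma-variate concentration curve (mM).

    C(t) = peak * (tau / (alpha beta))^alpha * exp(alpha - tau/beta) for
    tau = t - t0 > 0, which attains ``peak_mM`` at tau = alpha * beta.
    """
    t = np.asarray(t, float)
    tau = t - t0_s
    out = np.zeros_like(t)
    pos = tau > 0
    tp = alpha * beta_s
    out[pos] = peak_mM * (tau[pos] / tp) ** alpha * np.exp(alpha - tau[pos] / beta_s)
    return out


@dataclass
class DCEPhantomSpec:
    """Acquisition and tissue parameters of the digital phantom.

    Defaults follow a preclinical 7 T protocol: SPGR with TR 1.7 ms and
    a 5 deg dynamic flip angle, 16 VFA angles from 1 to 8 deg, an AFI
    pair with TR1/TR2 = 10/100 ms at 64 deg, and 50 dynamic frames
    ~13 s apart with injection at the start of the 11th frame.
    """

    grid_shape: tuple[int, int, int] = (8, 32, 32)  # (z, y, x)
    tr_ms: float = 1.7
    nominal_fa_deg: float = 5.0
    flip_angles_deg: tuple = tuple(np.linspace(1.0, 8.0, 16))
    afi_tr1_ms: float = 10.0
    afi_tr2_ms: float = 100.0
    afi_nominal_fa_deg: float = 64.0
    n_frames: int = 50
    frame_spacing_s: float = 13.0
    injection_frame: int = 10  # 0-based index; the 11th frame of 50
    relaxivity_r1: float = DEFAULT_R1_RELAXIVITY
    #: baseline T1 (ms) and M0; scalars are broadcast to maps
    t1_ms: float | np.ndarray = 1500.0
    m0: float | np.ndarray = 1000.0
    #: actual/nominal flip-angle map (B1 error); scalar broadcasts
    fa_scale: float | np.ndarray = 1.0
    #: per-voxel gamma-variate parameter maps; None -> built by masks below
    peak_mM: np.ndarray | None = None
    gamma_alpha: float = 2.0
    gamma_beta_s: float = 20.0
    #: fraction of tumour voxels that enhance; rest stay at baseline
    tumor_enhancing_fraction: float = 0.6
    tumor_peak_mM: float = 0.5
    muscle_peak_mM: float = 0.1
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be gaussian or rician")
        if not 0 <= self.injection_frame < self.n_frames:
            raise ValueError("injection_frame outside series")
        if np.any(np.asarray(self.fa_scale) <= 0):
            raise ValueError("fa_scale must be positive")

    @property
    def frame_times_s(self) -> np.ndarray:
        # timestamp of the k-space centre of each frame
        return (np.arange(self.n_frames) + 0.5) * self.frame_spacing_s


def default_masks(grid_shape):
    """Disjoint tumour (left half) and muscle (right quarter) slabs."""
    nz, ny, nx = grid_shape
    tumor = np.zeros(grid_shape, bool)
    muscle = np.zeros(grid_shape, bool)
    tumor[:, :, : nx // 2] = True
    muscle[:, :, 3 * nx // 4 :] = True
    return tumor, muscle


def generate_dce_phantom(spec: DCEPhantomSpec):
    """Build a :class:`DCEStudy` plus a ground-truth dictionary.

    Ground truth contains the noiseless concentration series ``c_true``,
    the tissue maps (``t1_ms``, ``m0``, ``fa_scale``), the enhancing
    compartment mask, and per-voxel ``iauc90`` / ``mrt_s`` evaluated
    from the closed-form curves by fine quadrature.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    t1_0 = np.broadcast_to(np.asarray(spec.t1_ms, float), shape).copy()
    m0 = np.broadcast_to(np.asarray(spec.m0, float), shape).copy()
    fa_scale = np.broadcast_to(np.asarray(spec.fa_scale, float), shape).copy()

    tumor, muscle = default_masks(shape)
    if spec.peak_mM is not None:
        peak = np.asarray(spec.peak_mM, float)
    else:
        peak = np.zeros(shape)
        tumor_idx = np.flatnonzero(tumor.ravel())
        n_enh = int(round(spec.tumor_enhancing_fraction * tumor_idx.size))
        # deterministic spatial pattern: first n_enh tumour voxels enhance
        enh = tumor_idx[:n_enh]
        flat = peak.ravel()
        flat[enh] = spec.tumor_peak_mM
        flat[muscle.ravel()] = spec.muscle_peak_mM
        peak = flat.reshape(shape)

    times = spec.frame_times_s
    t_inj = float(times[spec.injection_frame])

    # concentration at frame times: (T, z, y, x)
    unit = gamma_variate(times, 1.0, t_inj, spec.gamma_alpha, spec.gamma_beta_s)
    c_true = unit.reshape((-1,) + (1,) * 3) * peak[None]

    # dynamic SPGR signals
    a_dyn = np.radians(spec.nominal_fa_deg) * fa_scale
    with np.errstate(divide="ignore"):
        r1_t = 1.0 / t1_0[None] + spec.relaxivity_r1 * c_true / 1000.0  # per ms
    t1_t = 1.0 / r1_t
    signal = spgr_signal(m0[None], t1_t, spec.tr_ms, a_dyn[None])

    # VFA series at baseline T1
    vfa_fa = np.asarray(spec.flip_angles_deg, float)
    a_vfa = np.radians(vfa_fa).reshape((-1, 1, 1, 1)) * fa_scale[None]
    vfa = spgr_signal(m0[None], t1_0[None], spec.tr_ms, a_vfa)

    # AFI pair at the actual angle
    a_afi = np.radians(spec.afi_nominal_fa_deg) * fa_scale
    s1, s2 = afi_signals_exact(m0, t1_0, spec.afi_tr1_ms, spec.afi_tr2_ms, a_afi)

    if spec.noise_sigma > 0:
        def noised(x):
            if spec.noise_model == "rician":
                re = x + rng.normal(0, spec.noise_sigma, x.shape)
                im = rng.normal(0, spec.noise_sigma, x.shape)
                return np.hypot(re, im)
            return x + rng.normal(0, spec.noise_sigma, x.shape)
        signal, vfa, s1, s2 = map(noised, (signal, vfa, s1, s2))

    study = DCEStudy(
        signal=signal,
        frame_times_s=times,
        injection_frame=spec.injection_frame,
        tr_ms=spec.tr_ms,
        nominal_fa_deg=spec.nominal_fa_deg,
        vfa_signals=vfa,
        vfa_fa_deg=vfa_fa,
        afi_s1=s1,
        afi_s2=s2,
        afi_tr1_ms=spec.afi_tr1_ms,
        afi_tr2_ms=spec.afi_tr2_ms,
        afi_nominal_fa_deg=spec.afi_nominal_fa_deg,
        tumor_mask=tumor,
        muscle_mask=muscle,
        relaxivity_r1=spec.relaxivity_r1,
        meta={"phantom_seed": spec.seed, "noise_sigma": spec.noise_sigma},
    )

    # ground-truth iAUC90 and MRT by fine quadrature of the closed form
    tg = np.arange(t_inj, t_inj + 90.0 + 1e-9, 0.02)
    unit_iauc90 = float(np.trapezoid(
        gamma_variate(tg, 1.0, t_inj, spec.gamma_alpha, spec.gamma_beta_s), tg
    ))
    tg_full = np.arange(t_inj, times[-1] + 1e-9, 0.02)
    cg = gamma_variate(tg_full, 1.0, t_inj, spec.gamma_alpha, spec.gamma_beta_s)
    unit_area = float(np.trapezoid(cg, tg_full))
    unit_moment = float(np.trapezoid(cg * (tg_full - t_inj), tg_full))
    mrt_true = np.where(peak > 0, unit_moment / unit_area, np.nan)

    truth = {
        "c_true": c_true,
        "t1_ms": t1_0,
        "m0": m0,
        "fa_scale": fa_scale,
        "peak_mM": peak,
        "enhancing_mask": peak > 0,
        "iauc90": peak * unit_iauc90,
        "mrt_s": mrt_true,
        "injection_time_s": t_inj,
    }
    return study, truth
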