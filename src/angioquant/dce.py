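"""DCE-MRI quantification: B1 correction, T1 mapping, concentration
conversion, and model-free perfusion metrics.

The signal model throughout is the spoiled gradient echo (SPGR) steady
state

    S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1)

with the actual flip angle ``a`` obtained voxel-wise from an
actual-flip-angle-imaging (AFI) pair, T1 from a linearized
variable-flip-angle (VFA) fit, and tissue gadolinium concentration from
inverting the SPGR equation against the pre-injection baseline:
1/T1(t) = 1/T1_0 + r1 * C(t).

Perfusion is summarized without a pharmacokinetic model: the initial
area under the concentration curve over the first 90 s after injection
(iAUC90, mM*s), the mean residence time (MRT, s) from the first
temporal moment of C(t), and the fraction of tumour voxels whose iAUC90
exceeds the median iAUC90 of a muscle reference region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: default longitudinal relaxivity, s^-1 mM^-1 (Gd-DTPA class agent at 7 T)
DEFAULT_R1_RELAXIVITY = 3.3


# ---------------------------------------------------------------------------
# forward models


def spgr_signal(m0, t1_ms, tr_ms, fa_rad):
    """SPGR steady-state signal. Arrays broadcast."""
    e1 = np.exp(-np.asarray(tr_ms, float) / np.asarray(t1_ms, float))
    return m0 * np.sin(fa_rad) * (1.0 - e1) / (1.0 - e1 * np.cos(fa_rad))


def afi_signals_exact(m0, t1_ms, tr1_ms, tr2_ms, fa_rad):
    """Exact pulsed steady state of the two-TR AFI sequence.

    Returns ``(S1, S2)`` for the interleaved TR1/TR2 acquisition.
    """
    e1 = np.exp(-tr1_ms / np.asarray(t1_ms, float))
    e2 = np.exp(-tr2_ms / np.asarray(t1_ms, float))
    c = np.cos(fa_rad)
    s = np.sin(fa_rad)
    denom = 1.0 - e1 * e2 * c**2
    s1 = m0 * s * (1.0 - e2 + (1.0 - e1) * e2 * c) / denom
    s2 = m0 * s * (1.0 - e1 + (1.0 - e2) * e1 * c) / denom
    return s1, s2


def afi_signals_linear(m0, t1_ms, tr1_ms, tr2_ms, fa_rad):
    """Short-TR (linearized) AFI model, the one the arccos inversion
    inverts exactly: S2/S1 = (1 + n cos a) / (n + cos a), n = TR2/TR1."""
    n = tr2_ms / tr1_ms
    c = np.cos(fa_rad)
    s1 = m0 * np.sin(fa_rad) * (n + c)
    s2 = m0 * np.sin(fa_rad) * (1.0 + n * c)
    return s1, s2


# ---------------------------------------------------------------------------
# containers


@dataclass
class DCEStudy:
    """One DCE acquisition with its VFA / AFI companions and masks.

    ``signal`` has shape ``(n_frames, nz, ny, nx)``; ``vfa_signals`` has
    shape ``(n_fa, nz, ny, nx)``.
    """

    signal: np.ndarray
    frame_times_s: np.ndarray
    injection_frame: int
    tr_ms: float
    nominal_fa_deg: float
    vfa_signals: np.ndarray
    vfa_fa_deg: np.ndarray
    afi_s1: np.ndarray
    afi_s2: np.ndarray
    afi_tr1_ms: float
    afi_tr2_ms: float
    afi_nominal_fa_deg: float
    tumor_mask: np.ndarray
    muscle_mask: np.ndarray
    relaxivity_r1: float = DEFAULT_R1_RELAXIVITY
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        self.frame_times_s = np.asarray(self.frame_times_s, float)
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not 0 <= self.injection_frame < len(self.frame_times_s):
            raise ValueError("injection_frame outside series")
        if self.tr_ms <= 0 or self.nominal_fa_deg <= 0:
            raise ValueError("TR and flip angle must be positive")
        self.tumor_mask = np.asarray(self.tumor_mask, bool)
        self.muscle_mask = np.asarray(self.muscle_mask, bool)

    @property
    def injection_time_s(self) -> float:
        return float(self.frame_times_s[self.injection_frame])

    # -- I/O: per-frame TIFFs plus a JSON sidecar --------------------------

    def write_dir(self, path) -> None:
        from pathlib import Path

        import tifffile

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for k in range(self.signal.shape[0]):
            tifffile.imwrite(path / f"frame_{k:03d}.tif", self.signal[k].astype(np.float32), photometric="minisblack")
        tifffile.imwrite(path / "vfa.tif", self.vfa_signals.astype(np.float32), photometric="minisblack")
        tifffile.imwrite(path / "afi_s1.tif", self.afi_s1.astype(np.float32), photometric="minisblack")
        tifffile.imwrite(path / "afi_s2.tif", self.afi_s2.astype(np.float32), photometric="minisblack")
        tifffile.imwrite(path / "tumor_mask.tif", self.tumor_mask.astype(np.uint8), photometric="minisblack")
        tifffile.imwrite(path / "muscle_mask.tif", self.muscle_mask.astype(np.uint8), photometric="minisblack")
        sidecar = {
            "frame_times_s": self.frame_times_s.tolist(),
            "injection_frame": int(self.injection_frame),
            "tr_ms": self.tr_ms,
            "nominal_fa_deg": self.nominal_fa_deg,
            "vfa_fa_deg": np.asarray(self.vfa_fa_deg).tolist(),
            "afi_tr1_ms": self.afi_tr1_ms,
            "afi_tr2_ms": self.afi_tr2_ms,
            "afi_nominal_fa_deg": self.afi_nominal_fa_deg,
            "relaxivity_r1": self.relaxivity_r1,
            "n_frames": int(self.signal.shape[0]),
            "meta": self.meta,
        }
        (path / "study.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_dir(cls, path) -> "DCEStudy":
        from pathlib import Path

        import tifffile

        path = Path(path)
        side = json.loads((path / "study.json").read_text())
        missing = [
            name
            for name in ("vfa.tif", "afi_s1.tif", "afi_s2.tif", "tumor_mask.tif", "muscle_mask.tif")
            if not (path / name).exists()
        ]
        if missing:
            raise FileNotFoundError(f"DCE study incomplete; missing {missing}")
        frames = [
            tifffile.imread(path / f"frame_{k:03d}.tif") for k in range(side["n_frames"])
        ]
        return cls(
            signal=np.stack(frames),
            frame_times_s=np.asarray(side["frame_times_s"]),
            injection_frame=side["injection_frame"],
            tr_ms=side["tr_ms"],
            nominal_fa_deg=side["nominal_fa_deg"],
            vfa_signals=tifffile.imread(path / "vfa.tif"),
            vfa_fa_deg=np.asarray(side["vfa_fa_deg"]),
            afi_s1=tifffile.imread(path / "afi_s1.tif"),
            afi_s2=tifffile.imread(path / "afi_s2.tif"),
            afi_tr1_ms=side["afi_tr1_ms"],
            afi_tr2_ms=side["afi_tr2_ms"],
            afi_nominal_fa_deg=side["afi_nominal_fa_deg"],
            tumor_mask=tifffile.imread(path / "tumor_mask.tif") > 0,
            muscle_mask=tifffile.imread(path / "muscle_mask.tif") > 0,
            relaxivity_r1=side.get("relaxivity_r1", DEFAULT_R1_RELAXIVITY),
            meta=side.get("meta", {}),
        )


@dataclass
class T1Map:
    t1_ms: np.ndarray
    m0: np.ndarray
    fa_scale: np.ndarray
    valid: np.ndarray


@dataclass
class PerfusionSummary:
    iauc90: np.ndarray
    mrt_s: np.ndarray
    perfused_fraction_initial: float
    perfused_fraction_end: float
    muscle_median_iauc90: float
    relaxivity_r1: float
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def afi_actual_flip_angle(s1, s2, tr1_ms, tr2_ms, nominal_fa_deg):
    """Voxel-wise actual/nominal flip-angle ratio from an AFI pair.

    With r = S2/S1 and n = TR2/TR1 the actual angle is
    arccos((r n - 1) / (n - r)).  Voxels whose ratio falls outside the
    invertible range (or with non-positive S1) are flagged invalid.

    Returns ``(fa_scale, valid)``.
    """
    if not (tr2_ms > tr1_ms > 0):
        raise ValueError("need TR2 > TR1 > 0")
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    n = tr2_ms / tr1_ms
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s1 > 0, s2 / s1, np.nan)
        cosa = (r * n - 1.0) / (n - r)
    valid = np.isfinite(cosa) & (cosa > -1.0) & (cosa < 1.0)
    fa = np.full(s1.shape if s1.ndim else (), np.nan)
    fa = np.where(valid, np.degrees(np.arccos(np.clip(cosa, -1, 1))), np.nan)
    # a recovered angle of ~0 means r ~ 1: degenerate, flag it
    degenerate = fa < 1e-3
    valid = valid & ~degenerate
    fa_scale = fa / nominal_fa_deg
    return fa_scale, valid


def vfa_t1_fit(vfa_signals, fa_deg, tr_ms, fa_scale=None):
    """Linearized VFA T1 fit, voxel-wise.

    Regresses S/sin(a) on S/tan(a) over the flip angles; the slope is
    E1 = exp(-TR/T1) and the intercept M0 (1 - E1).  ``fa_scale``
    multiplies the nominal angles voxel-wise (B1 correction).
    Voxels with slope outside (0, 1) or degenerate signals are invalid.
    """
    s = np.asarray(vfa_signals, float)
    fa = np.radians(np.asarray(fa_deg, float))
    if fa.size < 2:
        raise ValueError("need at least two flip angles")
    shape = s.shape[1:]
    if fa_scale is None:
        fa_scale = np.ones(shape)
    fa_scale = np.asarray(fa_scale, float)
    # per-voxel corrected angles: (n_fa, *shape)
    a = fa.reshape((-1,) + (1,) * len(shape)) * fa_scale[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = s / np.sin(a)
        x = s / np.tan(a)
    nfa = fa.size
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
    valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & (sxx > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -tr_ms / np.log(slope), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)
    valid = valid & np.isfinite(t1) & (t1 > 0)
    return T1Map(t1_ms=t1, m0=m0, fa_scale=fa_scale, valid=valid)


def signal_to_concentration(
    signal,
    t1map: T1Map,
    tr_ms: float,
    nominal_fa_deg: float,
    relaxivity_r1: float = DEFAULT_R1_RELAXIVITY,
    baseline_frames: slice | np.ndarray = slice(0, 10),
    negative_floor_mM: float = -0.05,
):
    """Invert the SPGR equation frame-by-frame to a concentration series.

    The enhancement ratio relative to the mean pre-injection baseline
    signal determines E1(t) given the baseline T1; then
    R1(t) = -ln(E1(t))/TR and C(t) = (R1(t) - R1_0) / r1.

    Returns ``(C, valid)`` where ``C`` has the shape of ``signal`` (mM)
    and ``valid`` marks voxel-frames inside the invertible range.
    Negative excursions below ``negative_floor_mM`` are flagged; smaller
    negatives are retained as noise.
    """
    s = np.asarray(signal, float)
    tr_s = tr_ms / 1000.0
    a = np.radians(nominal_fa_deg) * t1map.fa_scale
    cos_a = np.cos(a)
    e10 = np.exp(-tr_ms / t1map.t1_ms)
    f0 = (1.0 - e10) / (1.0 - e10 * cos_a)
    s0 = s[baseline_frames].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (s / s0[None]) * f0[None]
        e1t = (1.0 - f) / (1.0 - f * cos_a[None])
        r1t = -np.log(e1t) / tr_s
        r10 = -np.log(e10) / tr_s
        c = (r1t - r10[None]) / relaxivity_r1
    valid = (
        np.isfinite(c)
        & (e1t > 0)
        & (e1t < 1)
        & t1map.valid[None]
        & (s0[None] > 0)
        & (c > negative_floor_mM)
    )
    c = np.where(np.isfinite(c), c, np.nan)
    return c, valid


def _window_trapz(c, times, t0, t1, first_moment=False):
    """Trapezoidal integral of voxel series over [t0, t1] with linear
    interpolation to the exact window endpoints.

    ``c`` is (n_frames, ...); NaNs are treated as 0 (flagged frames drop
    out of the integral).
    """
    times = np.asarray(times, float)
    if t1 <= t0:
        raise ValueError("empty integration window")
    inside = (times > t0) & (times < t1)
    c = np.nan_to_num(np.asarray(c, float), nan=0.0)

    def interp_at(t):
        i = np.searchsorted(times, t)
        i = np.clip(i, 1, len(times) - 1)
        w = (t - times[i - 1]) / (times[i] - times[i - 1])
        w = np.clip(w, 0.0, 1.0)
        return (1 - w) * c[i - 1] + w * c[i]

    t_grid = np.concatenate([[t0], times[inside], [t1]])
    v0 = np.asarray(interp_at(t0))[None]
    v1 = np.asarray(interp_at(t1))[None]
    v_grid = np.concatenate([v0, c[inside], v1], axis=0)
    if first_moment:
        v_grid = v_grid * (t_grid - t0).reshape((-1,) + (1,) * (v_grid.ndim - 1))
    dt = np.diff(t_grid).reshape((-1,) + (1,) * (v_grid.ndim - 1))
    return (0.5 * dt * (v_grid[:-1] + v_grid[1:])).sum(axis=0)


def iauc(c, frame_times_s, injection_time_s, window_s=90.0):
    """Initial area under the concentration curve, mM*s per voxel.

    Integrates C over ``[t_inj, t_inj + window]`` by the trapezoidal
    rule with interpolation to the exact window endpoints.
    """
    times = np.asarray(frame_times_s, float)
    t1 = injection_time_s + window_s
    if t1 > times[-1] + 1e-9:
        raise ValueError("iAUC window extends beyond the acquisition")
    n_inside = int(np.sum((times >= injection_time_s) & (times <= t1)))
    if n_inside < 2:
        raise ValueError("fewer than 2 frames in the iAUC window")
    return _window_trapz(c, times, injection_time_s, t1)


def mrt(c, frame_times_s, injection_time_s, min_area=1e-9):
    """Mean residence time, s per voxel: first temporal moment of C
    normalized by its area over the post-injection observation window."""
    times = np.asarray(frame_times_s, float)
    t_end = times[-1]
    c = np.clip(np.nan_to_num(np.asarray(c, float), nan=0.0), 0.0, None)
    area = _window_trapz(c, times, injection_time_s, t_end)
    moment = _window_trapz(c, times, injection_time_s, t_end, first_moment=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(area > min_area, moment / area, np.nan)
    return out


def perfused_voxel_fraction(iauc_map, tumor_mask, muscle_mask):
    """Fraction of tumour voxels with iAUC strictly above the muscle
    median, plus that median."""
    tumor_mask = np.asarray(tumor_mask, bool)
    muscle_mask = np.asarray(muscle_mask, bool)
    if not tumor_mask.any() or not muscle_mask.any():
        raise ValueError("tumor and muscle masks must be non-empty")
    med = float(np.nanmedian(np.asarray(iauc_map)[muscle_mask]))
    vals = np.asarray(iauc_map)[tumor_mask]
    frac = float(np.mean(np.nan_to_num(vals, nan=-np.inf) > med))
    return frac, med


def perfused_fraction_at_end(c, frame_times_s, injection_time_s, tumor_mask, muscle_mask):
    """Muscle-median rule applied to the AUC over the full post-injection
    window ending at the last frame ("end of imaging session")."""
    times = np.asarray(frame_times_s, float)
    auc_full = _window_trapz(
        np.clip(np.nan_to_num(np.asarray(c, float), nan=0.0), 0.0, None),
        times, injection_time_s, times[-1],
    )
    frac, _ = perfused_voxel_fraction(auc_full, tumor_mask, muscle_mask)
    return frac


def quantify_dce(study: DCEStudy, window_s: float = 90.0,
                 baseline_frames: slice | None = None) -> PerfusionSummary:
    """Full pipeline: AFI correction -> VFA T1 fit -> concentration ->
    iAUC90 / MRT maps -> perfused-volume fractions."""
    if baseline_frames is None:
        baseline_frames = slice(0, study.injection_frame)
    fa_scale, fa_valid = afi_actual_flip_angle(
        study.afi_s1, study.afi_s2, study.afi_tr1_ms, study.afi_tr2_ms,
        study.afi_nominal_fa_deg,
    )
    fa_scale = np.where(fa_valid, fa_scale, 1.0)
    t1map = vfa_t1_fit(study.vfa_signals, study.vfa_fa_deg, study.tr_ms, fa_scale)
    c, _ = signal_to_concentration(
        study.signal, t1map, study.tr_ms, study.nominal_fa_deg,
        study.relaxivity_r1, baseline_frames,
    )
    t_inj = study.injection_time_s
    iauc90 = iauc(c, study.frame_times_s, t_inj, window_s)
    mrt_map = mrt(c, study.frame_times_s, t_inj)
    frac_init, muscle_med = perfused_voxel_fraction(iauc90, study.tumor_mask, study.muscle_mask)
    frac_end = perfused_fraction_at_end(
        c, study.frame_times_s, t_inj, study.tumor_mask, study.muscle_mask
    )
    return PerfusionSummary(
        iauc90=iauc90,
        mrt_s=mrt_map,
        perfused_fraction_initial=frac_init,
        perfused_fraction_end=frac_end,
        muscle_median_iauc90=muscle_med,
        relaxivity_r1=study.relaxivity_r1,
        notes={
            "window_s": window_s,
            "t2star_correction": "neglected (TE << T2*)",
            "afi_invalid_voxels": int((~fa_valid).sum()),
        },
    )
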