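"""Rasterize vessel graphs into two-channel 3D image stacks.

Each branch is drawn as a tube of radius ``diameter / 2`` around its
centerline, the endothelium channel containing every branch and the
perfusion channel only branches flagged perfused — the synthetic
counterpart of a genetically labelled endothelium imaged together with
an intravascular tracer.  The binary rasterization is scaled to
``signal_level`` over ``background_level``, blurred with a Gaussian PSF
and optionally noised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..graphs import VesselGraph
from ..stacks import CHANNEL_ENDOTHELIUM, CHANNEL_PERFUSION, DEFAULT_VOXEL_SIZE_UM, ImageStack

log = logging.getLogger(__name__)


@dataclass
class RenderSpec:
    """Imaging model for rasterizing a vessel graph.

    ``noise_model`` is one of ``"none"``, ``"gaussian"`` (additive, std
    ``noise_sigma``) or ``"poisson"`` (shot noise with ``noise_scale``
    photons per intensity unit).
    """

    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    psf_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_level: float = 0.0
    signal_level: float = 100.0
    noise_model: str = "none"
    noise_sigma: float = 0.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def rasterize_tubes(
    graph: VesselGraph,
    shape_zyx: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    perfused_only: bool = False,
) -> np.ndarray:
    """Binary tube mask: voxels whose centre lies within ``diameter/2``
    of a branch centerline."""
    dx, dy, dz = voxel_size_um
    vol = np.zeros(shape_zyx, dtype=bool)
    step = 0.5 * min(dx, dy, dz)
    for b in graph.branches:
        if perfused_only and not b.perfused:
            continue
        r = b.mean_diameter_um / 2.0
        pts = _resample_polyline(b.points, step)
        _stamp_balls(vol, pts, r, voxel_size_um)
    return vol


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return points[:1]
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(total / step)) + 1)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, points[:, k])
    return out


def _ball_offsets(radius_um: float, voxel_size_um) -> tuple[np.ndarray, np.ndarray]:
    """Voxel index offsets within radius of a point, plus their physical
    offsets (z, y, x ordering)."""
    dx, dy, dz = voxel_size_um
    nx = int(np.floor(radius_um / dx))
    ny = int(np.floor(radius_um / dy))
    nz = int(np.floor(radius_um / dz))
    zz, yy, xx = np.meshgrid(
        np.arange(-nz, nz + 1), np.arange(-ny, ny + 1), np.arange(-nx, nx + 1),
        indexing="ij",
    )
    off = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    phys = off * np.array([dz, dy, dx])
    keep = np.linalg.norm(phys, axis=1) <= radius_um + 1e-9
    return off[keep], phys[keep]


def _stamp_balls(vol, pts_um, radius_um, voxel_size_um) -> None:
    dx, dy, dz = voxel_size_um
    off, _ = _ball_offsets(radius_um, voxel_size_um)
    # voxel centre at index i is at i * voxel_size
    centers = np.round(pts_um[:, ::-1] / np.array([dz, dy, dx])).astype(int)
    idx = centers[:, None, :] + off[None, :, :]
    idx = idx.reshape(-1, 3)
    shape = np.array(vol.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[ok]
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True


def render_stack(graph: VesselGraph, spec: RenderSpec) -> ImageStack:
    """Render a graph to a two-channel stack (endothelium, perfusion)."""
    if graph.domain_size_um is None:
        raise ValueError("graph has no domain size; cannot infer render volume")
    lx, ly, lz = graph.domain_size_um
    dx, dy, dz = spec.voxel_size_um
    shape = (max(1, int(round(lz / dz))), max(1, int(round(ly / dy))), max(1, int(round(lx / dx))))

    if graph.branches:
        dmin = min(b.mean_diameter_um for b in graph.branches)
        if dmin < max(spec.voxel_size_um):
            log.warning(
                "smallest vessel diameter %.2f um is below the voxel size %s um: "
                "sub-resolution vessels will render poorly", dmin, spec.voxel_size_um,
            )

    vessel = rasterize_tubes(graph, shape, spec.voxel_size_um, perfused_only=False)
    perf = rasterize_tubes(graph, shape, spec.voxel_size_um, perfused_only=True)

    rng = np.random.default_rng(spec.seed)
    channels = []
    for binary in (vessel, perf):
        img = spec.background_level + (spec.signal_level - spec.background_level) * binary
        img = img.astype(np.float32)
        if any(s > 0 for s in spec.psf_sigma_um):
            sig_vox = (
                spec.psf_sigma_um[2] / dz,
                spec.psf_sigma_um[1] / dy,
                spec.psf_sigma_um[0] / dx,
            )
            img = gaussian_filter(img, sigma=sig_vox)
        if spec.noise_model == "gaussian" and spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)
        elif spec.noise_model == "poisson":
            img = rng.poisson(np.clip(img, 0, None) * spec.noise_scale).astype(np.float32) / spec.noise_scale
        channels.append(img)

    return ImageStack(
        data=np.stack(channels),
        voxel_size_um=spec.voxel_size_um,
        channels=(CHANNEL_ENDOTHELIUM, CHANNEL_PERFUSION),
        meta={"render": {"psf_sigma_um": list(spec.psf_sigma_um), "noise_model": spec.noise_model,
                         "signal_level": spec.signal_level, "background_level": spec.background_level,
                         "seed": spec.seed}},
    )
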