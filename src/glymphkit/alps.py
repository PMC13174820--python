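"""DTI-ALPS: diffusion along the perivascular space index.

At the level of the lateral ventricle bodies, medullary veins (and their
perivascular spaces) run left-right (x), perpendicular both to projection
fibers (z, in the corona radiata) and association fibers (y, in the superior
longitudinal fasciculus).  Diffusivity along x that exceeds the diffusivities
along the local fiber axes therefore indicates water movement along the
perivascular channel, and the index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

is a proxy for perivenous efflux integrity (1 = no perivascular contribution).

ROIs are supplied as voxel sets or masks; automatic template-based placement
is out of scope.  Diffusivities come from a conventional single-tensor fit by
default (see :func:`glymphkit.bitensor.fit_dti_volume`); a tissue-tensor field
may be substituted by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError

__all__ = ["AlpsRoiSpec", "AlpsResult", "compute_alps", "make_alps_phantom_rois"]

Voxel = tuple[int, int, int]


@dataclass(frozen=True)
class AlpsRoiSpec:
    """Projection- and association-fiber ROIs for one hemisphere (or bilateral).

    ``proj_voxels``: corona-radiata ROI, dominant fiber axis z.
    ``assoc_voxels``: superior-longitudinal-fasciculus ROI, dominant axis y.
    """

    proj_voxels: tuple[Voxel, ...]
    assoc_voxels: tuple[Voxel, ...]
    side: str = "bilateral"

    def __post_init__(self) -> None:
        proj = tuple(tuple(int(i) for i in v) for v in self.proj_voxels)
        assoc = tuple(tuple(int(i) for i in v) for v in self.assoc_voxels)
        if not proj or not assoc:
            raise InputError("ALPS ROIs must be nonempty")
        if set(proj) & set(assoc):
            raise InputError("projection and association ROIs overlap")
        if self.side not in ("left", "right", "bilateral"):
            raise InputError(f"unknown side {self.side!r}")
        object.__setattr__(self, "proj_voxels", proj)
        object.__setattr__(self, "assoc_voxels", assoc)


@dataclass(frozen=True)
class AlpsResult:
    Dxx_proj: float
    Dxx_assoc: float
    Dyy_proj: float
    Dzz_assoc: float
    alps_index: float
    side: str = "bilateral"

    def to_dict(self) -> dict:
        return {
            "Dxx_proj": self.Dxx_proj,
            "Dxx_assoc": self.Dxx_assoc,
            "Dyy_proj": self.Dyy_proj,
            "Dzz_assoc": self.Dzz_assoc,
            "alps_index": self.alps_index,
            "side": self.side,
        }


def _roi_mean(vol: np.ndarray, voxels: Sequence[Voxel], what: str) -> float:
    vals = np.array([vol[v] for v in voxels], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InputError(f"ALPS ROI '{what}' has no finite voxels")
    m = float(vals.mean())
    if m < 0:
        tol = 1e-6 * max(1.0, float(np.nanmax(np.abs(vol))))
        if m < -tol:
            warnings.warn(f"negative mean diffusivity in ROI '{what}' clamped to 0",
                          stacklevel=3)
        m = 0.0
    return m


def compute_alps(
    Dxx: np.ndarray,
    Dyy: np.ndarray,
    Dzz: np.ndarray,
    rois: AlpsRoiSpec,
) -> AlpsResult:
    """Compute the ALPS index from directional diffusivity maps and ROIs.

    ROI means use finite voxels only; negative means are clamped to zero with
    a warning.  For a bilateral analysis compute left and right separately and
    average with :func:`numpy.mean` of the two indices.
    """
    if not (Dxx.shape == Dyy.shape == Dzz.shape):
        raise InputError("diffusivity maps must share one grid")
    dxx_p = _roi_mean(Dxx, rois.proj_voxels, "proj")
    dxx_a = _roi_mean(Dxx, rois.assoc_voxels, "assoc")
    dyy_p = _roi_mean(Dyy, rois.proj_voxels, "proj")
    dzz_a = _roi_mean(Dzz, rois.assoc_voxels, "assoc")
    denom = (dyy_p + dzz_a) / 2.0
    if denom <= 0:
        raise InputError("ALPS denominator is non-positive")
    index = (dxx_p + dxx_a) / 2.0 / denom
    return AlpsResult(Dxx_proj=dxx_p, Dxx_assoc=dxx_a, Dyy_proj=dyy_p,
                      Dzz_assoc=dzz_a, alps_index=index, side=rois.side)


def bilateral_alps(left: AlpsResult, right: AlpsResult) -> float:
    """Bilateral index = arithmetic mean of the unilateral indices."""
    return (left.alps_index + right.alps_index) / 2.0


def make_alps_phantom_rois(
    shape: tuple[int, int, int],
    roi_size: int = 2,
    separation: int = 2,
    side: str = "bilateral",
) -> AlpsRoiSpec:
    """Deterministically place two disjoint cubic ROIs on a phantom grid.

    The two cubic ROIs straddle the grid center along y, separated by
    ``separation`` voxels.  Raises if the grid cannot hold both.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise InputError("grid must be 3-D")
    c = [s // 2 for s in shape]
    half = roi_size // 2
    shift = (roi_size + separation + 1) // 2

    def cube(center) -> list[Voxel]:
        vox = []
        for dx in range(roi_size):
            for dy in range(roi_size):
                for dz in range(roi_size):
                    v = (center[0] - half + dx, center[1] - half + dy, center[2] - half + dz)
                    if not all(0 <= v[i] < shape[i] for i in range(3)):
                        raise InputError("ALPS phantom ROI falls outside the grid")
                    vox.append(v)
        return vox

    proj = cube((c[0], c[1] - shift, c[2]))
    assoc = cube((c[0], c[1] + shift, c[2]))
    return AlpsRoiSpec(proj_voxels=tuple(proj), assoc_voxels=tuple(assoc), side=side)
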