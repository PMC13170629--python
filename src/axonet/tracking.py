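"""Deterministic FACT streamline tracking and connectome construction.

FACT (fiber assignment by continuous tracking) propagates a path voxel to
voxel along each voxel's principal diffusion direction: the ray advances to
the boundary of the current voxel and continues with the next voxel's
direction, without sub-voxel interpolation. Eight seeds are launched per
masked voxel (at the voxel's octant centers) and tracked in both directions
along the local eigenvector; the two half-tracks are merged into one
polyline. A half-track stops when it enters a voxel with FA below the
threshold (low_fa), when the turn between successive voxel directions
exceeds the angle limit (sharp_angle), or when it exits the brain mask
(left_mask). The offending voxel is not added to the visited list.

Eigenvector sign is resolved per step: the next voxel's direction is
flipped to have a non-negative dot product with the incoming direction, and
the turn angle is computed after flipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import ConnectivityMatrix
from .phantom import TensorFieldVolume, ParcellationVolume, _exit_time

logger = logging.getLogger(__name__)

__all__ = ["Streamline", "StreamlineSet", "track_fact", "build_network",
           "write_streamlines"]

_OCTANTS = np.array([(sx, sy, sz)
                     for sx in (-0.25, 0.25)
                     for sy in (-0.25, 0.25)
                     for sz in (-0.25, 0.25)])


@dataclass
class Streamline:
    """One tracked fiber: polyline, visited voxels, per-end stop reasons."""
    points: np.ndarray                      # (k, 3) continuous coordinates
    visited: list[tuple[int, int, int]]     # ordered, no repeats
    reasons: tuple[str, str]                # (backward end, forward end)

    @property
    def termination_reason(self) -> str:
        """Stop reason of the forward end (spec surface)."""
        return self.reasons[1]

    def __len__(self):
        return len(self.visited)


class StreamlineSet(list):
    """List of :class:`Streamline` with the tracking parameters attached."""

    def __init__(self, streamlines=(), params: dict | None = None):
        super().__init__(streamlines)
        self.params = params or {}


def _half_track(volume, pos, vox, d, fa_min, angle_max_rad, max_steps):
    """Propagate one direction; returns (visited after seed, points, reason)."""
    shape = volume.shape
    fa, mask, dirs = volume.fa, volume.mask, volume.directions
    visited: list[tuple[int, int, int]] = []
    points = [pos.copy()]
    cos_min = np.cos(angle_max_rad)
    for _ in range(max_steps):
        t = _exit_time(pos, d, np.floor(pos))
        pos = pos + (t + 1e-6) * d
        nvox = tuple(np.floor(pos).astype(int))
        if nvox == vox:
            break  # numerically stuck; treat as mask exit
        if any(c < 0 or c >= s for c, s in zip(nvox, shape)) or not mask[nvox]:
            points.append(pos)
            return visited, points, "left_mask"
        if fa[nvox] < fa_min:
            points.append(pos)
            return visited, points, "low_fa"
        nd = dirs[nvox].copy()
        if float(nd @ d) < 0:
            nd = -nd
        if float(nd @ d) < cos_min - 1e-12:
            points.append(pos)
            return visited, points, "sharp_angle"
        vox, d = nvox, nd
        visited.append(nvox)
        points.append(pos.copy())
    return visited, points, "left_mask"


def track_fact(volume: TensorFieldVolume, seeds_per_voxel: int = 8,
               fa_min: float = 0.1, angle_max: float = 45.0,
               max_steps: int = 10000) -> StreamlineSet:
    """Track FACT streamlines from every masked voxel.

    Parameters
    ----------
    seeds_per_voxel : int
        Number of seeds per voxel, taken in order from the eight octant
        centers (offsets of +/-1/4 voxel from the center).
    fa_min : float
        FA stopping threshold, in (0, 1).
    angle_max : float
        Maximum allowed turn in degrees, in (0, 90].
    """
    if not 0 < fa_min < 1:
        raise ValueError("fa_min must lie in (0, 1)")
    if not 0 < angle_max <= 90:
        raise ValueError("angle_max must lie in (0, 90] degrees")
    if not 1 <= seeds_per_voxel <= 8:
        raise ValueError("seeds_per_voxel must lie in 1..8")
    angle_rad = np.deg2rad(angle_max)

    out = StreamlineSet(params=dict(seeds_per_voxel=seeds_per_voxel,
                                    fa_min=fa_min, angle_max=angle_max))
    for vox in zip(*np.nonzero(volume.mask)):
        center = np.asarray(vox, float) + 0.5
        if volume.fa[vox] < fa_min:
            for s in range(seeds_per_voxel):
                p = center + _OCTANTS[s]
                out.append(Streamline(np.array([p]), [vox],
                                      ("low_fa", "low_fa")))
            continue
        d0 = volume.directions[vox]
        for s in range(seeds_per_voxel):
            p = center + _OCTANTS[s]
            fwd_vis, fwd_pts, fwd_r = _half_track(
                volume, p.copy(), vox, d0.copy(), fa_min, angle_rad, max_steps)
            bwd_vis, bwd_pts, bwd_r = _half_track(
                volume, p.copy(), vox, -d0.copy(), fa_min, angle_rad, max_steps)
            visited = list(reversed(bwd_vis)) + [vox] + fwd_vis
            pts = np.array(list(reversed(bwd_pts)) + fwd_pts[1:])
            out.append(Streamline(pts, visited, (bwd_r, fwd_r)))
    return out


def build_network(streamlines: StreamlineSet,
                  parcellation: ParcellationVolume,
                  fa_volume: np.ndarray | TensorFieldVolume
                  ) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Aggregate streamlines into FA- and NOS-weighted matrices.

    A streamline contributes to edge (A, B) iff it visits at least one
    voxel labeled A and one labeled B (pass-through rule). NOS[A, B] counts
    contributing streamlines; FA[A, B] is the traversal-weighted mean of
    voxel FA over all voxels crossed by contributing streamlines, each
    crossing counted once. A streamline visiting more than two labels
    serves every pair, so total NOS can exceed the streamline count only
    in that case.
    """
    fa_grid = fa_volume.fa if isinstance(fa_volume, TensorFieldVolume) \
        else np.asarray(fa_volume)
    if fa_grid.shape != parcellation.labels.shape:
        raise ValueError("parcellation and FA volume shapes differ")
    ids = sorted(parcellation.node_table)
    n = len(ids)
    pos = {node_id: i for i, node_id in enumerate(ids)}
    names = [parcellation.node_table[i][0] for i in ids]
    nos = np.zeros((n, n))
    fa_sum = np.zeros((n, n))
    fa_cnt = np.zeros((n, n))
    if len(streamlines) == 0:
        logger.warning("empty streamline set; returning zero matrices")
    for sl in streamlines:
        hit = {parcellation.labels[v] for v in sl.visited}
        hit.discard(0)
        if len(hit) < 2:
            continue
        fa_vals = [fa_grid[v] for v in sl.visited]
        s, c = float(np.sum(fa_vals)), len(fa_vals)
        for a in hit:
            for b in hit:
                if a < b:
                    i, j = pos[a], pos[b]
                    nos[i, j] += 1
                    fa_sum[i, j] += s
                    fa_cnt[i, j] += c
    nos = nos + nos.T
    with np.errstate(invalid="ignore"):
        fa = np.where(fa_cnt > 0, fa_sum / np.maximum(fa_cnt, 1), 0.0)
    fa = fa + fa.T
    return (ConnectivityMatrix(fa, "FA", names),
            ConnectivityMatrix(nos, "NOS", names))


def write_streamlines(path, streamlines: StreamlineSet) -> None:
    """Plain-text polyline export (one block per streamline)."""
    with open(path, "w") as fh:
        fh.write(f"# axonet streamlines, params={streamlines.params}\n")
        for k, sl in enumerate(streamlines):
            fh.write(f"> streamline {k} reasons={sl.reasons[0]},"
                     f"{sl.reasons[1]} n_voxels={len(sl.visited)}\n")
            for p in sl.points:
                fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
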