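"""Programmatic tensor-field phantoms for exercising the streamline tracker.

A phantom is a pair (:class:`TensorFieldVolume`, :class:`ParcellationVolume`)
built from bundle primitives: straight tubes, low-FA gap tubes, constant-
curvature arc chains, and orthogonal crossings. Each bundle's two end-cap
voxels are labeled as distinct parcellation nodes, so tracked phantoms can
be turned into connectivity matrices.

Phantoms are deterministic given their spec; the ``seed`` argument exists
for API symmetry with the other generators and currently only perturbs
nothing (all primitives are exact constructions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TensorFieldVolume", "ParcellationVolume",
    "StraightTube", "ArcChain", "Crossing", "PhantomSpec",
    "generate_phantom",
]


@dataclass
class TensorFieldVolume:
    """Per-voxel principal diffusion direction, FA, and brain mask."""
    directions: np.ndarray   # (X, Y, Z, 3), unit norm inside mask
    fa: np.ndarray           # (X, Y, Z) in [0, 1]
    mask: np.ndarray         # (X, Y, Z) bool

    def __post_init__(self):
        if self.fa.min() < 0 or self.fa.max() > 1:
            raise ValueError("FA must lie in [0, 1]")
        norms = np.linalg.norm(self.directions[self.mask], axis=-1)
        if self.mask.any() and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("principal directions must be unit vectors "
                             "inside the mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fa.shape

    def save(self, prefix) -> None:
        """Write fa/mask/directions as plain-text grids + JSON sidecar."""
        prefix = Path(prefix)
        np.savetxt(f"{prefix}.fa.txt", self.fa.reshape(self.fa.shape[0], -1))
        np.savetxt(f"{prefix}.mask.txt",
                   self.mask.reshape(self.mask.shape[0], -1), fmt="%d")
        np.savetxt(f"{prefix}.dir.txt",
                   self.directions.reshape(self.directions.shape[0], -1))
        Path(f"{prefix}.json").write_text(json.dumps(
            {"shape": list(self.shape), "spacing_mm": [1, 1, 1]}))

    @classmethod
    def load(cls, prefix) -> "TensorFieldVolume":
        prefix = Path(prefix)
        meta = json.loads(Path(f"{prefix}.json").read_text())
        shape = tuple(meta["shape"])
        fa = np.loadtxt(f"{prefix}.fa.txt").reshape(shape)
        mask = np.loadtxt(f"{prefix}.mask.txt").reshape(shape).astype(bool)
        dirs = np.loadtxt(f"{prefix}.dir.txt").reshape(shape + (3,))
        return cls(dirs, fa, mask)


@dataclass
class ParcellationVolume:
    """Integer label per voxel (0 = background) plus the node table."""
    labels: np.ndarray                       # (X, Y, Z) int
    node_table: dict[int, tuple[str, str]]   # id -> (name, cortical|subcortical)

    def __post_init__(self):
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.node_table)
        if missing:
            raise ValueError(f"labels without node-table entries: {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_table)


@dataclass
class StraightTube:
    """Axis-aligned single-voxel-thick tube.

    ``fa_profile`` overrides the constant FA with one value per voxel along
    the tube (used for low-FA gaps and segment-wise FA tests).
    """
    start: tuple[int, int, int]
    length: int
    fa: float = 0.6
    axis: int = 0
    fa_profile: list[float] | None = None
    node_a: str = "tube_A"
    node_b: str = "tube_B"


@dataclass
class ArcChain:
    """Constant per-step turn chain in the xy-plane.

    Built by marching a ray from the start voxel's center: the k-th chain
    voxel carries the in-plane direction at angle ``k * turn_deg``, so a
    tracked streamline turns by exactly ``turn_deg`` at every step.
    """
    start: tuple[int, int, int]
    n_steps: int
    turn_deg: float
    fa: float = 0.6
    node_a: str = "arc_A"
    node_b: str = "arc_B"


@dataclass
class Crossing:
    """Two orthogonal tubes (x- and y-axis) sharing a crossing block.

    In the shared voxels the direction field is assigned to the x-tube's
    direction (first-bundle-wins rule, documented here); the y-tube is
    therefore interrupted at the crossing for a deterministic tracker.
    """
    center: tuple[int, int, int]
    arm: int = 4
    fa: float = 0.6
    names: tuple[str, str, str, str] = ("cross_xA", "cross_xB",
                                        "cross_yA", "cross_yB")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    bundles: list = field(default_factory=list)


def generate_phantom(spec: PhantomSpec, seed: int = 0
                     ) -> tuple[TensorFieldVolume, ParcellationVolume]:
    """Materialize a phantom spec into tensor-field and parcellation volumes."""
    del seed  # exact construction; kept for generator API symmetry
    shape = tuple(spec.shape)
    fa = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    dirs = np.zeros(shape + (3,))
    labels = np.zeros(shape, dtype=int)
    node_table: dict[int, tuple[str, str]] = {}
    next_id = [1]

    def add_node(name: str, voxel) -> None:
        if labels[voxel] != 0:
            raise ValueError(
                f"overlapping parcellation labels at voxel {voxel}")
        node_table[next_id[0]] = (name, "cortical")
        labels[voxel] = next_id[0]
        next_id[0] += 1

    def put(voxel, d, f):
        mask[voxel] = True
        fa[voxel] = f
        dirs[voxel] = np.asarray(d, float) / np.linalg.norm(d)

    for bundle in spec.bundles:
        if isinstance(bundle, StraightTube):
            x0 = np.asarray(bundle.start, int)
            step = np.zeros(3, int)
            step[bundle.axis] = 1
            prof = bundle.fa_profile or [bundle.fa] * bundle.length
            if len(prof) != bundle.length:
                raise ValueError("fa_profile length must equal tube length")
            voxels = [tuple(x0 + i * step) for i in range(bundle.length)]
            for v, f in zip(voxels, prof):
                put(v, step, f)
            add_node(bundle.node_a, voxels[0])
            add_node(bundle.node_b, voxels[-1])
        elif isinstance(bundle, ArcChain):
            voxels = _march_arc(bundle, shape)
            for k, v in enumerate(voxels):
                ang = np.deg2rad(k * bundle.turn_deg)
                put(v, (np.cos(ang), np.sin(ang), 0.0), bundle.fa)
            add_node(bundle.node_a, voxels[0])
            add_node(bundle.node_b, voxels[-1])
        elif isinstance(bundle, Crossing):
            cx, cy, cz = bundle.center
            xa = [(x, cy, cz) for x in range(cx - bundle.arm, cx + bundle.arm + 1)]
            ya = [(cx, y, cz) for y in range(cy - bundle.arm, cy + bundle.arm + 1)]
            for v in ya:
                put(v, (0, 1, 0), bundle.fa)
            for v in xa:           # x-tube wins in the shared block
                put(v, (1, 0, 0), bundle.fa)
            add_node(bundle.names[0], xa[0])
            add_node(bundle.names[1], xa[-1])
            add_node(bundle.names[2], ya[0])
            add_node(bundle.names[3], ya[-1])
        else:
            raise TypeError(f"unknown bundle primitive {type(bundle).__name__}")

    return (TensorFieldVolume(dirs, fa, mask),
            ParcellationVolume(labels, node_table))


def _march_arc(bundle: ArcChain, shape) -> list[tuple[int, int, int]]:
    """Voxel chain visited by a ray turning ``turn_deg`` at each voxel."""
    pos = np.asarray(bundle.start, float) + 0.5
    vox = np.asarray(bundle.start, int)
    voxels = [tuple(vox)]
    eps = 1e-9
    for k in range(bundle.n_steps):
        ang = np.deg2rad(k * bundle.turn_deg)
        d = np.array([np.cos(ang), np.sin(ang), 0.0])
        while tuple(np.floor(pos + eps).astype(int)) == voxels[-1]:
            t = _exit_time(pos, d, np.floor(pos))
            pos = pos + (t + 1e-6) * d
        nvox = tuple(np.floor(pos).astype(int))
        if any(c < 0 or c >= s for c, s in zip(nvox, shape)):
            raise ValueError("arc chain leaves the volume; enlarge shape "
                             "or reduce n_steps")
        if nvox in voxels:
            raise ValueError("arc chain revisits a voxel; reduce n_steps")
        voxels.append(nvox)
    return voxels


def _exit_time(pos: np.ndarray, d: np.ndarray, lo: np.ndarray) -> float:
    """Ray-box exit time from the unit voxel [lo, lo+1)."""
    ts = []
    for ax in range(3):
        if d[ax] > 1e-12:
            ts.append((lo[ax] + 1.0 - pos[ax]) / d[ax])
        elif d[ax] < -1e-12:
            ts.append((lo[ax] - pos[ax]) / d[ax])
    if not ts:
        raise ValueError("zero direction vector")
    return max(min(ts), 0.0)
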