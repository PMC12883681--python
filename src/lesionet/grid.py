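"""Shared sampling grid for all volumes in an analysis.

Every mask, scan and statistic map in one analysis must live on a single
common grid (one shape, one voxel-to-world affine).  Registration is out of
scope: inputs are assumed pre-aligned, and any grid mismatch is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "GridMismatchError"]

#: absolute tolerance when comparing affines read from disk
AFFINE_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when a volume does not share the analysis reference grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling grid: array shape plus voxel-to-world affine.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels per axis, each >= 1.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm transform (homogeneous). Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        self.affine.setflags(write=False)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 2.0) -> "VolumeGrid":
        """Axis-aligned grid with cubic voxels, origin at the volume centre."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([voxel_mm] * 3 + [1.0])
        affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
        return cls(shape, affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(np.linalg.norm(self.affine[:3, i]) for i in range(3))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def check_same(self, other: "VolumeGrid", what: str = "volume") -> None:
        """Raise :class:`GridMismatchError` unless ``other`` matches bit-for-bit tolerance."""
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch for {what}: shape {other.shape} / affine differs "
                f"from reference shape {self.shape}"
            )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out.squeeze()

    def __eq__(self, other: object) -> bool:  # exact, for "bit-equal" invariants
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))
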