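"""Rigid-body poses: a translation plus a unit quaternion.

A pose maps reference coordinates x to ``R (x - c0) + c0 + t`` where ``c0``
is the reference centroid, so the rotation acts about the molecule's own
centroid and the posed centroid is ``c0 + t``.  Quaternions follow the
scipy scalar-last convention and are renormalized after every composition.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidPose"]


@dataclasses.dataclass
class RigidPose:
    translation: np.ndarray
    quaternion: np.ndarray  # (x, y, z, w)

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        norm = np.linalg.norm(q)
        if norm == 0:
            raise ValueError("zero quaternion")
        self.quaternion = q / norm

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    def apply(self, positions: np.ndarray, centroid: np.ndarray) -> np.ndarray:
        """Pose reference coordinates (rotation about ``centroid``, then shift)."""
        return self.rotation.apply(positions - centroid) + centroid + self.translation

    def compose(self, delta_translation: np.ndarray, delta_rotation: Rotation) -> "RigidPose":
        """New pose with the increment applied on top (rotation pre-multiplied)."""
        q = (delta_rotation * self.rotation).as_quat()
        return RigidPose(self.translation + delta_translation, q)

    def copy(self) -> "RigidPose":
        return RigidPose(self.translation.copy(), self.quaternion.copy())
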