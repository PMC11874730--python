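"""Helpers shared across test modules."""

import numpy as np

from spiralcine.trajectory import SpiralTrajectory


def cartesian_traj(n: int) -> SpiralTrajectory:
    """Full Cartesian sampling expressed as n arms of n samples."""
    k = (np.arange(n) - n // 2) / n
    ky, kx = np.meshgrid(k, k, indexing="ij")
    arms = np.stack([ky, kx], axis=-1)
    return SpiralTrajectory(arm_coords=arms, n_arms=n, dwell_time=1e-5,
                            rotation_offset=0.0, fov_mm=float(n),
                            resolution_mm=1.0)
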