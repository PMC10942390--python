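import numpy as np
import pytest

from cellscene import coords, fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_frame():
    """Tomogram geometry at typical CryoET scales: 256^2 x 128 voxels, 5 Å/voxel."""
    return coords.TomogramFrame(np.array([256.0, 256.0, 128.0]), 5.0)


@pytest.fixture
def toy_structure_pair():
    """(Structure, pdb_text) with 2 chains x 3 atoms."""
    return fixtures.make_toy_structure(2, 3, seed=1)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method), test-local oracle."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle between two rotations, degrees.

    Uses the Frobenius-norm form 2*arcsin(|Ra-Rb|_F / (2*sqrt(2))), which
    keeps full floating precision for near-identical rotations (the trace
    formula loses half the digits near zero).
    """
    d = np.linalg.norm(Ra - Rb) / (2.0 * np.sqrt(2.0))
    return float(np.degrees(2.0 * np.arcsin(min(d, 1.0))))


def parallel_transport_frames(samples, n0):
    """Discrete parallel transport of a normal along (point, tangent) samples.

    First-order reference method, independent of the double-reflection
    implementation: each step rotates the normal by the smallest rotation
    aligning consecutive tangents.
    """
    out = [(samples[0][0], samples[0][1], np.asarray(n0, dtype=float))]
    n = np.asarray(n0, dtype=float)
    for k in range(1, len(samples)):
        p, t = samples[k]
        tp = out[-1][1]
        ax = np.cross(tp, t)
        s = np.linalg.norm(ax)
        c = float(tp @ t)
        if s > 1e-15:
            ax = ax / s
            ang = np.arctan2(s, c)
            K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
            n = R @ n
        n = n - (n @ t) * t
        n /= np.linalg.norm(n)
        out.append((p, t, n))
    return out
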