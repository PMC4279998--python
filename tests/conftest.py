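import math

import numpy as np
import pytest

import localtf as lt


def brute_force_delta(vol, fv, edit):
    """Independent triple-loop evaluation of the per-voxel shift formula."""
    nx, ny, nz = vol.shape
    i0, j0, k0 = edit.x0
    I0 = vol.data[i0, j0, k0]
    out = np.empty(vol.shape)
    sp = vol.spacing
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if edit.metric == "orientation":
                    e, e0 = fv.e3[i, j, k], fv.e3[i0, j0, k0]
                    d_F = 1.0 - abs(float(np.dot(e, e0)))
                elif edit.metric == "lambda_ratio":
                    d_F = (
                        abs(fv.lambda_ratio[i, j, k] - fv.lambda_ratio[i0, j0, k0])
                        / fv.sigma_lambda
                    )
                elif edit.metric == "mahalanobis":
                    diff = fv.feature_at((i, j, k)) - fv.feature_at((i0, j0, k0))
                    d_F = math.sqrt(float(diff @ np.linalg.inv(fv.covariance) @ diff))
                else:  # dot
                    c = fv.feature_at((i, j, k))
                    c0 = fv.feature_at((i0, j0, k0))
                    n, n0 = np.linalg.norm(c), np.linalg.norm(c0)
                    c = c / n if n > 0 else c
                    c0 = c0 / n0 if n0 > 0 else c0
                    d_F = 1.0 - float(np.dot(c, c0))
                d_E = min(
                    math.sqrt(
                        sum(((p[a] - [i, j, k][a]) * sp[a] / sp[0]) ** 2 for a in range(3))
                    )
                    for p in edit.stroke_centers
                )
                g = math.exp(-edit.alpha * d_F) / (1.0 + math.exp(d_E - edit.beta))
                out[i, j, k] = (I0 - vol.data[i, j, k]) * g
    return out


def axis_voxels(scene, sid):
    """Integer voxels lying on (within half a voxel of) tube ``sid``'s axis."""
    meta = scene.structures[sid]
    point = np.asarray(meta["point"])
    direction = np.asarray(meta["direction"])
    shape = np.asarray(scene.volume.shape)
    length = float(np.linalg.norm(shape))
    seen = set()
    out = []
    for t in np.arange(-length, length, 0.25):
        idx = np.rint(point + t * direction).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            continue
        key = tuple(idx)
        if key in seen:
            continue
        seen.add(key)
        rel = idx - point
        d2 = rel @ rel - (rel @ direction) ** 2
        if d2 <= 0.5 and scene.labels[key] == sid:
            out.append(key)
    return out


@pytest.fixture(scope="session")
def ramp_tf():
    """Grayscale ramp preset: transparent below 0.2, fully visible above 0.9."""
    return lt.TransferFunction1D.grayscale_ramp(threshold=0.2, full=0.9)


@pytest.fixture(scope="session")
def tube_volume():
    """Noiseless diagonal tube through a 32^3 grid, with its axis mask."""
    direction = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    vol, mask = lt.make_tube((32, 32, 32), (16, 16, 16), direction, radius=2.0, peak=0.9)
    return vol, mask, direction


@pytest.fixture(scope="session")
def tube_features(tube_volume):
    vol, _, _ = tube_volume
    return lt.build_feature_volume(vol, scale=1.0)


@pytest.fixture(scope="session")
def small_scene():
    """A compact seeded crossing scene for pipeline-level tests."""
    return lt.make_crossing_scene(shape=(48, 48, 48), n_tubes_per_family=2, seed=7)
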