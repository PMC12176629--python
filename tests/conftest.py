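import numpy as np
import pytest

from rimpet import LabelMap, Volume3D, simulate_reference_tac


@pytest.fixture(scope="session")
def reference_tac():
    """Gamma-variate reference TAC on the default 60-min framing."""
    return simulate_reference_tac()


@pytest.fixture()
def voxel_sphere():
    """A 4-mm-radius sphere voxelised at 1-mm isotropic voxels, centred on
    a voxel centre, inside a 26^3 grid — room for 4-mm shells."""
    n = 26
    coords = np.meshgrid(*[(np.arange(n) + 0.5)] * 3, indexing="ij")
    c = n / 2 + 0.5
    r = np.sqrt(sum((g - c) ** 2 for g in coords))
    labels = LabelMap((r <= 4).astype(np.uint16))
    return labels, r


def brute_force_boundary_distance(lesion: np.ndarray, spacing) -> np.ndarray:
    """O(N*M) oracle: distance from every voxel centre to the nearest
    midpoint of a face separating lesion from background voxels (grid-hull
    faces of edge lesion voxels included); 0 inside the lesion."""
    sp = np.asarray(spacing, float)
    n = lesion.shape
    mids = []
    for ax in range(3):
        for idx in np.argwhere(lesion):
            for direction in (-1, 1):
                nb = idx.copy()
                nb[ax] += direction
                outside = not (0 <= nb[ax] < n[ax])
                if outside or not lesion[tuple(nb)]:
                    m = (idx + 0.5) * sp
                    m[ax] += direction * sp[ax] / 2.0
                    mids.append(m)
    mids = np.array(mids)
    centers = (np.indices(n).reshape(3, -1).T + 0.5) * sp
    out = np.empty(len(centers))
    for i, p in enumerate(centers):
        out[i] = np.sqrt(((mids - p) ** 2).sum(axis=1)).min()
    out = out.reshape(n)
    out[lesion] = 0.0
    return out
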