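import numpy as np
import pytest

from contoureval import ImageGeometry, StructureMask


def make_mask(arr, spacing=(0.1, 0.1, 0.1), origin=(0.0, 0.0, 0.0), organ="", provenance=""):
    arr = np.asarray(arr)
    geom = ImageGeometry(shape=arr.shape, spacing=spacing, origin=origin)
    return StructureMask(geometry=geom, voxels=arr, organ=organ, provenance=provenance)


def cube_mask(grid_shape, lo, size, spacing=(0.1, 0.1, 0.1), **kw):
    """Axis-aligned solid cube of `size` voxels starting at index `lo`."""
    arr = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(l, l + s) for l, s in zip(np.broadcast_to(lo, 3), np.broadcast_to(size, 3)))
    arr[sl] = True
    return make_mask(arr, spacing=spacing, **kw)


def brute_force_directed(a_pts, b_pts):
    """O(n*m) all-pairs nearest distances: the oracle for surface metrics."""
    from scipy.spatial.distance import cdist

    return cdist(np.atleast_2d(a_pts), np.atleast_2d(b_pts)).min(axis=1)


def brute_force_surface_indices(occ):
    """Occupied voxels with an unoccupied (or out-of-grid) 6-neighbor."""
    out = []
    nx, ny, nz = occ.shape
    for i, j, k in np.argwhere(occ):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz) or not occ[ii, jj, kk]:
                out.append((i, j, k))
                break
    return np.array(out, dtype=int).reshape(-1, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask_pair(rng):
    """Two random blob-like masks on a shared small grid (both nonempty)."""

    def _make(max_side=15, spacing=(0.1, 0.1, 0.1)):
        shape = tuple(int(s) for s in rng.integers(4, max_side + 1, size=3))
        masks = []
        for _ in range(2):
            arr = rng.random(shape) < 0.3
            if not arr.any():
                arr[tuple(rng.integers(0, s) for s in shape)] = True
            masks.append(make_mask(arr, spacing=spacing))
        return masks[0], masks[1]

    return _make
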