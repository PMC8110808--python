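import numpy as np
import pytest


def flood_fill_label(binary: np.ndarray, connectivity: int = 4) -> tuple[np.ndarray, int]:
    """Independent brute-force connected-component labeller (BFS flood fill).

    Used as an oracle against the package's spot labelling; deliberately
    implemented without scipy.
    """
    binary = np.asarray(binary, dtype=bool)
    ny, nx = binary.shape
    labels = np.zeros((ny, nx), dtype=int)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    current = 0
    for i in range(ny):
        for j in range(nx):
            if binary[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx \
                                and binary[yy, xx] and labels[yy, xx] == 0:
                            labels[yy, xx] = current
                            stack.append((yy, xx))
    return labels, current


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label maps define the same partition of foreground."""
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
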