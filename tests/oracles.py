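"""Independent brute-force oracles used to cross-check the fast implementations."""

from collections import deque

import numpy as np


def brute_force_pearson(a: np.ndarray, b: np.ndarray, sel: np.ndarray) -> float:
    """Textbook Pearson correlation over selected voxels, by explicit loops."""
    xs, ys = [], []
    ni, nj, nk = a.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if sel[i, j, k]:
                    xs.append(a[i, j, k])
                    ys.append(b[i, j, k])
    xs, ys = np.array(xs), np.array(ys)
    num = ((xs - xs.mean()) * (ys - ys.mean())).sum()
    den = np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
    return float(num / den)


def brute_force_components(peaks: np.ndarray) -> list[frozenset]:
    """26-connectivity connected components by breadth-first flood fill."""
    shape = peaks.shape
    seen = np.zeros(shape, dtype=bool)
    components = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(peaks)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = set()
        while queue:
            vox = queue.popleft()
            comp.add(vox)
            for off in offsets:
                nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
                if all(0 <= nb[d] < shape[d] for d in range(3)) and \
                        peaks[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(frozenset(comp))
    return components
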