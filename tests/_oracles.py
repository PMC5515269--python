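"""Independent brute-force oracles used by the test suite."""

from collections import deque
from itertools import product

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[int]:
    """Independent BFS labelling; returns sorted component sizes."""
    if connectivity == 6:
        offsets = [
            (dz, dy, dx)
            for dz, dy, dx in product((-1, 0, 1), repeat=3)
            if abs(dz) + abs(dy) + abs(dx) == 1
        ]
    else:  # 26
        offsets = [
            o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
        ]
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    nz, ny, nx = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in offsets:
                z2, y2, x2 = z + dz, y + dy, x + dx
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                    if binary[z2, y2, x2] and not seen[z2, y2, x2]:
                        seen[z2, y2, x2] = True
                        queue.append((z2, y2, x2))
        sizes.append(size)
    return sorted(sizes)
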