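"""On-lattice diffusion-limited aggregation kernel (numba-compiled)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def grow_dla(lattice_size: int, particle_count: int, seed: int) -> np.ndarray:  # pragma: no cover
    np.random.seed(seed)
    n = lattice_size
    grid = np.zeros((n, n), dtype=np.uint8)
    c = n // 2
    grid[c, c] = 1
    r_cluster = 1.0

    stuck = 1
    while stuck < particle_count:
        r_birth = r_cluster + 5.0
        r_kill = max(3.0 * r_cluster, 20.0)
        if r_kill > c - 2:
            r_kill = c - 2.0
        if r_birth > r_kill - 2:
            r_birth = r_kill - 2.0
        # spawn on the birth circle
        theta = np.random.uniform(0.0, 2.0 * np.pi)
        x = int(round(c + r_birth * np.cos(theta)))
        y = int(round(c + r_birth * np.sin(theta)))
        while True:
            step = np.random.randint(0, 4)
            if step == 0:
                x += 1
            elif step == 1:
                x -= 1
            elif step == 2:
                y += 1
            else:
                y -= 1
            dx = x - c
            dy = y - c
            d2 = dx * dx + dy * dy
            if d2 > r_kill * r_kill:
                break  # walker lost; respawn
            if x < 1 or x > n - 2 or y < 1 or y > n - 2:
                break
            if (
                grid[x + 1, y] == 1
                or grid[x - 1, y] == 1
                or grid[x, y + 1] == 1
                or grid[x, y - 1] == 1
            ):
                grid[x, y] = 1
                stuck += 1
                d = np.sqrt(d2)
                if d > r_cluster:
                    r_cluster = d
                break
    return grid
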