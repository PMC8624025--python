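"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/skimage and any hemitherm code path: component
labeling is a plain breadth-first flood fill over explicit neighbor offsets.
"""

from collections import deque

import numpy as np

_OFFS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFS8 = _OFFS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_components(mask, connectivity: int):
    """All connected components of a boolean mask as a list of frozensets."""
    mask = np.asarray(mask, dtype=bool)
    offs = _OFFS8 if connectivity == 8 else _OFFS4
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            comp = set()
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            comps.append(frozenset(comp))
    return comps
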