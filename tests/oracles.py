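"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid scipy.ndimage / skimage and recompute everything
pixel-by-pixel (spot detection) or codon-by-codon (uAUG scanning), so a test
comparing them against the package exercises two unrelated code paths.
"""

from __future__ import annotations

import numpy as np


def brute_force_spots(
    img: np.ndarray,
    window: int,
    k: float,
    min_area: int,
    max_area: int,
) -> list[frozenset[tuple[int, int]]]:
    """Per-pixel local median/MAD threshold + hand flood fill.

    Boundary handling is symmetric reflection (edge pixel duplicated), the
    same convention the fast path uses. Returns the set of spot masks.
    """
    h, w = img.shape
    half = window // 2
    padded = np.pad(img, half, mode="symmetric")

    local_median = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            block = padded[r : r + window, c : c + window]
            local_median[r, c] = sorted(block.ravel().tolist())[window * window // 2]

    dev = np.abs(img - local_median)
    dev_padded = np.pad(dev, half, mode="symmetric")
    local_mad = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            block = dev_padded[r : r + window, c : c + window]
            local_mad[r, c] = sorted(block.ravel().tolist())[window * window // 2]

    foreground = img > local_median + k * local_mad

    seen = np.zeros_like(foreground, dtype=bool)
    masks = []
    for r in range(h):
        for c in range(w):
            if not foreground[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            component = []
            while stack:
                rr, cc = stack.pop()
                component.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < h
                            and 0 <= nc < w
                            and foreground[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            if min_area <= len(component) <= max_area:
                masks.append(frozenset(component))
    return masks


def codon_walk_uaugs(utr: str) -> list[tuple[int, int, bool]]:
    """Enumerate (offset, frame, is_uorf) for every ATG by explicit codon walking."""
    n = len(utr)
    out = []
    for i in range(n):
        if utr[i : i + 3] != "ATG":
            continue
        frame = (n - i) % 3
        has_stop = False
        j = i + 3
        while j + 3 <= n:
            if utr[j : j + 3] in ("TAA", "TAG", "TGA"):
                has_stop = True
                break
            j += 3
        out.append((i, frame, has_stop))
    return out
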