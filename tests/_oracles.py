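"""Independent reference implementations used only to check the package.

These are deliberately naive (quadratic loops, dictionaries) and share no
code with the implementations they validate.
"""

from __future__ import annotations

import numpy as np


def ward_d2_linkage_brute(dist_matrix: np.ndarray) -> np.ndarray:
    """Brute-force Ward.D2 agglomeration via the Lance-Williams recursion.

    Input dissimilarities are squared inside the update:

        d(k, i+j)^2 = [ (n_i + n_k) d(k,i)^2 + (n_j + n_k) d(k,j)^2
                        - n_k d(i,j)^2 ] / (n_i + n_j + n_k)

    Returns a scipy-style linkage matrix (merged ids, height, size),
    scanning all active pairs at every step (no nearest-neighbor chain).
    """
    D0 = np.asarray(dist_matrix, dtype=float)
    n = D0.shape[0]
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = D0[i, j]
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    nxt = n
    Z = []

    def get(i: int, j: int) -> float:
        return d[(min(i, j), max(i, j))]

    while len(active) > 1:
        h, i, j = min((get(a, b), a, b) for a in active for b in active if a < b)
        ni, nj = sizes[i], sizes[j]
        new = nxt
        nxt += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            val2 = ((ni + nk) * get(i, k) ** 2 + (nj + nk) * get(j, k) ** 2
                    - nk * h ** 2) / (ni + nj + nk)
            d[(min(k, new), max(k, new))] = np.sqrt(val2)
        active -= {i, j}
        active.add(new)
        sizes[new] = ni + nj
        Z.append([min(i, j), max(i, j), h, sizes[new]])
    return np.array(Z)


def nearest_nucleus_assignment_brute(nuclei_labels: np.ndarray,
                                     ktr_ok: np.ndarray,
                                     ring_px: float) -> dict[tuple[int, int], set[int]]:
    """For each candidate ring pixel, the set of nuclei at minimal distance.

    Returns {(row, col): {labels at min distance}} for pixels outside
    all nuclei, within ``ring_px`` of the closest nucleus pixel, and
    passing the intensity gate ``ktr_ok``.  Ties keep every minimizer so
    the caller can accept either resolution.
    """
    ids = np.unique(nuclei_labels)
    ids = ids[ids > 0]
    pix = {int(l): np.argwhere(nuclei_labels == l) for l in ids}
    out: dict[tuple[int, int], set[int]] = {}
    h, w = nuclei_labels.shape
    for r in range(h):
        for c in range(w):
            if nuclei_labels[r, c] != 0 or not ktr_ok[r, c]:
                continue
            dists = {}
            for l, coords in pix.items():
                dd = np.sqrt(((coords - [r, c]) ** 2).sum(axis=1))
                dists[l] = dd.min()
            dmin = min(dists.values())
            if dmin <= ring_px:
                out[(r, c)] = {l for l, v in dists.items() if np.isclose(v, dmin)}
    return out


def grayscale_opening_background(image: np.ndarray, radius: int) -> np.ndarray:
    """Reference rolling-ball background: grayscale opening with a ball.

    Direct O(N * r^2) min/max sweep with the ball structuring function
    b(u, v) = sqrt(r^2 - u^2 - v^2) - r.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    uu, vv = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    inside = uu ** 2 + vv ** 2 <= radius ** 2
    ball = np.where(inside, np.sqrt(np.clip(radius ** 2 - uu ** 2 - vv ** 2, 0, None)) - radius,
                    -np.inf)
    pad = radius
    big = np.pad(img, pad, mode="edge")
    ero = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            win = big[r:r + 2 * pad + 1, c:c + 2 * pad + 1]
            ero[r, c] = np.min(np.where(inside, win - ball, np.inf))
    big = np.pad(ero, pad, mode="edge")
    opn = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            win = big[r:r + 2 * pad + 1, c:c + 2 * pad + 1]
            opn[r, c] = np.max(np.where(inside, win + ball, -np.inf))
    return opn
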