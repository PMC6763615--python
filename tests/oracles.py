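"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: spot sums loop
over every pixel, and Ward distances are recomputed from the original
dissimilarity matrix at every agglomeration step via the closed form
(no Lance-Williams recursion).
"""

import numpy as np


def brute_force_spot_sum(image, cx, cy, r):
    """Sum of all pixels whose centers lie within the disc, by full loop."""
    total = 0.0
    count = 0
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            if (j - cx) ** 2 + (i - cy) ** 2 <= r**2:
                total += float(image[i, j])
                count += 1
    return total, count


def ward_oracle(D):
    """Exhaustive Ward agglomeration over dissimilarity matrix D.

    At every step the inter-cluster Ward distance is recomputed from the
    original squared dissimilarities via the centroid identity

        ||c_A - c_B||^2 = mean cross d^2 - mean within-A d^2 / 2
                                         - mean within-B d^2 / 2
        ward^2(A, B)    = (2|A||B| / (|A|+|B|)) * ||c_A - c_B||^2

    (within-cluster means taken over all ordered pairs including the
    zero diagonal). Ties break on the lexicographically smallest cluster
    id pair. Returns [(id_i, id_j, height)] in scipy id convention.
    """
    D2 = np.asarray(D, dtype=float) ** 2
    n = D2.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n

    def wd2(A, B):
        a, b = clusters[A], clusters[B]
        na, nb = len(a), len(b)
        cross = D2[np.ix_(a, b)].mean()
        within_a = D2[np.ix_(a, a)].mean()
        within_b = D2[np.ix_(b, b)].mean()
        return (2.0 * na * nb / (na + nb)) * (cross - within_a / 2.0 - within_b / 2.0)

    for _ in range(n - 1):
        best = None
        ids = sorted(clusters)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                cand = (wd2(ids[x], ids[y]), ids[x], ids[y])
                if best is None or cand < best:
                    best = cand
        d2, i, j = best
        merges.append((i, j, float(np.sqrt(max(d2, 0.0)))))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges
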