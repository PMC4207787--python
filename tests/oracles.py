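"""Independent, deliberately naive reference implementations used as test
oracles.  None of these call the code paths they check."""

import numpy as np


def ward_agglomerate(d: np.ndarray) -> np.ndarray:
    """Greedy Ward agglomeration recomputing every merge height from scratch
    out of the original squared distances via the centroid identity:

        ||c_A - c_B||^2 = S_AB/(|A||B|) - S_AA/(2|A|^2) - S_BB/(2|B|^2)
        h^2(A, B)       = 2|A||B|/(|A|+|B|) * ||c_A - c_B||^2

    with S_XY the full double sum of squared distances between X and Y.
    Returns rows (id_i, id_j, height, size) in scipy linkage convention.
    """
    n = d.shape[0]
    d2 = d**2
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []

    def height2(a_members, b_members):
        a, b = len(a_members), len(b_members)
        s_ab = d2[np.ix_(a_members, b_members)].sum()
        s_aa = d2[np.ix_(a_members, a_members)].sum()
        s_bb = d2[np.ix_(b_members, b_members)].sum()
        c2 = s_ab / (a * b) - s_aa / (2 * a * a) - s_bb / (2 * b * b)
        return 2.0 * a * b / (a + b) * c2

    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                h2 = height2(clusters[ids[i]], clusters[ids[j]])
                if best is None or h2 < best[0]:
                    best = (h2, ids[i], ids[j])
        h2, ci, cj = best
        merged = clusters.pop(ci) + clusters.pop(cj)
        merges.append([ci, cj, np.sqrt(max(h2, 0.0)), len(merged)])
        clusters[next_id] = merged
        next_id += 1
    return np.array(merges)


def random_distance_matrix(rng: np.random.Generator, n: int,
                           low: float = 0.1, high: float = 5.0) -> np.ndarray:
    m = rng.uniform(low, high, (n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def tanimoto_bit_loop(a, b) -> float:
    """Tanimoto similarity by explicit per-bit counting."""
    inter = union = 0
    for x, y in zip(a, b):
        if x and y:
            inter += 1
        if x or y:
            union += 1
    return 1.0 if union == 0 else inter / union


def leader_cluster_reference(ids, fingerprints, max_distance):
    """Quadratic re-implementation of descending-id leader clustering."""
    order = sorted(range(len(ids)), key=lambda i: ids[i], reverse=True)
    reps = []
    assignment = {}
    for i in order:
        chosen = None
        for r in reps:
            if 1.0 - tanimoto_bit_loop(fingerprints[i],
                                       fingerprints[r]) <= max_distance:
                chosen = r
                break
        if chosen is None:
            reps.append(i)
            assignment[ids[i]] = ids[i]
        else:
            assignment[ids[i]] = ids[chosen]
    return [ids[r] for r in reps], assignment
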