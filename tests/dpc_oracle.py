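"""Independent brute-force reference for the density-peaks clustering.

Works on plain dicts with explicit Python loops: density is counted by
enumerating every pixel pair, ranking / nearest-denser chains are
resolved by exhaustive search.  Deliberately unvectorized so it shares
no code path with the package.
"""

from __future__ import annotations


def oracle_dpc(counts: dict[int, int], d_c: float, k: int):
    """Return (rho, delta, gamma, centers, label) keyed by gray level."""
    counts = {g: c for g, c in counts.items() if c > 0}
    pixels = [g for g, c in counts.items() for _ in range(c)]
    levels = sorted(counts)

    rho = {}
    for g in levels:
        rho[g] = sum(1 for p in pixels if abs(g - p) < d_c)

    rank = sorted(levels, key=lambda g: (-rho[g], -counts[g], g))
    delta: dict[int, int] = {}
    nn: dict[int, int] = {}
    top = rank[0]
    if len(levels) == 1:
        delta[top] = 1
    else:
        delta[top] = max(abs(top - g) for g in levels if g != top)
        for pos in range(1, len(rank)):
            g = rank[pos]
            best_d, best_g = None, None
            for h in rank[:pos]:
                d = abs(g - h)
                if best_d is None or d < best_d or (d == best_d and h < best_g):
                    best_d, best_g = d, h
            delta[g] = best_d
            nn[g] = best_g

    gamma = {g: rho[g] * delta[g] for g in levels}
    centers = sorted(levels, key=lambda g: (-gamma[g], -rho[g], g))
    centers = centers[: min(k, len(levels))]

    label = {g: i for i, g in enumerate(centers)}
    for g in rank:
        if g not in label:
            label[g] = label[nn[g]]
    return rho, delta, gamma, centers, label
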