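"""Independent brute-force implementations of the haplotype statistics.

Everything here counts haplotype pairs explicitly (O(n^2 m)); the package
implementation refines identity classes instead.  The two routes share no
code.
"""

from __future__ import annotations

import math

import numpy as np


def brute_ehh_curve(haps: np.ndarray, carriers: np.ndarray, core: int,
                    step: int, cutoff: float) -> tuple[list[int], list[float]]:
    """EHH by explicit pair comparison, walking outward from the core."""
    n = len(carriers)
    n_pairs = n * (n - 1) // 2
    idx, vals = [core], [1.0]
    j = core + step
    while 0 <= j < haps.shape[1]:
        lo, hi = (j, core) if step < 0 else (core + 1, j + 1)
        identical = 0
        for a in range(n):
            for b in range(a + 1, n):
                if np.array_equal(haps[carriers[a], lo:hi], haps[carriers[b], lo:hi]):
                    identical += 1
        e = identical / n_pairs
        idx.append(j)
        vals.append(e)
        if e < max(cutoff, 1e-300):
            break
        j += step
    return idx, vals


def brute_ehh12_curve(haps: np.ndarray, core: int, step: int, cutoff: float
                      ) -> tuple[list[int], list[float]]:
    """EHH12: enumerate haplotype classes, pool the two largest."""
    n = haps.shape[0]
    n_pairs = n * (n - 1) // 2
    idx, vals = [core], [1.0]
    j = core + step
    while 0 <= j < haps.shape[1]:
        lo, hi = (j, core) if step < 0 else (core + 1, j + 1)
        classes: dict[bytes, int] = {}
        for h in range(n):
            key = haps[h, lo:hi].tobytes()
            classes[key] = classes.get(key, 0) + 1
        counts = sorted(classes.values(), reverse=True)
        if len(counts) >= 2:
            counts = [counts[0] + counts[1]] + counts[2:]
        e = sum(c * (c - 1) // 2 for c in counts) / n_pairs
        idx.append(j)
        vals.append(e)
        if e < max(cutoff, 1e-300):
            break
        j += step
    return idx, vals


def _integrate(positions: np.ndarray, idx: list[int], vals: list[float],
               cutoff: float) -> float:
    total = 0.0
    for i in range(1, len(vals)):
        d = abs(positions[idx[i]] - positions[idx[i - 1]])
        total += (vals[i] + vals[i - 1]) / 2.0 * d
        if vals[i] < cutoff:
            break
    return total


def brute_ihh(haps: np.ndarray, positions: np.ndarray, carriers: np.ndarray,
              core: int, cutoff: float) -> float:
    total = 0.0
    for step in (-1, 1):
        idx, vals = brute_ehh_curve(haps, carriers, core, step, cutoff)
        total += _integrate(positions, idx, vals, cutoff)
    return total


def brute_ihs(haps: np.ndarray, positions: np.ndarray, core: int,
              cutoff: float = 0.05) -> float:
    anc = np.flatnonzero(haps[:, core] == 0)
    der = np.flatnonzero(haps[:, core] == 1)
    ia = brute_ihh(haps, positions, anc, core, cutoff)
    idd = brute_ihh(haps, positions, der, core, cutoff)
    return math.log(ia / idd)


def brute_nsl(haps: np.ndarray, core: int) -> float:
    """nSL by explicit per-pair maximal identical intervals around the core."""

    def sl(carriers: np.ndarray) -> float:
        total, n_pairs = 0.0, 0
        m = haps.shape[1]
        for a in range(len(carriers)):
            for b in range(a + 1, len(carriers)):
                ha, hb = haps[carriers[a]], haps[carriers[b]]
                left = 0
                j = core - 1
                while j >= 0 and ha[j] == hb[j]:
                    left += 1
                    j -= 1
                right = 0
                j = core + 1
                while j < m and ha[j] == hb[j]:
                    right += 1
                    j += 1
                total += left + right + 1
                n_pairs += 1
        return total / n_pairs

    anc = np.flatnonzero(haps[:, core] == 0)
    der = np.flatnonzero(haps[:, core] == 1)
    return math.log(sl(anc) / sl(der))


def brute_ihh12(haps: np.ndarray, positions: np.ndarray, core: int,
                cutoff: float = 0.05) -> float:
    total = 0.0
    for step in (-1, 1):
        idx, vals = brute_ehh12_curve(haps, core, step, cutoff)
        total += _integrate(positions, idx, vals, cutoff)
    return total
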