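"""JIT-compiled inner loops for the per-trial cost evaluation.

These mirror the reference numpy implementations in :mod:`nmrpd.solver`
(`antibump` and `nth_intermolecular_distance`), which remain the readable
/ oracle-grade path; the solver's hot loop calls these instead.  Both
paths are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def antibump_sum(frac, mol, radii, rot, tran, orth, factor):
    """Σ ((r_min − d)/r_min)² over intermolecular pairs with d < r_min.

    Pairs run (central atom i, op/lattice image of atom j); images are
    the nearest cell of each pair plus its 26 neighbours; same-molecule
    pairs in the identity image are skipped.
    """
    n = frac.shape[0]
    n_ops = rot.shape[0]
    o00, o01, o02 = orth[0, 0], orth[0, 1], orth[0, 2]
    o11, o12 = orth[1, 1], orth[1, 2]
    o22 = orth[2, 2]
    total = 0.0
    for o in range(n_ops):
        for j in range(n):
            xj0 = rot[o, 0, 0] * frac[j, 0] + rot[o, 0, 1] * frac[j, 1] + rot[o, 0, 2] * frac[j, 2] + tran[o, 0]
            xj1 = rot[o, 1, 0] * frac[j, 0] + rot[o, 1, 1] * frac[j, 1] + rot[o, 1, 2] * frac[j, 2] + tran[o, 1]
            xj2 = rot[o, 2, 0] * frac[j, 0] + rot[o, 2, 1] * frac[j, 1] + rot[o, 2, 2] * frac[j, 2] + tran[o, 2]
            for i in range(n):
                rmin = factor * (radii[i] + radii[j])
                rmin2 = rmin * rmin
                d0 = frac[i, 0] - xj0
                d1 = frac[i, 1] - xj1
                d2_ = frac[i, 2] - xj2
                b0 = round(d0)
                b1 = round(d1)
                b2 = round(d2_)
                skip_same = o == 0 and mol[i] == mol[j]
                for sa in range(-1, 2):
                    for sb in range(-1, 2):
                        for sc in range(-1, 2):
                            if skip_same and b0 + sa == 0 and b1 + sb == 0 and b2 + sc == 0:
                                continue
                            f0 = d0 - b0 - sa
                            f1 = d1 - b1 - sb
                            f2 = d2_ - b2 - sc
                            cx = o00 * f0 + o01 * f1 + o02 * f2
                            cy = o11 * f1 + o12 * f2
                            cz = o22 * f2
                            dd = cx * cx + cy * cy + cz * cz
                            if dd < rmin2:
                                ex = (rmin - np.sqrt(dd)) / rmin
                                total += ex * ex
    return total


@njit(cache=True, fastmath=True)
def image_distance_list(frac_a, frac_b, same_mol, rot, tran, orth, shifts, cutoff):
    """All intermolecular image distances ≤ cutoff (unsorted)."""
    na = frac_a.shape[0]
    nb = frac_b.shape[0]
    n_ops = rot.shape[0]
    ns = shifts.shape[0]
    o00, o01, o02 = orth[0, 0], orth[0, 1], orth[0, 2]
    o11, o12 = orth[1, 1], orth[1, 2]
    o22 = orth[2, 2]
    cut2 = cutoff * cutoff
    out = np.empty(na * nb * n_ops * ns, dtype=np.float64)
    count = 0
    for o in range(n_ops):
        for j in range(nb):
            xj0 = rot[o, 0, 0] * frac_b[j, 0] + rot[o, 0, 1] * frac_b[j, 1] + rot[o, 0, 2] * frac_b[j, 2] + tran[o, 0]
            xj1 = rot[o, 1, 0] * frac_b[j, 0] + rot[o, 1, 1] * frac_b[j, 1] + rot[o, 1, 2] * frac_b[j, 2] + tran[o, 1]
            xj2 = rot[o, 2, 0] * frac_b[j, 0] + rot[o, 2, 1] * frac_b[j, 1] + rot[o, 2, 2] * frac_b[j, 2] + tran[o, 2]
            for i in range(na):
                d0 = frac_a[i, 0] - xj0
                d1 = frac_a[i, 1] - xj1
                d2_ = frac_a[i, 2] - xj2
                b0 = round(d0)
                b1 = round(d1)
                b2 = round(d2_)
                skip_same = o == 0 and same_mol[i, j]
                for s in range(ns):
                    if skip_same and b0 + shifts[s, 0] == 0 and b1 + shifts[s, 1] == 0 and b2 + shifts[s, 2] == 0:
                        continue
                    f0 = d0 - b0 - shifts[s, 0]
                    f1 = d1 - b1 - shifts[s, 1]
                    f2 = d2_ - b2 - shifts[s, 2]
                    cx = o00 * f0 + o01 * f1 + o02 * f2
                    cy = o11 * f1 + o12 * f2
                    cz = o22 * f2
                    dd = cx * cx + cy * cy + cz * cz
                    if dd <= cut2:
                        out[count] = np.sqrt(dd)
                        count += 1
    return out[:count]
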