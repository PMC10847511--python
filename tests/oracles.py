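"""Independent brute-force reference implementations used only by tests.

Each function re-derives its quantity directly from the rule statement with
naive enumeration, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def bruteforce_loh(profile, arms, min_len=15_000_000, tol=0):
    """Literal enumeration: segments with minor copy number 0, total >= 1,
    longer than min_len, not spanning an entire chromosome."""
    n = 0
    for seg in profile.segments:
        chrom_len = arms.length(seg.chromosome)
        is_loh = seg.b_cn == 0 and seg.total_cn >= 1
        long_enough = (seg.end - seg.start + 1) > min_len
        whole_chrom = seg.start <= 1 + tol and seg.end >= chrom_len - tol
        if is_loh and long_enough and not whole_chrom:
            n += 1
    return n


def bruteforce_tai(profile, arms, min_len=11_000_000, tol=0):
    """Literal enumeration: imbalanced segments, at least min_len long,
    reaching a chromosome end, not extending into the centromere."""
    n = 0
    for seg in profile.segments:
        chrom_len = arms.length(seg.chromosome)
        cen_start, cen_end = arms.centromere(seg.chromosome)
        imbalanced = seg.a_cn != seg.b_cn
        long_enough = (seg.end - seg.start + 1) >= min_len
        telomeric = seg.start <= 1 + tol or seg.end >= chrom_len - tol
        crosses_cen = seg.start < cen_end and seg.end > cen_start
        if imbalanced and long_enough and telomeric and not crosses_cen:
            n += 1
    return n


def bruteforce_lst(profile, arms, min_seg=10_000_000, smooth=3_000_000):
    """Literal per-arm re-derivation: clip to arm, drop short segments,
    repeatedly fuse same-state neighbours within the smoothing gap, count
    large adjacent state transitions."""
    total = 0
    for chrom in arms.chromosomes:
        chrom_len = arms.length(chrom)
        cen_start, cen_end = arms.centromere(chrom)
        for arm_lo, arm_hi in ((1, cen_start), (cen_end, chrom_len)):
            pieces = []
            for seg in profile.segments:
                if seg.chromosome != chrom:
                    continue
                lo, hi = max(seg.start, arm_lo), min(seg.end, arm_hi)
                if lo <= hi:
                    pieces.append([lo, hi, seg.total_cn, seg.b_cn])
            pieces = [p for p in pieces if p[1] - p[0] + 1 >= smooth]
            changed = True
            while changed:
                changed = False
                for i in range(len(pieces) - 1):
                    a, b = pieces[i], pieces[i + 1]
                    same_state = a[2:] == b[2:]
                    gap = b[0] - a[1] - 1
                    if same_state and gap <= smooth:
                        pieces[i] = [a[0], b[1], a[2], a[3]]
                        del pieces[i + 1]
                        changed = True
                        break
            for a, b in zip(pieces, pieces[1:]):
                gap = b[0] - a[1] - 1
                big_a = a[1] - a[0] + 1 >= min_seg
                big_b = b[1] - b[0] + 1 >= min_seg
                if gap <= smooth and a[2:] != b[2:] and big_a and big_b:
                    total += 1
    return total


def bruteforce_holm(pvalues):
    """Holm step-down from the definition: sort ascending, multiply the
    i-th smallest by (m - i), enforce the running maximum, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted


def cosine(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
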