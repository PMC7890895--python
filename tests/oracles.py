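"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's interval index and
classification code paths: overlaps are counted on per-base boolean arrays,
rank tests are enumerated exhaustively, and regressions are solved through
the raw normal equations.
"""

from __future__ import annotations

import itertools

import numpy as np

from regevo.intervals import GenomicInterval


def base_mask(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def per_base_union(intervals, length: int) -> np.ndarray:
    return base_mask(intervals, length)


def _bases(iv: GenomicInterval, length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    m[iv.start : iv.end] = True
    return m


def classify_brute_force(k4me3, k27ac, k4me1, length: int):
    """Per-base reimplementation of the AP/AE/PE calling rules.

    Returns ``(ap, ae, pe)`` as sets of (start, end) tuples.
    """
    masks3 = {iv: _bases(iv, length) for iv in k4me3}
    masksac = {iv: _bases(iv, length) for iv in k27ac}
    masks1 = {iv: _bases(iv, length) for iv in k4me1}
    ac_cov = base_mask(k27ac, length)
    me3_cov = base_mask(k4me3, length)

    ap, ae, pe = set(), set(), set()
    excl = np.zeros(length, dtype=bool)
    for p in k4me3:
        if any(
            np.count_nonzero(masks3[p] & masksac[q]) * 2 >= p.length() for q in k27ac
        ):
            ap.add((p.start, p.end))
            excl |= masks3[p]
            for q in k27ac:
                if np.count_nonzero(masks3[p] & masksac[q]) > 0:
                    excl |= masksac[q]
    for ac in k27ac:
        if np.count_nonzero(masksac[ac] & excl) > 0:
            continue
        if any(
            np.count_nonzero(masksac[ac] & masks1[m]) * 2 >= ac.length() for m in k4me1
        ):
            ae.add((ac.start, ac.end))
    for m in k4me1:
        if not np.any(masks1[m] & (ac_cov | me3_cov)):
            pe.add((m.start, m.end))
    return ap, ae, pe


def cross_tissue_brute_force(regions_by_tissue, length: int):
    """Per-base reimplementation of tissue linking and dynamic flagging.

    ``regions_by_tissue`` maps tissue -> list of (signature, interval).
    Returns per (tissue, start, end): (activity_tissue_set, intra_dynamic).
    """
    entries = [
        (tissue, sig, iv)
        for tissue, lst in regions_by_tissue.items()
        for sig, iv in lst
    ]
    masks = {id(iv): _bases(iv, length) for _, _, iv in entries}

    def either_half(iv_a, iv_b):
        ovl = np.count_nonzero(masks[id(iv_a)] & masks[id(iv_b)])
        return ovl * 2 >= iv_a.length() or ovl * 2 >= iv_b.length()

    results = {}
    for tissue, sig, iv in entries:
        active = {tissue}
        saw_promoter_pair = False
        saw_enhancer_pair = False
        for other_t, other_sig, other_iv in entries:
            if other_t == tissue:
                continue
            if not either_half(iv, other_iv):
                continue
            if other_sig == sig:
                active.add(other_t)
            elif "AP" in (sig, other_sig):
                saw_promoter_pair = True
            else:
                saw_enhancer_pair = True
        if saw_promoter_pair:
            dynamic = "dynamic_PE"
        elif saw_enhancer_pair:
            dynamic = "dynamic_E"
        else:
            dynamic = "none"
        results[(tissue, iv.start, iv.end)] = (frozenset(active), dynamic)
    return results


def mwu_statistic(x, y) -> float:
    return sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y
    )


def mwu_exact_p(x, y, alternative: str = "greater") -> float:
    """Exact Mann-Whitney p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    obs = mwu_statistic(x, y)
    hits = total = 0
    for subset in itertools.combinations(range(len(pooled)), n):
        chosen = set(subset)
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = mwu_statistic(xs, ys)
        total += 1
        if alternative == "greater" and u >= obs - 1e-12:
            hits += 1
        if alternative == "less" and u <= obs + 1e-12:
            hits += 1
    return hits / total


def normal_equations_fit(xs, ys) -> tuple[float, float]:
    """OLS slope/intercept straight from the normal equations."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs)
    sxx = n * np.sum(xs * xs) - np.sum(xs) ** 2
    slope = (n * np.sum(xs * ys) - np.sum(xs) * np.sum(ys)) / sxx
    intercept = (np.sum(ys) - slope * np.sum(xs)) / n
    return float(slope), float(intercept)


def triad_outcome_enumeration(pi, m_internal, m_ingroup, m_outgroup) -> np.ndarray:
    """Expected parsimony transition matrix from the 27 triad outcomes.

    The triad topology is ((A, B), C): the root state z (distribution
    ``pi``) evolves through ``m_internal`` to the ingroup ancestor m, then
    through ``m_ingroup`` to each ingroup leaf, and through ``m_outgroup``
    to the outgroup leaf. Parsimony-usable outcomes are (X,X,X) (a stay) and
    those where exactly one ingroup matches the outgroup X (one X->Y change).
    """
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            for c in range(3):
                p = sum(
                    pi[z] * m_internal[z, m] * m_ingroup[m, a] * m_ingroup[m, b] * m_outgroup[z, c]
                    for z in range(3)
                    for m in range(3)
                )
                if a == b == c:
                    counts[c, c] += p
                elif (a == c) != (b == c):
                    counts[c, b if a == c else a] += p
    return counts / counts.sum(axis=1, keepdims=True)
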