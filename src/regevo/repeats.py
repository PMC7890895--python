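"""Transposable-element enrichment and LINE age / length comparisons.

The central statistic is a *relative enrichment*: within a repeat class
(e.g. LINE), the share of regions in set A overlapping a given subgroup
(e.g. L1) among all A regions overlapping any repeat of that class, minus
the same share for set B, in percentage points. Positive values mean the
subgroup is proportionally more common in set A. Significance uses a
two-proportion z-test with Bonferroni correction over every cell of the
emitted matrix; display is limited to subgroups with at least 100
occurrences in both sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalIndex, merge_intervals, overlap_length
from .io import RepeatElement
from .regulome import RegulatoryRegion
from .stats import two_proportion_ztest, wilcoxon_rank_sum_one_sided

__all__ = [
    "EnrichmentCell",
    "RepeatOverlapPartition",
    "relative_enrichment",
    "partition_repeats",
    "compare_repeat_attribute",
    "shuffle_control",
]


@dataclass
class EnrichmentCell:
    species: str
    region_class: str
    repeat_group: str
    subgroup: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    p_adj: float
    p_raw: float
    displayed: bool

    @property
    def pct_a(self) -> float:
        return 100.0 * self.count_a / self.total_a

    @property
    def pct_b(self) -> float:
        return 100.0 * self.count_b / self.total_b

    @property
    def delta(self) -> float:
        return self.pct_a - self.pct_b


def _region_subgroups(
    regions: Sequence[RegulatoryRegion | GenomicInterval],
    repeat_index: IntervalIndex,
    min_overlap: str,
    strict_subgroup: bool,
) -> list[dict[str, set[str]]]:
    """Per region: repeat groups mapped to the subgroups it overlaps.

    ``min_overlap="one_bp"`` accepts any shared base; ``"half_region"``
    requires a single repeat to cover >=50% of the region's length. In
    strict mode each region is attributed, per group, only to its
    largest-overlap subgroup.
    """
    out: list[dict[str, set[str]]] = []
    for reg in regions:
        iv = reg.interval if isinstance(reg, RegulatoryRegion) else reg
        best: dict[str, tuple[int, str]] = {}
        groups: dict[str, set[str]] = {}
        for rep_iv, payload in repeat_index.overlapping(iv):
            el: RepeatElement = payload  # type: ignore[assignment]
            ovl = overlap_length(iv, rep_iv)
            if min_overlap == "half_region" and ovl * 2 < iv.length():
                continue
            groups.setdefault(el.repeat_class, set()).add(el.subgroup)
            cur = best.get(el.repeat_class)
            if cur is None or ovl > cur[0]:
                best[el.repeat_class] = (ovl, el.subgroup)
        if strict_subgroup:
            groups = {g: {sub} for g, (_, sub) in best.items()}
        out.append(groups)
    return out


def relative_enrichment(
    set_a: Sequence[RegulatoryRegion | GenomicInterval],
    set_b: Sequence[RegulatoryRegion | GenomicInterval],
    repeats: Sequence[RepeatElement],
    species: str = "",
    region_class: str = "",
    min_overlap: str = "one_bp",
    min_display: int = 100,
    strict_subgroup: bool = False,
    continuity_correction: bool = False,
) -> list[EnrichmentCell]:
    """Per-subgroup relative enrichment of set A over set B.

    For each repeat group the denominator is the number of regions of the
    set overlapping *any* repeat of the group (each region counted once);
    the numerator counts regions overlapping the specific subgroup. A region
    overlapping several subgroups counts once per subgroup unless
    ``strict_subgroup`` attributes it to its largest overlap only. Bonferroni
    uses the number of emitted cells, before the display filter.
    """
    if min_overlap not in ("one_bp", "half_region"):
        raise ValueError("min_overlap must be 'one_bp' or 'half_region'")
    repeat_index = IntervalIndex([(el.interval, el) for el in repeats])
    per_a = _region_subgroups(set_a, repeat_index, min_overlap, strict_subgroup)
    per_b = _region_subgroups(set_b, repeat_index, min_overlap, strict_subgroup)

    def tally(per_region: list[dict[str, set[str]]]):
        totals: dict[str, int] = {}
        counts: dict[tuple[str, str], int] = {}
        for groups in per_region:
            for g, subs in groups.items():
                totals[g] = totals.get(g, 0) + 1
                for sub in subs:
                    counts[(g, sub)] = counts.get((g, sub), 0) + 1
        return totals, counts

    totals_a, counts_a = tally(per_a)
    totals_b, counts_b = tally(per_b)

    cells: list[EnrichmentCell] = []
    keys = sorted(set(counts_a) | set(counts_b))
    emitted = [
        (g, sub)
        for g, sub in keys
        if totals_a.get(g, 0) > 0 and totals_b.get(g, 0) > 0
    ]
    n_tests = max(1, len(emitted))
    for g, sub in emitted:
        ca, cb = counts_a.get((g, sub), 0), counts_b.get((g, sub), 0)
        ta, tb = totals_a[g], totals_b[g]
        res = two_proportion_ztest(ca, ta, cb, tb, correction=continuity_correction)
        cells.append(
            EnrichmentCell(
                species=species,
                region_class=region_class,
                repeat_group=g,
                subgroup=sub,
                count_a=ca,
                count_b=cb,
                total_a=ta,
                total_b=tb,
                p_raw=res.p_value,
                p_adj=min(1.0, res.p_value * n_tests),
                displayed=(ca >= min_display and cb >= min_display),
            )
        )
    return cells


@dataclass
class RepeatOverlapPartition:
    """Repeats split by the evolutionary status of regions they touch.

    Categories are mutually exclusive with precedence
    dynamic > recently evolved > inactive: a repeat under an evolutionarily
    dynamic region makes the stronger claim even if it also touches a
    recently evolved one. Repeats touching only stable maintained regions
    fall through to the inactive category.
    """

    categories: dict[str, list[RepeatElement]] = field(default_factory=dict)

    ORDER = ("regulatorily_inactive", "recently_evolved_overlap", "evolutionarily_dynamic_overlap")

    def values(self, category: str, attribute: str) -> list[float]:
        elements = self.categories.get(category, [])
        if attribute == "pct_divergence":
            return [el.pct_divergence for el in elements]
        if attribute == "length":
            return [float(el.interval.length()) for el in elements]
        raise ValueError(f"unknown attribute {attribute!r}")


def partition_repeats(
    repeats: Sequence[RepeatElement],
    recently_evolved: Sequence[RegulatoryRegion | GenomicInterval],
    dynamic: Sequence[RegulatoryRegion | GenomicInterval],
    subgroups: Iterable[str] = ("L1", "L2"),
) -> RepeatOverlapPartition:
    """Assign each repeat of the selected subgroups to exactly one category.

    Overlap tests use >=1 shared base. ``recently_evolved`` are regions
    without cross-species maintenance; ``dynamic`` are maintained regions
    aligned to a different signature in another species.
    """

    def as_index(regions: Sequence[RegulatoryRegion | GenomicInterval]) -> IntervalIndex:
        ivs = [r.interval if isinstance(r, RegulatoryRegion) else r for r in regions]
        return IntervalIndex.from_intervals(ivs)

    recent_idx = as_index(recently_evolved)
    dynamic_idx = as_index(dynamic)
    wanted = set(subgroups)
    partition = RepeatOverlapPartition({c: [] for c in RepeatOverlapPartition.ORDER})
    for el in repeats:
        if wanted and el.subgroup not in wanted:
            continue
        if dynamic_idx.any_overlap(el.interval):
            cat = "evolutionarily_dynamic_overlap"
        elif recent_idx.any_overlap(el.interval):
            cat = "recently_evolved_overlap"
        else:
            cat = "regulatorily_inactive"
        partition.categories[cat].append(el)
    return partition


def compare_repeat_attribute(
    partition: RepeatOverlapPartition,
    attribute: str = "pct_divergence",
    alternative: str = "greater",
) -> dict[tuple[str, str], dict[str, float]]:
    """One-sided rank-sum comparisons of an attribute between category pairs.

    For each ordered pair (first, second) the test asks whether *first*
    tends to larger (``alternative="greater"``) or smaller values than
    *second*. Empty categories are skipped. Returns per pair the p-value and
    both medians.
    """
    cats = [c for c in RepeatOverlapPartition.ORDER if partition.categories.get(c)]
    out: dict[tuple[str, str], dict[str, float]] = {}
    for a in cats:
        for b in cats:
            if a == b:
                continue
            va = partition.values(a, attribute)
            vb = partition.values(b, attribute)
            _, p = wilcoxon_rank_sum_one_sided(va, vb, alternative=alternative)
            out[(a, b)] = {
                "p_value": p,
                "median_first": float(np.median(va)),
                "median_second": float(np.median(vb)),
            }
    return out


def _coverage_fraction(iv: GenomicInterval, merged: IntervalIndex) -> float:
    covered = sum(overlap_length(iv, hit) for hit, _ in merged.overlapping(iv))
    return covered / iv.length()


def shuffle_control(
    regions: Sequence[RegulatoryRegion | GenomicInterval],
    genome_sizes: dict[str, int],
    exclude: Sequence[GenomicInterval],
    repeats: Sequence[RepeatElement],
    seed: int,
    repeat_class: str = "LINE",
    min_overlap_fraction: float = 0.5,
) -> dict[str, float]:
    """Random-placement null for repeat overlap of regulatory regions.

    For every real region a random region of identical length is placed
    uniformly on the same genome, outside the exclusion set (the
    regulatorily active intervals). Both the real and the random sets are
    then scored for the fraction of regions whose bases are covered
    >= ``min_overlap_fraction`` by repeats of ``repeat_class``; a
    two-proportion z-test compares the two fractions. Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    merged_excl: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(exclude):
        merged_excl.setdefault(iv.seq_id, []).append(iv)

    gaps: dict[str, list[tuple[int, int]]] = {}
    for seq_id, size in genome_sizes.items():
        pos = 0
        seq_gaps: list[tuple[int, int]] = []
        for iv in merged_excl.get(seq_id, []):
            if iv.start > pos:
                seq_gaps.append((pos, iv.start))
            pos = max(pos, iv.end)
        if pos < size:
            seq_gaps.append((pos, size))
        gaps[seq_id] = seq_gaps

    rep_merged = IntervalIndex.from_intervals(
        merge_intervals(el.interval for el in repeats if el.repeat_class == repeat_class)
    )

    real_ivs = [r.interval if isinstance(r, RegulatoryRegion) else r for r in regions]
    placements: list[GenomicInterval] = []
    all_gaps = [(seq, s, e) for seq, seq_gaps in gaps.items() for s, e in seq_gaps]
    for iv in real_ivs:
        length = iv.length()
        candidates = [(seq, s, e) for seq, s, e in all_gaps if e - s >= length]
        if not candidates:
            raise ValueError(f"no placeable gap of length {length} for region {iv}")
        weights = np.array([e - s - length + 1 for _, s, e in candidates], dtype=float)
        gi = rng.choice(len(candidates), p=weights / weights.sum())
        seq, s, e = candidates[gi]
        start = int(rng.integers(s, e - length + 1))
        placements.append(GenomicInterval(seq, start, start + length))

    def frac_covered(ivs: Sequence[GenomicInterval]) -> tuple[int, int]:
        hits = sum(
            1 for iv in ivs if _coverage_fraction(iv, rep_merged) >= min_overlap_fraction
        )
        return hits, len(ivs)

    real_hits, n_real = frac_covered(real_ivs)
    rand_hits, n_rand = frac_covered(placements)
    res = two_proportion_ztest(real_hits, n_real, rand_hits, n_rand)
    return {
        "real_fraction": real_hits / n_real,
        "random_fraction": rand_hits / n_rand,
        "p_value": res.p_value,
        "n": float(n_real),
    }
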