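"""Regulome construction: reproducible peaks, signature calling, tissue logic.

A *regulome* here is the per-tissue set of regulatory regions of one species,
classified from three histone marks:

* **AP** (active promoter) — H3K4me3 peak covered >=50% of its length by
  H3K27ac.
* **AE** (active enhancer) — H3K27ac peak covered >=50% of its length by
  H3K4me1, outside any promoter footprint.
* **PE** (primed enhancer) — H3K4me1 peak with no overlap at all to H3K27ac
  or H3K4me3.

Cross-tissue comparison then assigns each region a tissue-activity set and
flags regions whose signature differs between tissues (intra-species
dynamic); those are excluded from downstream specificity and evolution
tallies by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    edge_distance,
    merge_intervals,
    overlap_length,
)
from .io import BedRecord, PeakCall, write_bed

__all__ = [
    "write_regulome",
    "read_regulome",
    "SIGNATURES",
    "RegulatoryRegion",
    "Regulome",
    "EnhancerAssignment",
    "merge_reproducible_peaks",
    "call_regulatory_regions",
    "cross_tissue_classify",
    "associate_enhancers",
    "assign_nearest_gene",
]

SIGNATURES = ("AP", "AE", "PE")


@dataclass(eq=False)
class RegulatoryRegion:
    """A classified regulatory region in one tissue of one species.

    Instances compare by identity: the same genomic footprint called in two
    tissues is two distinct regions linked (or not) by cross-tissue overlap.
    """

    interval: GenomicInterval
    signature: str
    species: str
    home_tissue: str
    activity_tissues: frozenset[str] = field(default_factory=frozenset)
    specificity: str = "tissue_specific"
    intra_dynamic: str = "none"  # none / dynamic_PE / dynamic_E

    def __post_init__(self) -> None:
        if self.signature not in SIGNATURES:
            raise ValueError(f"unknown signature {self.signature!r}")
        if not self.activity_tissues:
            self.activity_tissues = frozenset({self.home_tissue})

    @property
    def is_dynamic(self) -> bool:
        return self.intra_dynamic != "none"


@dataclass
class Regulome:
    """All classified regions of one species, organized per tissue."""

    species: str
    tissues: dict[str, dict[str, list[RegulatoryRegion]]] = field(default_factory=dict)
    unclassified: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def add_tissue(
        self,
        tissue: str,
        regions: dict[str, list[RegulatoryRegion]],
        unclassified: Sequence[GenomicInterval] = (),
    ) -> None:
        self.tissues[tissue] = regions
        self.unclassified[tissue] = list(unclassified)

    def regions(
        self,
        tissue: str | None = None,
        signature: str | None = None,
        include_dynamic: bool = True,
    ) -> list[RegulatoryRegion]:
        tissues = [tissue] if tissue is not None else sorted(self.tissues)
        sigs = [signature] if signature is not None else list(SIGNATURES)
        out: list[RegulatoryRegion] = []
        for t in tissues:
            per_sig = self.tissues.get(t, {})
            for s in sigs:
                for r in per_sig.get(s, []):
                    if include_dynamic or not r.is_dynamic:
                        out.append(r)
        return out


@dataclass(frozen=True)
class EnhancerAssignment:
    enhancer: RegulatoryRegion
    promoter: RegulatoryRegion | None
    distance: int | None


def _reciprocal_half_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    ovl = overlap_length(a, b)
    return ovl * 2 >= a.length() and ovl * 2 >= b.length()


def merge_reproducible_peaks(
    replicates: Sequence[Sequence[PeakCall | GenomicInterval]],
    min_replicates: int = 2,
) -> list[GenomicInterval]:
    """Collapse per-replicate peaks into the biologically reproducible set.

    A peak is reproducible iff it has a *reciprocal* >=50%-of-length overlap
    partner in at least one other replicate. Connected groups of reproducible
    peaks (linked by such reciprocal overlaps across replicates) are merged
    into their union span; everything else is dropped.
    """
    if len(replicates) < min_replicates:
        raise ValueError(
            f"need at least {min_replicates} replicate peak lists, got {len(replicates)}"
        )
    peaks: list[tuple[int, GenomicInterval]] = []
    for rep_idx, rep in enumerate(replicates):
        for p in rep:
            iv = p.interval if isinstance(p, PeakCall) else p
            peaks.append((rep_idx, iv))

    index = IntervalIndex([(iv, i) for i, (_, iv) in enumerate(peaks)])
    parent = list(range(len(peaks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    reproducible = [False] * len(peaks)
    for i, (rep_i, iv_i) in enumerate(peaks):
        for _, j in index.overlapping(iv_i):
            j = int(j)  # type: ignore[arg-type]
            if j <= i:
                continue
            rep_j, iv_j = peaks[j]
            if rep_i != rep_j and _reciprocal_half_overlap(iv_i, iv_j):
                reproducible[i] = reproducible[j] = True
                union(i, j)

    spans: dict[int, tuple[str, int, int]] = {}
    for i, (_, iv) in enumerate(peaks):
        if not reproducible[i]:
            continue
        root = find(i)
        if root in spans:
            seq, s, e = spans[root]
            spans[root] = (seq, min(s, iv.start), max(e, iv.end))
        else:
            spans[root] = (iv.seq_id, iv.start, iv.end)
    consensus = [GenomicInterval(seq, s, e) for seq, s, e in spans.values()]
    return merge_intervals(consensus)


def call_regulatory_regions(
    k4me3: Sequence[GenomicInterval],
    k27ac: Sequence[GenomicInterval],
    k4me1: Sequence[GenomicInterval],
    species: str,
    tissue: str,
    ae_overlap_subject: str = "k27ac",
) -> tuple[dict[str, list[RegulatoryRegion]], list[GenomicInterval]]:
    """Classify consensus mark peaks into AP / AE / PE for one tissue.

    Promoters are called first and their footprint (the H3K4me3 peak plus
    every H3K27ac peak touching it) is excluded from enhancer calling;
    primed enhancers require zero overlap with the *raw* H3K27ac and H3K4me3
    peak sets. ``ae_overlap_subject`` selects whose length the 50% enhancer
    rule refers to ("k27ac", the default, or "k4me1").

    Returns ``(regions_by_signature, unclassified_intervals)``.
    """
    if ae_overlap_subject not in ("k27ac", "k4me1"):
        raise ValueError("ae_overlap_subject must be 'k27ac' or 'k4me1'")
    ac_index = IntervalIndex.from_intervals(k27ac)
    me1_index = IntervalIndex.from_intervals(k4me1)
    me3_index = IntervalIndex.from_intervals(k4me3)

    regions: dict[str, list[RegulatoryRegion]] = {"AP": [], "AE": [], "PE": []}
    exclusion: list[GenomicInterval] = []
    consumed_ac: set[GenomicInterval] = set()
    consumed_me1: set[GenomicInterval] = set()

    # (i) Active promoters: H3K4me3 covered >=50% by some H3K27ac peak.
    for p in k4me3:
        ac_hits = [iv for iv, _ in ac_index.overlapping(p)]
        if any(overlap_length(p, q) * 2 >= p.length() for q in ac_hits):
            regions["AP"].append(RegulatoryRegion(p, "AP", species, tissue))
            exclusion.append(p)
            exclusion.extend(ac_hits)
            consumed_ac.update(ac_hits)

    excl_index = IntervalIndex.from_intervals(merge_intervals(exclusion))

    # (ii) Active enhancers: remaining H3K27ac covered >=50% by H3K4me1.
    for ac in k27ac:
        if ac in consumed_ac or excl_index.any_overlap(ac):
            continue
        me1_hits = [iv for iv, _ in me1_index.overlapping(ac)]
        ok = False
        for m in me1_hits:
            ovl = overlap_length(ac, m)
            subject_len = ac.length() if ae_overlap_subject == "k27ac" else m.length()
            if ovl * 2 >= subject_len:
                ok = True
                break
        if ok:
            regions["AE"].append(RegulatoryRegion(ac, "AE", species, tissue))
            consumed_ac.add(ac)
            consumed_me1.update(me1_hits)

    # (iii) Primed enhancers: H3K4me1 untouched by any raw H3K27ac/H3K4me3.
    for m in k4me1:
        if not ac_index.any_overlap(m) and not me3_index.any_overlap(m):
            regions["PE"].append(RegulatoryRegion(m, "PE", species, tissue))
            consumed_me1.add(m)

    ap_set = {r.interval for r in regions["AP"]}
    unclassified = (
        [p for p in k4me3 if p not in ap_set]
        + [ac for ac in k27ac if ac not in consumed_ac]
        + [m for m in k4me1 if m not in consumed_me1]
    )
    return regions, unclassified


def _either_half_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True if a and b overlap by >=50% of *either* region's length."""
    ovl = overlap_length(a, b)
    return ovl * 2 >= a.length() or ovl * 2 >= b.length()


def cross_tissue_classify(
    regulome: Regulome,
    n_tissues_for_full_share: int = 4,
    transitive: bool = False,
) -> Regulome:
    """Populate activity tissues, specificity, and intra-species dynamics.

    Two same-signature regions in different tissues are linked when either
    overlaps the other by >=50% of its own length; a region's activity set is
    its home tissue plus every tissue holding a directly linked region
    (``transitive=True`` instead takes the connected-component closure, for
    sensitivity analysis). Cross-signature links under the same rule flag
    both partners as intra-species dynamic: promoter vs either enhancer type
    is ``dynamic_PE``, active vs primed enhancer is ``dynamic_E``.
    """
    tissues = sorted(regulome.tissues)
    indexes: dict[tuple[str, str], IntervalIndex] = {}
    for t in tissues:
        for sig in SIGNATURES:
            regs = regulome.tissues[t].get(sig, [])
            indexes[(t, sig)] = IntervalIndex([(r.interval, r) for r in regs])

    links: dict[RegulatoryRegion, set[RegulatoryRegion]] = {}
    for t in tissues:
        for sig in SIGNATURES:
            for r in regulome.tissues[t].get(sig, []):
                links.setdefault(r, set())
                for u in tissues:
                    if u == t:
                        continue
                    for other_sig in SIGNATURES:
                        for iv, partner in indexes[(u, other_sig)].overlapping(r.interval):
                            if not _either_half_overlap(r.interval, iv):
                                continue
                            partner_r = partner  # type: ignore[assignment]
                            if other_sig == sig:
                                links[r].add(partner_r)
                            else:
                                pair = {sig, other_sig}
                                kind = "dynamic_PE" if "AP" in pair else "dynamic_E"
                                for reg in (r, partner_r):
                                    if kind == "dynamic_PE" or reg.intra_dynamic == "none":
                                        reg.intra_dynamic = kind

    if transitive:
        changed = True
        while changed:
            changed = False
            for r, partners in links.items():
                for p in list(partners):
                    extra = links.get(p, set()) - partners - {r}
                    if extra:
                        partners |= extra
                        changed = True

    for r, partners in links.items():
        active = {r.home_tissue} | {p.home_tissue for p in partners}
        r.activity_tissues = frozenset(active)
        if len(active) == 1:
            r.specificity = "tissue_specific"
        elif len(active) >= n_tissues_for_full_share:
            r.specificity = "four_tissue_shared"
        else:
            r.specificity = "tissue_shared"
    return regulome


def _nearest(
    query: GenomicInterval,
    candidates: Sequence[tuple[GenomicInterval, object]],
    max_dist: int,
) -> tuple[object, int] | None:
    """Nearest candidate by edge distance; ties to lower start, then seq_id."""
    best: tuple[int, int, str, object] | None = None
    for iv, payload in candidates:
        d = edge_distance(query, iv)
        if d is None or d > max_dist:
            continue
        key = (d, iv.start, iv.seq_id, payload)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return None
    return best[3], best[0]


def associate_enhancers(
    tissue_regions: dict[str, list[RegulatoryRegion]],
    max_dist: int = 1_000_000,
) -> list[EnhancerAssignment]:
    """Assign each enhancer to the nearest active promoter of the same tissue.

    Edge-to-edge distance, 0 when overlapping; enhancers farther than
    ``max_dist`` (1 Mb by default) from every promoter remain unassigned.
    """
    promoters = [(r.interval, r) for r in tissue_regions.get("AP", [])]
    by_seq: dict[str, list[tuple[GenomicInterval, object]]] = {}
    for iv, r in promoters:
        by_seq.setdefault(iv.seq_id, []).append((iv, r))
    out: list[EnhancerAssignment] = []
    for sig in ("AE", "PE"):
        for enh in tissue_regions.get(sig, []):
            hit = _nearest(enh.interval, by_seq.get(enh.interval.seq_id, []), max_dist)
            if hit is None:
                out.append(EnhancerAssignment(enh, None, None))
            else:
                promoter, dist = hit
                out.append(EnhancerAssignment(enh, promoter, dist))  # type: ignore[arg-type]
    return out


def assign_nearest_gene(
    promoters: Sequence[RegulatoryRegion],
    tss: Sequence[tuple[GenomicInterval, str]],
    assignments: Sequence[EnhancerAssignment] = (),
    max_dist: int = 1_000_000,
) -> dict[RegulatoryRegion, str | None]:
    """Map each promoter to its closest TSS gene within 1 Mb (edge distance).

    TSS are single-base intervals (the most downstream coordinate of the
    gene). Each enhancer in ``assignments`` inherits the gene of its assigned
    promoter. Ties break to the lower-coordinate TSS.
    """
    by_seq: dict[str, list[tuple[GenomicInterval, object]]] = {}
    for iv, gene in tss:
        by_seq.setdefault(iv.seq_id, []).append((iv, gene))
    mapping: dict[RegulatoryRegion, str | None] = {}
    for p in promoters:
        hit = _nearest(p.interval, by_seq.get(p.interval.seq_id, []), max_dist)
        mapping[p] = None if hit is None else hit[0]  # type: ignore[assignment]
    for a in assignments:
        if a.promoter is not None and a.promoter in mapping:
            mapping[a.enhancer] = mapping[a.promoter]
    return mapping


def write_regulome(regulome: Regulome, path) -> None:
    """Serialize a regulome as BED6+ with columns
    signature, tissue, activity_tissues (comma list), intra_dynamic,
    specificity."""
    records = []
    for tissue in sorted(regulome.tissues):
        for sig in SIGNATURES:
            for r in regulome.tissues[tissue].get(sig, []):
                records.append(
                    BedRecord(
                        interval=r.interval,
                        name=r.signature,
                        score="0",
                        extra=(
                            tissue,
                            ",".join(sorted(r.activity_tissues)),
                            r.intra_dynamic,
                            r.specificity,
                        ),
                    )
                )
    records.sort(key=lambda rec: (rec.interval.seq_id, rec.interval.start, rec.extra[0]))
    write_bed(records, path)


def read_regulome(path, species: str) -> Regulome:
    from .io import read_bed

    regulome = Regulome(species=species)
    for rec in read_bed(path):
        tissue, activity, dynamic, specificity = rec.extra[:4]
        region = RegulatoryRegion(
            interval=rec.interval,
            signature=rec.name,
            species=species,
            home_tissue=tissue,
            activity_tissues=frozenset(activity.split(",")),
            specificity=specificity,
            intra_dynamic=dynamic,
        )
        regulome.tissues.setdefault(tissue, {s: [] for s in SIGNATURES})
        regulome.tissues[tissue][region.signature].append(region)
        regulome.unclassified.setdefault(tissue, [])
    return regulome
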