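"""Cross-species comparison of regulomes through pairwise alignment maps.

For a pair of species, every (non intra-dynamic) regulatory region is
projected through the gapless block map and partitioned into

* **P_N** — unaligned: no block covers any base of the region;
* **P_L** — aligned, but the projected footprint overlaps no regulatory
  region of the other species;
* **P_M** — maintained: the footprint overlaps some regulatory region of
  any signature and any tissue by at least one base.

The partition identity ``P_A = P_N + P_L + P_M`` holds by construction, and
recently evolved regions are ``P_R = P_N + P_L``. Maintenance fractions,
replicate-based zero points, evolutionary-rate regressions, and the
signature-switching decomposition of 1-to-1 maintained regions all build on
this projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .intervals import GenomicInterval, IntervalIndex, merge_intervals
from .io import AlignmentBlock
from .regulome import RegulatoryRegion, Regulome, SIGNATURES

__all__ = [
    "AlignmentMap",
    "ProjectionResult",
    "PairProjection",
    "ClassCounts",
    "PairwiseEvolutionSummary",
    "ReplicateReproducibility",
    "SignatureAlignmentTable",
    "RateFit",
    "project_region",
    "summarize_pair",
    "replicate_zero_point",
    "fit_rate",
    "signature_decomposition",
]


class AlignmentMap:
    """A pairwise genome alignment as a table of gapless collinear blocks.

    Projection from species A to species B maps each base of an interval
    through the block it falls in; bases outside every block are lost.
    """

    def __init__(self, blocks: list[AlignmentBlock]):
        if not blocks:
            raise ValueError("alignment map needs at least one block")
        species = {(b.species_a, b.species_b) for b in blocks}
        if len(species) != 1:
            raise ValueError(f"mixed species pairs in one map: {sorted(species)}")
        self.species_a, self.species_b = species.pop()
        self.blocks = blocks
        self._index = IntervalIndex([(b.interval_a, b) for b in blocks])

    def reversed(self) -> "AlignmentMap":
        rev = [
            AlignmentBlock(b.interval_b, b.interval_a, b.species_b, b.species_a)
            for b in self.blocks
        ]
        return AlignmentMap(rev)

    def oriented(self, source_species: str) -> "AlignmentMap":
        if source_species == self.species_a:
            return self
        if source_species == self.species_b:
            return self.reversed()
        raise ValueError(
            f"species {source_species!r} not in map ({self.species_a}, {self.species_b})"
        )

    def project(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """Map an interval on species A into species-B coordinates."""
        pieces: list[GenomicInterval] = []
        for block_iv, block in self._index.overlapping(iv):
            b: AlignmentBlock = block  # type: ignore[assignment]
            s = max(iv.start, block_iv.start)
            e = min(iv.end, block_iv.end)
            offset = b.interval_b.start - b.interval_a.start
            pieces.append(
                GenomicInterval(b.interval_b.seq_id, s + offset, e + offset)
            )
        return merge_intervals(pieces)


@dataclass
class ProjectionResult:
    region: RegulatoryRegion
    status: str  # unaligned / aligned_no_regulation / maintained / multi_mapped_excluded
    footprint: list[GenomicInterval] = field(default_factory=list)
    partners: list[RegulatoryRegion] = field(default_factory=list)
    one_to_one: bool = False


def _cluster_footprint(
    pieces: list[GenomicInterval], cluster_gap: int
) -> list[list[GenomicInterval]]:
    clusters: list[list[GenomicInterval]] = []
    for iv in sorted(pieces, key=lambda p: (p.seq_id, p.start)):
        if (
            clusters
            and clusters[-1][-1].seq_id == iv.seq_id
            and iv.start - clusters[-1][-1].end <= cluster_gap
        ):
            clusters[-1].append(iv)
        else:
            clusters.append([iv])
    return clusters


def project_region(
    region: RegulatoryRegion,
    amap: AlignmentMap,
    target_index: IntervalIndex,
    cluster_gap: int = 10_000,
) -> ProjectionResult:
    """Project one region and classify it against the target regulome.

    The projected footprint is clustered with a ``cluster_gap`` tolerance;
    a footprint splitting into more than one cluster means the region aligns
    to multiple genomic locations and is excluded from all counts.
    """
    amap = amap.oriented(region.species)
    pieces = amap.project(region.interval)
    if not pieces:
        return ProjectionResult(region, "unaligned")
    clusters = _cluster_footprint(pieces, cluster_gap)
    if len(clusters) > 1:
        return ProjectionResult(region, "multi_mapped_excluded", footprint=pieces)
    partners: list[RegulatoryRegion] = []
    seen: set[int] = set()
    for piece in pieces:
        for _, payload in target_index.overlapping(piece):
            r: RegulatoryRegion = payload  # type: ignore[assignment]
            if id(r) not in seen:
                seen.add(id(r))
                partners.append(r)
    status = "maintained" if partners else "aligned_no_regulation"
    return ProjectionResult(region, status, footprint=pieces, partners=partners)


def _regulome_index(regulome: Regulome, tissue: str | None = None) -> IntervalIndex:
    regs = regulome.regions(tissue=tissue, include_dynamic=True)
    return IntervalIndex([(r.interval, r) for r in regs])


class PairProjection:
    """Both-direction projections for one species pair.

    Queries exclude intra-species dynamic regions (they are excluded from
    all evolution tallies by default) but dynamic regions still count as
    maintenance partners. ``same_tissue=True`` restricts partner lookup to
    the query's home tissue.
    """

    def __init__(
        self,
        regulome_i: Regulome,
        regulome_j: Regulome,
        amap: AlignmentMap,
        cluster_gap: int = 10_000,
        same_tissue: bool = False,
        include_dynamic_queries: bool = False,
    ):
        self.regulome_i = regulome_i
        self.regulome_j = regulome_j
        self.map_ij = amap.oriented(regulome_i.species)
        self.map_ji = self.map_ij.reversed()
        self.cluster_gap = cluster_gap
        self.same_tissue = same_tissue
        self.include_dynamic_queries = include_dynamic_queries
        self.forward = self._project_all(regulome_i, regulome_j, self.map_ij)
        self.backward = self._project_all(regulome_j, regulome_i, self.map_ji)
        self._mark_one_to_one()

    def _project_all(
        self, source: Regulome, target: Regulome, amap: AlignmentMap
    ) -> dict[RegulatoryRegion, ProjectionResult]:
        results: dict[RegulatoryRegion, ProjectionResult] = {}
        full_index = _regulome_index(target)
        per_tissue: dict[str, IntervalIndex] = {}
        for region in source.regions(include_dynamic=self.include_dynamic_queries):
            if self.same_tissue:
                idx = per_tissue.get(region.home_tissue)
                if idx is None:
                    idx = _regulome_index(target, tissue=region.home_tissue)
                    per_tissue[region.home_tissue] = idx
            else:
                idx = full_index
            results[region] = project_region(region, amap, idx, self.cluster_gap)
        return results

    def _mark_one_to_one(self) -> None:
        for fwd, bwd in ((self.forward, self.backward), (self.backward, self.forward)):
            for region, res in fwd.items():
                if res.status != "maintained" or len(res.partners) != 1:
                    continue
                partner = res.partners[0]
                back = bwd.get(partner)
                if (
                    back is not None
                    and back.status == "maintained"
                    and len(back.partners) == 1
                    and back.partners[0] is region
                ):
                    res.one_to_one = True


@dataclass
class ClassCounts:
    """Directional P_A/P_N/P_L/P_M counts for one region class."""

    p_a: dict[str, int]
    p_n: dict[str, int]
    p_l: dict[str, int]
    p_m: dict[str, int]
    excluded_multi: dict[str, int]

    def p_r(self, direction: str) -> int:
        return self.p_n[direction] + self.p_l[direction]

    def maintenance_fraction_pct(self) -> float | None:
        """Mean over the two directions of 100 * P_M / (P_M + P_L)."""
        fracs = []
        for d in self.p_m:
            alignable = self.p_m[d] + self.p_l[d]
            if alignable == 0:
                return None
            fracs.append(100.0 * self.p_m[d] / alignable)
        return float(np.mean(fracs))


@dataclass
class PairwiseEvolutionSummary:
    species_pair: tuple[str, str]
    divergence_mya: float
    classes: dict[str, ClassCounts]


def _class_key(region: RegulatoryRegion, stratify_specificity: bool) -> str:
    if not stratify_specificity:
        return region.signature
    spec = (
        "tissue_specific"
        if region.specificity == "tissue_specific"
        else "tissue_shared"
    )
    return f"{region.signature}|{spec}"


def summarize_pair(
    pair: PairProjection,
    divergence_mya: float,
    stratify_specificity: bool = False,
) -> PairwiseEvolutionSummary:
    """Tally the maintained / recently-evolved partition for a species pair.

    Class keys are signatures, optionally crossed with tissue-specificity of
    the query region (the maintenance test itself ignores the partner's
    tissue and signature).
    """
    sp_i = pair.regulome_i.species
    sp_j = pair.regulome_j.species
    d_ij, d_ji = f"{sp_i}->{sp_j}", f"{sp_j}->{sp_i}"
    classes: dict[str, ClassCounts] = {}

    def counts_for(key: str) -> ClassCounts:
        if key not in classes:
            zeros = lambda: {d_ij: 0, d_ji: 0}
            classes[key] = ClassCounts(zeros(), zeros(), zeros(), zeros(), zeros())
        return classes[key]

    status_field = {
        "unaligned": "p_n",
        "aligned_no_regulation": "p_l",
        "maintained": "p_m",
    }
    for direction, results in ((d_ij, pair.forward), (d_ji, pair.backward)):
        for region, res in results.items():
            cc = counts_for(_class_key(region, stratify_specificity))
            if res.status == "multi_mapped_excluded":
                cc.excluded_multi[direction] += 1
                continue
            cc.p_a[direction] += 1
            getattr(cc, status_field[res.status])[direction] += 1
    return PairwiseEvolutionSummary((sp_i, sp_j), divergence_mya, classes)


@dataclass
class ReplicateReproducibility:
    species: str
    tissue: str | None
    replicate_pair: tuple[str, str]
    p_i: dict[str, dict[str, int]]  # per class: direction -> overlap count
    p_a: dict[str, dict[str, int]]
    fraction_pct: dict[str, float | None]


def replicate_zero_point(
    regulome_k: Regulome,
    regulome_l: Regulome,
    labels: tuple[str, str] = ("k", "l"),
) -> ReplicateReproducibility:
    """Inter-individual reproducibility between two replicate-subset regulomes.

    Both regulomes live on the same genome, so the overlap test is direct
    (>=1 base against any regulatory region of the other build). The
    per-class fraction is the mean over the two directions of
    ``100 * P_I / P_A``; it anchors the rate regressions at divergence 0.
    """
    k, l = labels
    d_kl, d_lk = f"{k}->{l}", f"{l}->{k}"
    idx = {k: _regulome_index(regulome_k), l: _regulome_index(regulome_l)}
    p_i: dict[str, dict[str, int]] = {}
    p_a: dict[str, dict[str, int]] = {}
    for direction, source, target_label in ((d_kl, regulome_k, l), (d_lk, regulome_l, k)):
        for region in source.regions(include_dynamic=False):
            sig = region.signature
            p_i.setdefault(sig, {d_kl: 0, d_lk: 0})
            p_a.setdefault(sig, {d_kl: 0, d_lk: 0})
            p_a[sig][direction] += 1
            if idx[target_label].any_overlap(region.interval):
                p_i[sig][direction] += 1
    fraction: dict[str, float | None] = {}
    for sig in p_a:
        fracs = []
        undefined = False
        for d in (d_kl, d_lk):
            if p_a[sig][d] == 0:
                undefined = True
                break
            fracs.append(100.0 * p_i[sig][d] / p_a[sig][d])
        fraction[sig] = None if undefined else float(np.mean(fracs))
    return ReplicateReproducibility(
        species=regulome_k.species,
        tissue=None,
        replicate_pair=labels,
        p_i=p_i,
        p_a=p_a,
        fraction_pct=fraction,
    )


@dataclass
class RateFit:
    category: str
    slope: float  # percentage points per MY
    intercept: float
    slope_se: float
    n_points: int


def fit_rate(
    points: list[tuple[float, float, str]],
) -> tuple[dict[str, RateFit], dict[tuple[str, str], float]]:
    """Per-category OLS of maintenance fraction on divergence time.

    ``points`` are ``(divergence_mya, fraction_pct, category)``; zero points
    from replicate reproducibility enter as ordinary points at divergence 0.
    Returns per-category fits plus, for every category pair, the p-value of
    the divergence x category interaction from the F-test (two-way ANOVA) on
    the joint linear model.
    """
    df = pd.DataFrame(points, columns=["divergence", "fraction", "category"])
    fits: dict[str, RateFit] = {}
    for cat, sub in df.groupby("category"):
        if len(sub) < 2:
            raise ValueError(f"category {cat!r} needs >=2 points")
        X = sm.add_constant(sub["divergence"].to_numpy())
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError(f"singular design for category {cat!r}")
        model = sm.OLS(sub["fraction"].to_numpy(), X).fit()
        fits[str(cat)] = RateFit(
            category=str(cat),
            slope=float(model.params[1]),
            intercept=float(model.params[0]),
            slope_se=float(model.bse[1]),
            n_points=len(sub),
        )
    interactions: dict[tuple[str, str], float] = {}
    cats = sorted(df["category"].unique())
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            sub = df[df["category"].isin([a, b])]
            joint = smf.ols("fraction ~ divergence * C(category)", data=sub).fit()
            anova = sm.stats.anova_lm(joint, typ=2)
            ss_int = float(anova.loc["divergence:C(category)", "sum_sq"])
            ss_total = float(anova["sum_sq"].sum())
            if ss_int <= 1e-10 * max(ss_total, 1.0):
                # exactly parallel categories (zero interaction signal);
                # the F ratio is 0/0 and the test carries no evidence
                interactions[(a, b)] = 1.0
            else:
                interactions[(a, b)] = float(anova.loc["divergence:C(category)", "PR(>F)"])
    return fits, interactions


@dataclass
class SignatureAlignmentTable:
    """Partner-signature decomposition of 1-to-1 maintained regions.

    Per direction and source class, ``partner_counts`` holds the counts of
    partners that are stable promoters (P), active enhancers (AE), primed
    enhancers (PE), intra-species dynamic promoter regions (DP), and
    intra-species dynamic enhancer regions (DE); their sum is the number of
    1-to-1 maintained regions of that class.
    """

    species_pair: tuple[str, str]
    partner_counts: dict[str, dict[str, dict[str, int]]]  # direction -> class -> column
    promoter_switch_pct: float | None  # mean over directions of 100 * (AE+PE)/NP_M
    ae_to_pe_switch_pct: dict[str, float | None]  # directional 100 * PE/NAE_M

    def np_m(self, direction: str, source_class: str) -> int:
        return sum(self.partner_counts[direction][source_class].values())


PARTNER_COLUMNS = ("P", "AE", "PE", "DP", "DE")


def _partner_column(partner: RegulatoryRegion) -> str:
    if partner.intra_dynamic == "dynamic_PE":
        return "DP"
    if partner.intra_dynamic == "dynamic_E":
        return "DE"
    return {"AP": "P", "AE": "AE", "PE": "PE"}[partner.signature]


def signature_decomposition(pair: PairProjection) -> SignatureAlignmentTable:
    """Decompose 1-to-1 maintained regions by the partner's signature.

    The promoter switch fraction counts promoters whose (stable) partner is
    an active or primed enhancer; the enhancer switch fraction counts active
    enhancers whose partner is a primed enhancer, reported per direction.
    """
    sp_i, sp_j = pair.regulome_i.species, pair.regulome_j.species
    d_ij, d_ji = f"{sp_i}->{sp_j}", f"{sp_j}->{sp_i}"
    counts: dict[str, dict[str, dict[str, int]]] = {
        d: {sig: {c: 0 for c in PARTNER_COLUMNS} for sig in SIGNATURES}
        for d in (d_ij, d_ji)
    }
    for direction, results in ((d_ij, pair.forward), (d_ji, pair.backward)):
        for region, res in results.items():
            if not res.one_to_one:
                continue
            col = _partner_column(res.partners[0])
            counts[direction][region.signature][col] += 1

    switch_fracs = []
    for d in (d_ij, d_ji):
        row = counts[d]["AP"]
        total = sum(row.values())
        if total == 0:
            switch_fracs = None
            break
        switch_fracs.append(100.0 * (row["AE"] + row["PE"]) / total)
    promoter_switch = None if switch_fracs is None else float(np.mean(switch_fracs))

    ae_switch: dict[str, float | None] = {}
    for d in (d_ij, d_ji):
        row = counts[d]["AE"]
        total = sum(row.values())
        ae_switch[d] = None if total == 0 else 100.0 * row["PE"] / total
    return SignatureAlignmentTable(
        species_pair=(sp_i, sp_j),
        partner_counts=counts,
        promoter_switch_pct=promoter_switch,
        ae_to_pe_switch_pct=ae_switch,
    )
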