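"""Outgroup triad analysis and the ancestral-state transition model.

A triad is two ingroup species plus one outgroup. Genomic regions kept for
the analysis must be maintained with a 1-to-1 alignment as AP, AE, or PE in
all three species and intra-species dynamic in none of them. Each region
contributes one count to a table row keyed by the unordered pair of ingroup
signatures, under the column of its outgroup signature, and one count to a
background ("All") marginal.

Parsimony orients signature changes: when the outgroup shares a signature X
with at least one ingroup, the ancestral state is inferred to be X, and an
ingroup carrying Y != X witnessed one X -> Y change. Configurations where the
two ingroups agree on X but the outgroup shows Y admit two equally
parsimonious histories and are excluded from model estimation (but retained
in the table). Row-normalizing the pooled counts yields the 3x3
ancestral -> derived transition probability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evolution import AlignmentMap, PairProjection
from .regulome import RegulatoryRegion, Regulome, SIGNATURES
from .stats import chi_square_against_background

__all__ = [
    "TriadTable",
    "TransitionModel",
    "build_triad_table",
    "triad_chi_square",
    "estimate_transition_model",
    "ROW_KEYS",
]

ROW_KEYS = (
    ("AP", "AP"),
    ("AP", "AE"),
    ("AP", "PE"),
    ("AE", "AE"),
    ("AE", "PE"),
    ("PE", "PE"),
)


def _row_key(sig_a: str, sig_b: str) -> tuple[str, str]:
    order = {s: i for i, s in enumerate(SIGNATURES)}
    return (sig_a, sig_b) if order[sig_a] <= order[sig_b] else (sig_b, sig_a)


@dataclass
class TriadTable:
    """Counts of outgroup signatures per unordered ingroup signature pair."""

    triad: tuple[str, str, str]  # (ingroup_a, ingroup_b, outgroup)
    rows: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ROW_KEYS:
            self.rows.setdefault(key, {s: 0 for s in SIGNATURES})

    def add(self, sig_a: str, sig_b: str, sig_out: str) -> None:
        self.rows[_row_key(sig_a, sig_b)][sig_out] += 1

    def background(self) -> dict[str, int]:
        """Marginal outgroup-signature counts over every considered region."""
        out = {s: 0 for s in SIGNATURES}
        for row in self.rows.values():
            for s, n in row.items():
                out[s] += n
        return out

    def total(self) -> int:
        return sum(self.background().values())


def build_triad_table(
    regulome_a: Regulome,
    regulome_b: Regulome,
    regulome_out: Regulome,
    maps: dict[frozenset[str], AlignmentMap],
    cluster_gap: int = 10_000,
) -> TriadTable:
    """Tally outgroup signatures for regions maintained across a triad.

    Anchored on the first ingroup: a region enters iff it is 1-to-1
    maintained toward both the other ingroup and the outgroup, its ingroup-b
    partner is itself 1-to-1 maintained toward the outgroup with the *same*
    outgroup partner, and none of the three copies is intra-species dynamic.
    """
    sp_a, sp_b, sp_o = regulome_a.species, regulome_b.species, regulome_out.species
    for pair in (frozenset((sp_a, sp_b)), frozenset((sp_a, sp_o)), frozenset((sp_b, sp_o))):
        if pair not in maps:
            raise ValueError(f"missing alignment map for pair {sorted(pair)}")
    pp_ab = PairProjection(regulome_a, regulome_b, maps[frozenset((sp_a, sp_b))], cluster_gap)
    pp_ao = PairProjection(regulome_a, regulome_out, maps[frozenset((sp_a, sp_o))], cluster_gap)
    pp_bo = PairProjection(regulome_b, regulome_out, maps[frozenset((sp_b, sp_o))], cluster_gap)

    table = TriadTable((sp_a, sp_b, sp_o))
    for region, res_ab in pp_ab.forward.items():
        if not res_ab.one_to_one:
            continue
        res_ao = pp_ao.forward.get(region)
        if res_ao is None or not res_ao.one_to_one:
            continue
        partner_b = res_ab.partners[0]
        partner_o = res_ao.partners[0]
        if partner_b.is_dynamic or partner_o.is_dynamic:
            continue
        res_bo = pp_bo.forward.get(partner_b)
        if res_bo is None or not res_bo.one_to_one or res_bo.partners[0] is not partner_o:
            continue
        table.add(region.signature, partner_b.signature, partner_o.signature)
    return table


def triad_chi_square(
    table: TriadTable, row: tuple[str, str]
) -> tuple[float, float]:
    """Chi-square (df=2) of one row's outgroup split against the background.

    Expected counts come from the background ("All") proportions scaled to
    the row total; the two-tailed p is the df=2 upper tail.
    """
    key = _row_key(*row)
    obs = table.rows[key]
    bg = table.background()
    observed = tuple(obs[s] for s in SIGNATURES)
    background = tuple(bg[s] for s in SIGNATURES)
    return chi_square_against_background(observed, background)  # type: ignore[arg-type]


@dataclass
class TransitionModel:
    """Row-stochastic ancestral -> derived signature probability matrix."""

    states: tuple[str, str, str]
    matrix: np.ndarray  # 3x3, rows sum to 1 (NaN row when a state has no counts)
    counts: np.ndarray  # raw parsimony counts feeding each row
    state_totals: dict[str, int]

    def prob(self, ancestral: str, derived: str) -> float:
        i = self.states.index(ancestral)
        j = self.states.index(derived)
        return float(self.matrix[i, j])


def estimate_transition_model(tables: list[TriadTable]) -> TransitionModel:
    """Estimate the transition matrix from pooled parsimony-usable counts.

    For ancestral state X: the count of X -> X is the {X,X} row's outgroup-X
    cell; the count of X -> Y (Y != X) is the {X,Y} row's outgroup-X cell.
    Raw counts are summed across tables before row normalization, so pooling
    two identical tables leaves the model unchanged.
    """
    if not tables:
        raise ValueError("need at least one triad table")
    counts = np.zeros((3, 3), dtype=float)
    idx = {s: i for i, s in enumerate(SIGNATURES)}
    for table in tables:
        for x in SIGNATURES:
            for y in SIGNATURES:
                counts[idx[x], idx[y]] += table.rows[_row_key(x, y)][x]
    matrix = np.full((3, 3), np.nan)
    totals: dict[str, int] = {}
    for i, s in enumerate(SIGNATURES):
        row_total = counts[i].sum()
        totals[s] = int(row_total)
        if row_total > 0:
            matrix[i] = counts[i] / row_total
            assert abs(matrix[i].sum() - 1.0) < 1e-9
    return TransitionModel(
        states=tuple(SIGNATURES),  # type: ignore[arg-type]
        matrix=matrix,
        counts=counts,
        state_totals=totals,
    )
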