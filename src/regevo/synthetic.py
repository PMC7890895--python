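"""Forward simulator of regulome evolution with recorded ground truth.

The generative model mirrors what the analysis assumes:

* A set of ancestral regulatory regions, each with a signature (AP/AE/PE)
  and a tissue-activity set, placed in disjoint slots on a small multi-
  chromosome genome.
* Evolution down a phylogeny with branch lengths in million years (MY):
  per branch, each region survives with probability ``1 - slope * t / 100``
  (linear maintenance decay in divergence time; an exponential mode exists
  for sensitivity checks) and its signature transitions according to a
  per-MY row-stochastic matrix raised to the branch length.
* Per-species coordinates drift by insertions between slots; pairwise
  alignment maps are gapless per-slot blocks, and each block independently
  becomes unalignable along each branch at a configurable per-MY rate.
* Observed data are per-replicate histone-mark peak calls (AP regions emit
  coincident H3K4me3 + H3K27ac, AE emit H3K27ac + H3K4me1, PE emit H3K4me1)
  with Gaussian boundary jitter, replicate dropout, and non-reproducible
  noise peaks that never touch true regions (unless ``hard_noise``).
* L1/L2 repeat elements with configurable densities, length and divergence
  distributions, and a placement odds ratio favouring tissue-specific over
  tissue-shared regions.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml
from scipy.linalg import expm, logm

from .intervals import GenomicInterval
from .io import (
    AlignmentBlock,
    RepeatElement,
    write_alignment_map,
    write_bed,
    write_divergence_table,
    write_repeat_table,
    BedRecord,
)

__all__ = [
    "RepeatFamilyConfig",
    "SimulationConfig",
    "RegionTruth",
    "SimulationTruth",
    "SimulationResult",
    "simulate",
    "write_simulation",
    "make_fixture",
    "branch_transition_matrix",
    "FIXTURES",
]

DEFAULT_NEWICK = "(((mouse:21,rat:21):61,rabbit:82):14,dog:96);"
MARKS_BY_SIGNATURE = {
    "AP": ("H3K4me3", "H3K27ac"),
    "AE": ("H3K27ac", "H3K4me1"),
    "PE": ("H3K4me1",),
}
_SIGS = ("AP", "AE", "PE")


@dataclass(frozen=True)
class RepeatFamilyConfig:
    density_per_mb: float
    length_mean: float
    length_sd: float
    divergence_mean: float
    divergence_sd: float
    odds_tissue_specific: float  # placement odds vs tissue-shared regions


def _default_repeats() -> dict[str, RepeatFamilyConfig]:
    # L1 elements are younger (lower % divergence) and longer than L2s and
    # preferentially land in tissue-specific regions; L2s are ancient and
    # lean toward tissue-shared regions.
    return {
        "L1": RepeatFamilyConfig(60.0, 800.0, 400.0, 12.0, 6.0, 2.0),
        "L2": RepeatFamilyConfig(40.0, 350.0, 150.0, 28.0, 6.0, 0.5),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    newick: str = DEFAULT_NEWICK
    n_ancestral_regions: int = 5000
    signature_proportions: dict[str, float] = field(
        default_factory=lambda: {"AP": 0.2, "AE": 0.4, "PE": 0.4}
    )
    tissue_specific_fraction: dict[str, float] = field(
        default_factory=lambda: {"AP": 0.4, "AE": 0.76, "PE": 0.83}
    )
    tissues: tuple[str, ...] = ("liver", "muscle", "brain", "testis")
    loss_slope: float | dict[str, float] = 0.3  # % per MY, optionally per specificity
    switch_matrix: list[list[float]] = field(
        default_factory=lambda: [
            [0.9990, 0.0007, 0.0003],
            [0.0005, 0.9985, 0.0010],
            [0.0003, 0.0012, 0.9985],
        ]
    )
    peak_jitter_sd: float = 10.0
    replicate_dropout: float = 0.1
    n_replicates: int = 3
    noise_peak_rate: float = 5.0  # peaks per Mb per (tissue, mark, replicate)
    repeat_config: dict[str, RepeatFamilyConfig] = field(default_factory=_default_repeats)
    repeat_fraction_in_regions: float = 0.3
    alignability_loss: float = 0.002  # per-MY probability a block turns unalignable
    n_chromosomes: int = 3
    slot_bp: int = 2400
    region_min_len: int = 400
    region_max_len: int = 1200
    exponential_decay: bool = False
    hard_noise: bool = False

    def __post_init__(self) -> None:
        M = np.asarray(self.switch_matrix, dtype=float)
        if M.shape != (3, 3) or np.any(M < 0) or np.any(M > 1):
            raise ValueError("switch_matrix must be 3x3 with entries in [0, 1]")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("switch_matrix rows must sum to 1")
        if abs(sum(self.signature_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("signature_proportions must sum to 1")
        if self.slot_bp - self.region_max_len < 1000:
            raise ValueError(
                "slot_bp must exceed region_max_len by >=1000 bp so noise and "
                "repeat placement in slot margins stays clear of true regions"
            )
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates for reproducible-peak calling")


def branch_transition_matrix(per_my: np.ndarray, t: float) -> tuple[np.ndarray, str]:
    """Signature transition matrix along a branch of ``t`` MY.

    Uses ``expm(t * logm(M))`` when the per-MY matrix is embeddable (its
    matrix log is a valid rate generator), otherwise repeated per-MY
    application via an integer matrix power. Returns the matrix and the
    method used.
    """
    M = np.asarray(per_my, dtype=float)
    if t == 0:
        return np.eye(3), "identity"
    try:
        G = logm(M)
        if np.max(np.abs(G.imag)) < 1e-9:
            G = G.real
            off = G - np.diag(np.diag(G))
            if np.min(off) >= -1e-9:
                Mt = expm(t * G).real
                Mt = np.clip(Mt, 0.0, None)
                Mt /= Mt.sum(axis=1, keepdims=True)
                return Mt, "matrix_exponential"
    except Exception:
        pass
    Mt = np.linalg.matrix_power(M, max(1, round(t)))
    Mt /= Mt.sum(axis=1, keepdims=True)
    return Mt, "per_my_power"


@dataclass
class RegionTruth:
    region_id: int
    chrom: str
    slot: int
    ancestral_signature: str
    tissues: frozenset[str]
    specificity: str  # tissue_specific / tissue_shared
    # per species: (alive, signature, interval in that species' coordinates)
    per_species: dict[str, tuple[bool, str, GenomicInterval]] = field(default_factory=dict)


@dataclass
class SimulationTruth:
    config: SimulationConfig
    regions: list[RegionTruth]
    branch_method: str
    repeat_target_counts: dict[str, dict[str, int]]  # family -> placement intent tallies


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: SimulationTruth
    species: list[str]
    peaks: dict[tuple[str, str, str, str], list[GenomicInterval]]
    maps: dict[frozenset[str], list[AlignmentBlock]]
    repeats: dict[str, list[RepeatElement]]
    tss: dict[str, list[tuple[GenomicInterval, str]]]
    divergence_mya: dict[frozenset[str], float]
    genome_sizes: dict[str, dict[str, int]]


def _tree_structures(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    nodes = list(tree.preorder_node_iter())
    leaves = [nd for nd in nodes if nd.is_leaf()]
    leaf_names = [nd.taxon.label.replace(" ", "_") for nd in leaves]
    if len(leaf_names) < 2:
        raise ValueError("tree must have at least 2 leaves")
    pdm = tree.phylogenetic_distance_matrix()
    divergence: dict[frozenset[str], float] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            d = pdm.patristic_distance(a.taxon, b.taxon)
            divergence[
                frozenset(
                    (a.taxon.label.replace(" ", "_"), b.taxon.label.replace(" ", "_"))
                )
            ] = d / 2.0
    # edges on the path between each leaf pair: symmetric difference of
    # root-to-leaf edge sets
    edge_ids: dict[int, float] = {}
    path_to_root: dict[str, set[int]] = {}
    for idx, nd in enumerate(nodes):
        if nd.parent_node is not None:
            edge_ids[idx] = nd.edge.length or 0.0
    for leaf in leaves:
        name = leaf.taxon.label.replace(" ", "_")
        edges: set[int] = set()
        nd = leaf
        while nd.parent_node is not None:
            edges.add(nodes.index(nd))
            nd = nd.parent_node
        path_to_root[name] = edges
    return tree, nodes, leaf_names, divergence, edge_ids, path_to_root


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    vals = rng.normal(mean, sd, size=size)
    return np.clip(vals, lo, hi)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the forward simulation; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree, nodes, species, divergence, edge_lengths, path_to_root = _tree_structures(
        config.newick
    )
    n = config.n_ancestral_regions
    n_chrom = config.n_chromosomes
    slot = config.slot_bp
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    slots_per_chrom = -(-n // n_chrom)
    base_chrom_len = slots_per_chrom * slot + slot

    # --- ancestral regions -------------------------------------------------
    sig_probs = [config.signature_proportions[s] for s in _SIGS]
    anc_sig = rng.choice(3, size=n, p=sig_probs)
    lengths = rng.integers(config.region_min_len, config.region_max_len + 1, size=n)
    slot_chrom = np.arange(n) % n_chrom
    slot_col = np.arange(n) // n_chrom
    anc_start = slot_col * slot + (slot - lengths) // 2

    tissue_sets: list[frozenset[str]] = []
    specificity = np.empty(n, dtype=object)
    n_tissues = len(config.tissues)
    for i in range(n):
        frac = config.tissue_specific_fraction[_SIGS[anc_sig[i]]]
        if rng.random() < frac or n_tissues == 1:
            chosen = [config.tissues[rng.integers(n_tissues)]]
            specificity[i] = "tissue_specific"
        else:
            k = int(rng.choice([2, 3, 4], p=[0.5, 0.3, 0.2]))
            k = min(k, n_tissues)
            chosen = list(rng.choice(n_tissues, size=k, replace=False))
            chosen = [config.tissues[c] for c in chosen]
            specificity[i] = "tissue_shared"
        tissue_sets.append(frozenset(chosen))

    # --- evolution down the tree ------------------------------------------
    def survival_prob(t: float) -> np.ndarray:
        if isinstance(config.loss_slope, dict):
            slopes = np.array(
                [config.loss_slope[specificity[i]] for i in range(n)], dtype=float
            )
        else:
            slopes = np.full(n, float(config.loss_slope))
        if config.exponential_decay:
            return np.exp(-slopes * t / 100.0)
        return np.clip(1.0 - slopes * t / 100.0, 0.0, 1.0)

    M_per_my = np.asarray(config.switch_matrix, dtype=float)
    branch_method = "identity"
    node_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    node_state[0] = (np.ones(n, dtype=bool), anc_sig.copy())
    for idx, nd in enumerate(nodes):
        if idx == 0:
            continue
        parent_idx = nodes.index(nd.parent_node)
        t = edge_lengths[idx]
        p_alive, p_sig = node_state[parent_idx]
        alive = p_alive & (rng.random(n) < survival_prob(t))
        Mt, method = branch_transition_matrix(M_per_my, t)
        if method != "identity":
            branch_method = method
        sig = p_sig.copy()
        for s in range(3):
            sel = np.flatnonzero(p_sig == s)
            if sel.size:
                sig[sel] = rng.choice(3, size=sel.size, p=Mt[s])
        node_state[idx] = (alive, sig)

    leaf_state = {
        nd.taxon.label.replace(" ", "_"): node_state[nodes.index(nd)]
        for nd in nodes
        if nd.is_leaf()
    }

    # --- per-species coordinate drift (insertions between slots) ----------
    offsets: dict[str, np.ndarray] = {}
    genome_sizes: dict[str, dict[str, int]] = {}
    for sp in species:
        indels = rng.integers(0, 41, size=(n_chrom, slots_per_chrom))
        offsets[sp] = np.cumsum(indels, axis=1)
        genome_sizes[sp] = {
            chroms[c]: int(base_chrom_len + offsets[sp][c, -1]) for c in range(n_chrom)
        }

    def species_interval(sp: str, i: int) -> GenomicInterval:
        c, j = int(slot_chrom[i]), int(slot_col[i])
        off = int(offsets[sp][c, j])
        return GenomicInterval(
            chroms[c], int(anc_start[i] + off), int(anc_start[i] + lengths[i] + off)
        )

    # --- alignment blocks and per-branch alignability loss -----------------
    edge_block_survival: dict[int, np.ndarray] = {}
    for idx, t in edge_lengths.items():
        p = (1.0 - config.alignability_loss) ** t
        edge_block_survival[idx] = rng.random(n) < p

    maps: dict[frozenset[str], list[AlignmentBlock]] = {}
    for pair in divergence:
        a, b = sorted(pair)
        path_edges = path_to_root[a] ^ path_to_root[b]
        alignable = np.ones(n, dtype=bool)
        for e in path_edges:
            alignable &= edge_block_survival[e]
        blocks: list[AlignmentBlock] = []
        for i in np.flatnonzero(alignable):
            c, j = int(slot_chrom[i]), int(slot_col[i])
            s0 = j * slot
            iv_a = GenomicInterval(chroms[c], s0 + int(offsets[a][c, j]), s0 + slot + int(offsets[a][c, j]))
            iv_b = GenomicInterval(chroms[c], s0 + int(offsets[b][c, j]), s0 + slot + int(offsets[b][c, j]))
            blocks.append(AlignmentBlock(iv_a, iv_b, a, b))
        maps[pair] = blocks

    # --- truth records ------------------------------------------------------
    regions: list[RegionTruth] = []
    for i in range(n):
        rec = RegionTruth(
            region_id=i,
            chrom=chroms[int(slot_chrom[i])],
            slot=int(slot_col[i]),
            ancestral_signature=_SIGS[int(anc_sig[i])],
            tissues=tissue_sets[i],
            specificity=str(specificity[i]),
        )
        for sp in species:
            alive, sig = leaf_state[sp]
            rec.per_species[sp] = (
                bool(alive[i]),
                _SIGS[int(sig[i])],
                species_interval(sp, i),
            )
        regions.append(rec)

    # --- peak emission ------------------------------------------------------
    jitter = config.peak_jitter_sd
    peaks: dict[tuple[str, str, str, str], list[GenomicInterval]] = {}
    rep_ids = [f"rep{r + 1}" for r in range(config.n_replicates)]
    for sp in species:
        for tissue in config.tissues:
            for mark in ("H3K4me3", "H3K27ac", "H3K4me1"):
                for rep in rep_ids:
                    peaks[(sp, tissue, mark, rep)] = []
    for rec in regions:
        c = chroms.index(rec.chrom)
        j = rec.slot
        for sp in species:
            alive, sig, iv = rec.per_species[sp]
            if not alive:
                continue
            off = int(offsets[sp][c, j])
            slot_lo, slot_hi = j * slot + off + 1, (j + 1) * slot + off - 1
            for tissue in rec.tissues:
                for mark in MARKS_BY_SIGNATURE[sig]:
                    for rep in rep_ids:
                        if config.replicate_dropout > 0 and rng.random() < config.replicate_dropout:
                            continue
                        if jitter > 0:
                            ds = int(round(rng.normal(0.0, jitter)))
                            de = int(round(rng.normal(0.0, jitter)))
                        else:
                            ds = de = 0
                        s = min(max(slot_lo, iv.start + ds), iv.end - 50)
                        e = max(min(slot_hi, iv.end + de), s + 50)
                        peaks[(sp, tissue, mark, rep)].append(
                            GenomicInterval(iv.seq_id, s, e)
                        )

    # Noise peaks are confined to slot margins, never touch a true region,
    # and are laid out on a per-replicate raster (170 bp stride, <=120 bp
    # long) so peaks from different replicates cannot reciprocally overlap
    # and become a spurious reproducible consensus.
    genome_mb = sum(genome_sizes[species[0]].values()) / 1e6
    margin = (slot - config.region_max_len) // 2
    for sp in species:
        for tissue in config.tissues:
            for mark in ("H3K4me3", "H3K27ac", "H3K4me1"):
                for rep_idx, rep in enumerate(rep_ids):
                    for _ in range(rng.poisson(config.noise_peak_rate * genome_mb)):
                        i = int(rng.integers(n))
                        c, j = int(slot_chrom[i]), int(slot_col[i])
                        length = int(rng.integers(60, 121))
                        off = int(offsets[sp][c, j])
                        iv = species_interval(sp, i)
                        raster = (rep_idx % 3) * 170
                        if config.hard_noise and rng.random() < 0.3:
                            s = iv.start + int(rng.integers(0, max(1, iv.length() // 2)))
                        elif rng.integers(2) == 0:
                            s = j * slot + off + 10 + raster
                        else:
                            s = iv.end + 40 + raster
                            if s + length > (j + 1) * slot + off - 10:
                                continue
                        peaks[(sp, tissue, mark, rep)].append(
                            GenomicInterval(chroms[c], s, s + length)
                        )

    # --- repeats ------------------------------------------------------------
    repeats: dict[str, list[RepeatElement]] = {}
    intent: dict[str, dict[str, int]] = {
        fam: {"in_specific": 0, "in_shared": 0, "background": 0}
        for fam in config.repeat_config
    }
    for sp in species:
        alive_ids = [i for i in range(n) if leaf_state[sp][0][i]]
        weights = {}
        for fam, fc in config.repeat_config.items():
            w = np.array(
                [
                    fc.odds_tissue_specific if specificity[i] == "tissue_specific" else 1.0
                    for i in alive_ids
                ],
                dtype=float,
            )
            weights[fam] = w / w.sum() if w.sum() > 0 else None
        sp_mb = sum(genome_sizes[sp].values()) / 1e6
        elements: list[RepeatElement] = []
        for fam, fc in sorted(config.repeat_config.items()):
            count = rng.poisson(fc.density_per_mb * sp_mb)
            lens = _truncated_normal(rng, fc.length_mean, fc.length_sd, 50, 1000, count)
            divs = _truncated_normal(
                rng, fc.divergence_mean, fc.divergence_sd, 0.5, 60.0, count
            )
            for k in range(count):
                length = int(lens[k])
                if alive_ids and weights[fam] is not None and rng.random() < config.repeat_fraction_in_regions:
                    ridx = alive_ids[int(rng.choice(len(alive_ids), p=weights[fam]))]
                    iv = species_interval(sp, ridx)
                    start = max(0, iv.start - length // 2)
                    intent[fam][
                        "in_specific" if specificity[ridx] == "tissue_specific" else "in_shared"
                    ] += 1
                    seq = iv.seq_id
                else:
                    i = int(rng.integers(n))
                    c, j = int(slot_chrom[i]), int(slot_col[i])
                    off = int(offsets[sp][c, j])
                    start = j * slot + off + 5
                    length = min(length, margin - 30)
                    seq = chroms[c]
                    intent[fam]["background"] += 1
                elements.append(
                    RepeatElement(
                        GenomicInterval(seq, start, start + max(50, length), "+"),
                        "LINE",
                        fam,
                        float(divs[k]),
                    )
                )
        repeats[sp] = elements

    # --- TSS annotation (one gene every 4th slot) --------------------------
    tss: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for sp in species:
        entries = []
        for i in range(0, n, 4):
            c, j = int(slot_chrom[i]), int(slot_col[i])
            off = int(offsets[sp][c, j])
            pos = j * slot + off + 10
            entries.append(
                (GenomicInterval(chroms[c], pos, pos + 1), f"g{chroms[c]}_{j}")
            )
        tss[sp] = entries

    truth = SimulationTruth(
        config=config,
        regions=regions,
        branch_method=branch_method,
        repeat_target_counts=intent,
    )
    return SimulationResult(
        config=config,
        truth=truth,
        species=species,
        peaks=peaks,
        maps=maps,
        repeats=repeats,
        tss=tss,
        divergence_mya=divergence,
        genome_sizes=genome_sizes,
    )


def write_simulation(result: SimulationResult, out_dir: str | Path) -> list[Path]:
    """Write every simulated input to ``out_dir``; returns written paths."""
    out = Path(out_dir)
    written: list[Path] = []

    def record(path: Path) -> Path:
        written.append(path)
        return path

    peaks_dir = out / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    for (sp, tissue, mark, rep), ivs in sorted(result.peaks.items()):
        path = peaks_dir / f"{sp}.{tissue}.{mark}.{rep}.bed"
        write_bed(sorted(ivs), record(path))
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for pair, blocks in sorted(result.maps.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        write_alignment_map(blocks, record(maps_dir / f"{a}__{b}.tsv"))
    rep_dir = out / "repeats"
    rep_dir.mkdir(exist_ok=True)
    for sp, elements in sorted(result.repeats.items()):
        write_repeat_table(elements, record(rep_dir / f"{sp}.tsv"))
    tss_dir = out / "tss"
    tss_dir.mkdir(exist_ok=True)
    for sp, entries in sorted(result.tss.items()):
        write_bed(
            [BedRecord(iv, name=gene) for iv, gene in entries],
            record(tss_dir / f"{sp}.bed"),
        )
    write_divergence_table(result.divergence_mya, record(out / "divergence.tsv"))

    lines = ["#region_id\tchrom\tslot\tancestral_signature\ttissues\tspecificity\tspecies\talive\tsignature\tstart\tend"]
    for rec in result.truth.regions:
        for sp in result.species:
            alive, sig, iv = rec.per_species[sp]
            lines.append(
                "\t".join(
                    [
                        str(rec.region_id),
                        rec.chrom,
                        str(rec.slot),
                        rec.ancestral_signature,
                        ",".join(sorted(rec.tissues)),
                        rec.specificity,
                        sp,
                        "1" if alive else "0",
                        sig,
                        str(iv.start),
                        str(iv.end),
                    ]
                )
            )
    record(out / "truth.tsv").write_text("".join(l + "\n" for l in lines))

    cfg = dataclasses.asdict(result.config)
    cfg["repeat_config"] = {
        fam: dataclasses.asdict(fc) for fam, fc in result.config.repeat_config.items()
    }
    cfg["tissues"] = list(result.config.tissues)
    cfg["branch_transition_method"] = result.truth.branch_method
    record(out / "config.resolved.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return written


FIXTURES = ("tiny", "triad", "enrichment")


def make_fixture(name: str, seed: int = 0) -> SimulationConfig:
    """Preset configurations for small, fully-synthetic datasets."""
    if name == "tiny":
        return SimulationConfig(
            seed=seed,
            newick="(speciesA:40,speciesB:40);",
            n_ancestral_regions=200,
            tissues=("liver", "brain"),
            peak_jitter_sd=5.0,
            replicate_dropout=0.05,
            noise_peak_rate=2.0,
        )
    if name == "triad":
        return SimulationConfig(
            seed=seed,
            newick="((ingroup1:21,ingroup2:21):61,outgroup:82);",
            n_ancestral_regions=2000,
            peak_jitter_sd=5.0,
            replicate_dropout=0.05,
        )
    if name == "enrichment":
        repeats = {
            "L1": RepeatFamilyConfig(80.0, 800.0, 400.0, 12.0, 6.0, 3.0),
            "L2": RepeatFamilyConfig(50.0, 350.0, 150.0, 28.0, 6.0, 1.0),
        }
        return SimulationConfig(
            seed=seed,
            newick="(speciesA:40,speciesB:40);",
            n_ancestral_regions=2000,
            repeat_config=repeats,
            repeat_fraction_in_regions=0.4,
            peak_jitter_sd=5.0,
        )
    raise ValueError(f"unknown fixture {name!r}; options: {', '.join(FIXTURES)}")
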