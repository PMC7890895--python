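"""Stage orchestration: simulate -> call -> tissue -> evolve -> triad -> repeats.

``run_pipeline`` executes the stage chain on simulator output (or
pre-existing input files in the same dialects), writing one tabular artifact
per stage plus a JSON manifest with a content hash for every output, so a
rerun under the same seed and configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .evolution import (
    AlignmentMap,
    PairProjection,
    fit_rate,
    replicate_zero_point,
    signature_decomposition,
    summarize_pair,
)
from .intervals import GenomicInterval
from .regulome import (
    Regulome,
    SIGNATURES,
    call_regulatory_regions,
    cross_tissue_classify,
    merge_reproducible_peaks,
    write_regulome,
)
from .repeats import compare_repeat_attribute, partition_repeats, relative_enrichment, shuffle_control
from .synthetic import SimulationConfig, SimulationResult, make_fixture, simulate, write_simulation
from .triads import build_triad_table, estimate_transition_model, triad_chi_square, ROW_KEYS

logger = logging.getLogger("regevo")

__all__ = ["PipelineConfig", "run_pipeline", "build_regulome", "regulomes_from_simulation"]


@dataclass
class PipelineConfig:
    """Resolved thresholds and toggles for one pipeline run.

    Defaults are the analysis defaults used throughout:
    reproducibility needs >=2 replicates with reciprocal 50% overlap,
    enhancer/promoter association within 1 Mb, 10 kb multi-mapping cluster
    gap, and a display floor of 100 occurrences per repeat subgroup.
    """

    seed: int = 0
    fixture: str | None = "tiny"
    sim_config: SimulationConfig | None = None
    min_replicates: int = 2
    ae_overlap_subject: str = "k27ac"
    cluster_gap: int = 10_000
    association_max_dist: int = 1_000_000
    min_display_count: int = 100
    run_triad: bool = True
    run_repeats: bool = True
    stratify_specificity: bool = True


def build_regulome(
    species: str,
    peaks_by_tissue_mark: dict[tuple[str, str], list[list[GenomicInterval]]],
    min_replicates: int = 2,
    ae_overlap_subject: str = "k27ac",
    n_tissues_for_full_share: int = 4,
) -> Regulome:
    """Consensus peaks -> signature calls -> cross-tissue classification.

    ``peaks_by_tissue_mark`` maps (tissue, mark) to per-replicate peak lists.
    """
    regulome = Regulome(species=species)
    tissues = sorted({t for t, _ in peaks_by_tissue_mark})
    for tissue in tissues:
        consensus = {}
        for mark in ("H3K4me3", "H3K27ac", "H3K4me1"):
            reps = peaks_by_tissue_mark.get((tissue, mark), [])
            consensus[mark] = (
                merge_reproducible_peaks(reps, min_replicates) if len(reps) >= min_replicates else []
            )
        regions, unclassified = call_regulatory_regions(
            consensus["H3K4me3"],
            consensus["H3K27ac"],
            consensus["H3K4me1"],
            species,
            tissue,
            ae_overlap_subject=ae_overlap_subject,
        )
        regulome.add_tissue(tissue, regions, unclassified)
    if len(tissues) >= 2:
        cross_tissue_classify(regulome, n_tissues_for_full_share=n_tissues_for_full_share)
    return regulome


def regulomes_from_simulation(
    result: SimulationResult,
    min_replicates: int = 2,
    replicate_subset: tuple[str, ...] | None = None,
) -> dict[str, Regulome]:
    """Build one regulome per simulated species from the emitted peaks."""
    out: dict[str, Regulome] = {}
    for sp in result.species:
        grouped: dict[tuple[str, str], dict[str, list[GenomicInterval]]] = {}
        for (s, tissue, mark, rep), ivs in result.peaks.items():
            if s != sp:
                continue
            if replicate_subset is not None and rep not in replicate_subset:
                continue
            grouped.setdefault((tissue, mark), {}).setdefault(rep, []).append(ivs)
        by_key = {
            key: [ivs for rep in sorted(reps) for ivs in reps[rep]]
            for key, reps in grouped.items()
        }
        out[sp] = build_regulome(
            sp,
            by_key,
            min_replicates=min_replicates,
            n_tissues_for_full_share=len(result.config.tissues),
        )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> Path:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("".join(l + "\n" for l in lines))
    return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all enabled stages; returns the manifest dictionary."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    logger.info("resolved pipeline parameters: %s", asdict(config))

    # stage: simulate
    sim_cfg = config.sim_config
    if sim_cfg is None:
        if config.fixture is None:
            raise ValueError("provide either a fixture name or a SimulationConfig")
        sim_cfg = make_fixture(config.fixture, seed=config.seed)
    result = simulate(sim_cfg)
    artifacts += write_simulation(result, out / "sim")
    logger.info("simulate: %d species, %d regions", len(result.species), len(result.truth.regions))

    # stage: call + tissue
    regulomes = regulomes_from_simulation(result, min_replicates=config.min_replicates)
    for sp, reg in sorted(regulomes.items()):
        path = out / f"regulome_{sp}.bed"
        write_regulome(reg, path)
        artifacts.append(path)

    # stage: evolve
    pair_projections: dict[frozenset[str], PairProjection] = {}
    pair_rows = []
    points: list[tuple[float, float, str]] = []
    decomposition_rows = []
    species = sorted(regulomes)
    for pair, blocks in sorted(result.maps.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        amap = AlignmentMap(blocks)
        pp = PairProjection(
            regulomes[a], regulomes[b], amap, cluster_gap=config.cluster_gap
        )
        pair_projections[pair] = pp
        summary = summarize_pair(
            pp,
            result.divergence_mya[pair],
            stratify_specificity=config.stratify_specificity,
        )
        for cls, cc in sorted(summary.classes.items()):
            frac = cc.maintenance_fraction_pct()
            d_ab = f"{a}->{b}"
            d_ba = f"{b}->{a}"
            pair_rows.append(
                [a, b, f"{summary.divergence_mya:g}", cls,
                 cc.p_a[d_ab], cc.p_n[d_ab], cc.p_l[d_ab], cc.p_m[d_ab],
                 cc.p_a[d_ba], cc.p_n[d_ba], cc.p_l[d_ba], cc.p_m[d_ba],
                 "NA" if frac is None else f"{frac:.4f}"]
            )
            if frac is not None:
                points.append((summary.divergence_mya, frac, cls))
        table = signature_decomposition(pp)
        for direction, per_class in sorted(table.partner_counts.items()):
            for cls, cols in per_class.items():
                decomposition_rows.append(
                    [a, b, direction, cls]
                    + [cols[c] for c in ("P", "AE", "PE", "DP", "DE")]
                )
    artifacts.append(
        _write_tsv(
            out / "pairwise_summary.tsv",
            ["species_a", "species_b", "divergence_mya", "class",
             "P_A_ab", "P_N_ab", "P_L_ab", "P_M_ab",
             "P_A_ba", "P_N_ba", "P_L_ba", "P_M_ba", "maintenance_pct"],
            pair_rows,
        )
    )
    artifacts.append(
        _write_tsv(
            out / "signature_decomposition.tsv",
            ["species_a", "species_b", "direction", "class", "P", "AE", "PE", "DP", "DE"],
            decomposition_rows,
        )
    )

    # replicate zero points (needs >=4 replicates for disjoint halves)
    n_reps = sim_cfg.n_replicates
    if n_reps >= 4:
        half = n_reps // 2
        reps = [f"rep{r + 1}" for r in range(n_reps)]
        subset_k, subset_l = tuple(reps[:half]), tuple(reps[half : 2 * half])
        for sp in species:
            reg_k = regulomes_from_simulation(result, config.min_replicates, subset_k)[sp]
            reg_l = regulomes_from_simulation(result, config.min_replicates, subset_l)[sp]
            zero = replicate_zero_point(reg_k, reg_l)
            for sig, frac in zero.fraction_pct.items():
                if frac is not None:
                    for cls in {c for _, _, c in points if c.startswith(sig)} or {sig}:
                        points.append((0.0, frac, cls))

    fit_rows = []
    categories_ok = {}
    for _, _, c in points:
        categories_ok[c] = categories_ok.get(c, 0) + 1
    fit_points = [p for p in points if categories_ok[p[2]] >= 2]
    if fit_points:
        fits, interactions = fit_rate(fit_points)
        for cat, fit in sorted(fits.items()):
            fit_rows.append(
                [cat, f"{fit.slope:.5f}", f"{fit.intercept:.4f}", f"{fit.slope_se:.5f}", fit.n_points]
            )
        artifacts.append(
            _write_tsv(
                out / "rate_fits.tsv",
                ["category", "slope_pct_per_my", "intercept_pct", "slope_se", "n_points"],
                fit_rows,
            )
        )
        artifacts.append(
            _write_tsv(
                out / "rate_interactions.tsv",
                ["category_a", "category_b", "interaction_p"],
                [[a, b, f"{p:.6g}"] for (a, b), p in sorted(interactions.items())],
            )
        )
    artifacts.append(
        _write_tsv(
            out / "rate_points.tsv",
            ["divergence_mya", "fraction_pct", "category"],
            [[f"{d:g}", f"{f:.4f}", c] for d, f, c in points],
        )
    )

    # stage: triad
    if config.run_triad and len(species) >= 3:
        a, b, outg = species[0], species[1], species[2]
        maps = {pair: AlignmentMap(blocks) for pair, blocks in result.maps.items()}
        table = build_triad_table(
            regulomes[a], regulomes[b], regulomes[outg], maps, cluster_gap=config.cluster_gap
        )
        triad_rows = []
        for key in ROW_KEYS:
            row = table.rows[key]
            total = sum(row.values())
            if total > 0:
                chi2, p = triad_chi_square(table, key)
                chi_s, p_s = f"{chi2:.4f}", f"{p:.6g}"
            else:
                chi_s = p_s = "NA"
            triad_rows.append(
                ["/".join(key)] + [row[s] for s in SIGNATURES] + [chi_s, p_s]
            )
        bg = table.background()
        triad_rows.append(["All"] + [bg[s] for s in SIGNATURES] + ["NA", "NA"])
        artifacts.append(
            _write_tsv(
                out / "triad_table.tsv",
                ["ingroup_pair", "out_AP", "out_AE", "out_PE", "chi2", "p"],
                triad_rows,
            )
        )
        model = estimate_transition_model([table])
        model_rows = [
            [s] + [f"{model.matrix[i, j]:.6f}" for j in range(3)]
            for i, s in enumerate(model.states)
        ]
        artifacts.append(
            _write_tsv(out / "transition_model.tsv", ["ancestral", "AP", "AE", "PE"], model_rows)
        )

    # stage: repeats
    if config.run_repeats:
        enrichment_rows = []
        age_rows = []
        shuffle_rows = []
        for sp in species:
            pps = [
                (pair, pp) for pair, pp in pair_projections.items() if sp in pair
            ]
            maintained: set[int] = set()
            recently: list = []
            dynamic: list = []
            status_by_region: dict[int, str] = {}
            region_objs: dict[int, object] = {}
            for pair, pp in pps:
                results = pp.forward if pp.regulome_i.species == sp else pp.backward
                for region, res in results.items():
                    rid = id(region)
                    region_objs[rid] = region
                    if res.status == "maintained":
                        status_by_region[rid] = "maintained"
                        maintained.add(rid)
                        if res.one_to_one and res.partners[0].signature != region.signature:
                            dynamic.append(region)
                    elif rid not in status_by_region:
                        status_by_region[rid] = "recent"
            dynamic_ids = {id(r) for r in dynamic}
            recently = [
                region_objs[rid]
                for rid, st in status_by_region.items()
                if st == "recent" and rid not in maintained
            ]
            stable = [region_objs[rid] for rid in maintained if rid not in dynamic_ids]
            reps = result.repeats[sp]
            for region_class in SIGNATURES:
                set_specific = [r for r in recently if r.signature == region_class and r.specificity == "tissue_specific"]
                set_shared = [r for r in recently if r.signature == region_class and r.specificity != "tissue_specific"]
                cells = (
                    relative_enrichment(
                        set_specific, set_shared, reps, species=sp, region_class=region_class,
                        min_display=config.min_display_count,
                    )
                    if set_specific and set_shared
                    else []
                )
                for cell in cells:
                    enrichment_rows.append(
                        [sp, "specific_vs_shared", region_class, cell.repeat_group, cell.subgroup,
                         cell.count_a, cell.total_a, cell.count_b, cell.total_b,
                         f"{cell.pct_a:.3f}", f"{cell.pct_b:.3f}", f"{cell.delta:.3f}",
                         f"{cell.p_adj:.6g}", int(cell.displayed)]
                    )
                for cell in relative_enrichment(
                    [r for r in dynamic if r.signature == region_class],
                    [r for r in stable if r.signature == region_class],
                    reps, species=sp, region_class=region_class,
                    min_display=config.min_display_count,
                ) if any(r.signature == region_class for r in dynamic) and any(
                    r.signature == region_class for r in stable
                ) else []:
                    enrichment_rows.append(
                        [sp, "dynamic_vs_stable", region_class, cell.repeat_group, cell.subgroup,
                         cell.count_a, cell.total_a, cell.count_b, cell.total_b,
                         f"{cell.pct_a:.3f}", f"{cell.pct_b:.3f}", f"{cell.delta:.3f}",
                         f"{cell.p_adj:.6g}", int(cell.displayed)]
                    )
            partition = partition_repeats(reps, recently, dynamic)
            comparisons = compare_repeat_attribute(partition, "pct_divergence", "greater")
            for (ca, cb), res in sorted(comparisons.items()):
                age_rows.append(
                    [sp, ca, cb, f"{res['median_first']:.3f}", f"{res['median_second']:.3f}", f"{res['p_value']:.6g}"]
                )
            all_regions = regulomes[sp].regions()
            exclude = [r.interval for r in all_regions]
            sizes = result.genome_sizes[sp]
            ctrl = shuffle_control(
                all_regions[: min(len(all_regions), 2000)], sizes, exclude, reps, seed=config.seed
            )
            shuffle_rows.append(
                [sp, f"{ctrl['real_fraction']:.4f}", f"{ctrl['random_fraction']:.4f}", f"{ctrl['p_value']:.6g}"]
            )
        artifacts.append(
            _write_tsv(
                out / "repeat_enrichment.tsv",
                ["species", "mode", "region_class", "group", "subgroup",
                 "count_A", "total_A", "count_B", "total_B",
                 "pct_A", "pct_B", "delta", "p_adj", "displayed"],
                enrichment_rows,
            )
        )
        artifacts.append(
            _write_tsv(
                out / "line_age_comparison.tsv",
                ["species", "category_a", "category_b", "median_a", "median_b", "p_one_sided"],
                age_rows,
            )
        )
        artifacts.append(
            _write_tsv(
                out / "shuffle_control.tsv",
                ["species", "real_fraction", "random_fraction", "p"],
                shuffle_rows,
            )
        )

    manifest = {
        "elapsed_s": round(time.time() - t0, 2),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "sim_config"
        },
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.1fs with %d artifacts", manifest["elapsed_s"], len(artifacts))
    return manifest
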