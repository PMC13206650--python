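"""End-to-end pipeline orchestration: simulate -> prepare -> analyses.

Every stage writes plain TSV/JSON outputs into a stage subdirectory so the
pipeline is resumable and each stage independently inspectable. All
randomness flows from the single simulation seed; two runs with identical
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplitude import amplitude_change, tissue_amplitudes
from .datasets import (
    StudyDataset,
    filter_detected,
    minmax_normalize,
    read_dataset,
    write_dataset,
)
from .errors import ConfigError
from .intra import compare_intra, correlation_matrix, summarize_matrix
from .inter import (
    condition_pair_summaries,
    network_edges,
    relative_change,
    tissue_sigma,
)
from .pathways import enrich_cluster
from .simulate import (
    SimulationConfig,
    designate_benchmarks,
    generate_dataset,
    simulate_annotation,
    write_ground_truth,
)
from .stats import one_sample_ttest
from .sync import (
    calibrate_threshold,
    global_set,
    overlap_sets,
    score_table,
    wave_clusters,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "prepare", "intra", "inter", "global", "pathways", "amplitude")

__all__ = ["RunParams", "run_pipeline", "ALL_STAGES"]


@dataclass(frozen=True)
class RunParams:
    """Analysis parameters with the study's operating defaults."""

    alpha: float = 0.05
    threshold_strategy: str = "largest_gap"
    manual_threshold: float | None = None
    cut_height: float = 1.0
    inter_mode: str = "all_pairs"
    k_terms: int = 5
    min_detect_value: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _float_json(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(type(obj))


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_float_json))


def _prepared(dataset: StudyDataset, params: RunParams) -> StudyDataset:
    return dataset.map_series(
        lambda ts: filter_detected(ts, min_value=params.min_detect_value)
    )


def run_pipeline(
    sim_config: SimulationConfig | None,
    params: RunParams = RunParams(),
    out_dir: str | Path = "circsync_run",
    stages=ALL_STAGES,
    input_dir: str | Path | None = None,
) -> dict:
    """Run the requested stages in order; returns the run manifest dict.

    Either ``sim_config`` (synthetic data) or ``input_dir`` (a directory
    written by the simulate stage / :func:`circsync.datasets.write_dataset`)
    must be provided.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    if sim_config is None and input_dir is None:
        raise ConfigError("either a simulation config or an input directory is required")

    manifest: dict = {
        "package_version": __version__,
        "params": params.to_dict(),
        "stages": list(stages),
        "stage_outputs": {},
    }

    truth = None
    if "simulate" in stages:
        if sim_config is None:
            raise ConfigError("simulate stage requested without a simulation config")
        dataset, truth = generate_dataset(sim_config)
        data_dir = out / "data"
        write_dataset(dataset, data_dir)
        write_ground_truth(truth, data_dir / "ground_truth.tsv")
        manifest["simulation"] = sim_config.to_dict()
        manifest["stage_outputs"]["simulate"] = {
            "n_series": len(dataset.series),
            "n_genes": sim_config.n_genes,
            "n_clipped": truth.n_clipped,
        }
    else:
        src = Path(input_dir) if input_dir is not None else out / "data"
        if not (src / "dataset.json").exists():
            raise ConfigError(
                f"no dataset found at {src}; run the 'simulate' stage (or point "
                "--input-dir at a dataset directory) first"
            )
        dataset = read_dataset(src)
        if sim_config is not None:
            _, truth = generate_dataset(sim_config)  # regenerate ground truth
            manifest["simulation"] = sim_config.to_dict()

    prepared = dataset
    if "prepare" in stages:
        prepared = _prepared(dataset, params)
        counts = {
            f"{c}/{t}": prepared.get(c, t).n_genes
            for c in prepared.conditions
            for t in prepared.tissues
        }
        manifest["stage_outputs"]["prepare"] = {
            "retained_genes_min": min(counts.values()),
            "retained_genes_max": max(counts.values()),
        }

    if "intra" in stages:
        manifest["stage_outputs"]["intra"] = _stage_intra(prepared, params, out / "intra")
    if "inter" in stages:
        manifest["stage_outputs"]["inter"] = _stage_inter(prepared, params, out / "inter")

    global_info = None
    if "global" in stages:
        if sim_config is None or truth is None:
            raise ConfigError(
                "the 'global' stage needs the simulation config to designate "
                "benchmark genes; supply one or run 'simulate' in the same call"
            )
        global_info = _stage_global(prepared, truth, sim_config, params, out / "global")
        manifest["stage_outputs"]["global"] = global_info["summary"]

    if "pathways" in stages:
        if global_info is None:
            raise ConfigError("the 'pathways' stage requires the 'global' stage")
        manifest["stage_outputs"]["pathways"] = _stage_pathways(
            global_info, sim_config, params, out / "pathways"
        )

    if "amplitude" in stages:
        if global_info is None:
            raise ConfigError("the 'amplitude' stage requires the 'global' stage")
        manifest["stage_outputs"]["amplitude"] = _stage_amplitude(
            dataset, global_info, out / "amplitude"
        )

    _write_json(out / "manifest.json", manifest)
    return manifest


def _stage_intra(dataset: StudyDataset, params: RunParams, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    matrices: dict[tuple[str, str], object] = {}
    for cond in dataset.conditions:
        for tissue, ts in sorted(dataset.condition_series(cond).items()):
            mat = correlation_matrix(minmax_normalize(ts))
            matrices[(cond, tissue)] = mat
            s = summarize_matrix(mat, alpha=params.alpha)
            rows.append(
                {
                    "condition": cond,
                    "tissue": tissue,
                    "mean_abs_r": s.mean_abs_r,
                    "n_significant": s.n_significant,
                    "n_pairs": s.n_pairs,
                    "alpha": s.alpha,
                }
            )
    pd.DataFrame(rows).to_csv(out / "summaries.tsv", sep="\t", index=False)

    comp_rows = []
    if len(dataset.conditions) == 2:
        cond_a, cond_b = dataset.conditions
        for tissue in dataset.tissues:
            if (cond_a, tissue) not in matrices or (cond_b, tissue) not in matrices:
                continue
            cmp = compare_intra(
                matrices[(cond_a, tissue)],
                matrices[(cond_b, tissue)],
                alpha=params.alpha,
            )
            comp_rows.append(
                {
                    "tissue": tissue,
                    "metric": cmp.metric,
                    f"value_{cond_a}": cmp.value_a,
                    f"value_{cond_b}": cmp.value_b,
                    "delta": cmp.delta,
                    "relative_change": cmp.relative_change,
                    "t": cmp.t,
                    "p": cmp.p,
                    "classification": cmp.classification,
                }
            )
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    return {"n_matrices": len(matrices), "n_comparisons": len(comp_rows)}


def _stage_inter(dataset: StudyDataset, params: RunParams, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    all_rows = []
    sigma_rows = []
    sigma_by_cond: dict[str, dict[str, float]] = {}
    for cond in dataset.conditions:
        normed = {
            t: minmax_normalize(ts)
            for t, ts in dataset.condition_series(cond).items()
        }
        summaries = condition_pair_summaries(
            normed, mode=params.inter_mode, alpha=params.alpha
        )
        for s in summaries:
            all_rows.append(
                {
                    "condition": cond,
                    "tissue_a": s.tissue_a,
                    "tissue_b": s.tissue_b,
                    "mean_abs_r": s.mean_abs_r,
                    "n_significant": s.n_significant,
                    "n_entries": s.n_entries,
                    "mode": s.mode,
                }
            )
        network_edges(summaries).to_csv(out / f"edges_{cond}.tsv", sep="\t", index=False)
        sigmas = tissue_sigma(summaries)
        sigma_by_cond[cond] = {s.tissue: s.sigma_abs_r for s in sigmas}
        for s in sigmas:
            sigma_rows.append(
                {"condition": cond, "tissue": s.tissue, "sigma_abs_r": s.sigma_abs_r}
            )
    pd.DataFrame(all_rows).to_csv(out / "pair_summaries.tsv", sep="\t", index=False)
    pd.DataFrame(sigma_rows).to_csv(out / "sigma.tsv", sep="\t", index=False)

    n_changes = 0
    if len(dataset.conditions) == 2:
        cond_a, cond_b = dataset.conditions
        change_rows = [
            {
                "tissue": t,
                f"sigma_{cond_a}": sigma_by_cond[cond_a][t],
                f"sigma_{cond_b}": sigma_by_cond[cond_b][t],
                "relative_change": relative_change(
                    sigma_by_cond[cond_a][t], sigma_by_cond[cond_b][t]
                ),
            }
            for t in sorted(sigma_by_cond[cond_a])
        ]
        pd.DataFrame(change_rows).to_csv(out / "relative_change.tsv", sep="\t", index=False)
        n_changes = len(change_rows)
    return {"n_pair_summaries": len(all_rows), "n_relative_changes": n_changes}


def _stage_global(
    dataset: StudyDataset,
    truth,
    sim_config: SimulationConfig,
    params: RunParams,
    out: Path,
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    benchmarks = designate_benchmarks(truth, sim_config)
    tables = {}
    sets = {}
    calibs = {}
    clusterings = {}
    for cond in dataset.conditions:
        table = score_table(dataset, cond)
        tables[cond] = table
        ranked = table.ranked()
        pd.DataFrame(
            [
                {"gene": g, "score": s, "n_pairs_used": table.n_pairs_used[g]}
                for g, s in ranked
            ]
        ).to_csv(out / f"scores_{cond}.tsv", sep="\t", index=False)
        bench_scores = {g: table.scores[g] for g in benchmarks if g in table.scores}
        if params.threshold_strategy == "manual":
            calib = calibrate_threshold(
                bench_scores, "manual", manual_value=params.manual_threshold
            )
        else:
            calib = calibrate_threshold(bench_scores, params.threshold_strategy)
        calibs[cond] = calib
        genes = global_set(table, calib.threshold)
        sets[cond] = genes
        pd.DataFrame(
            [{"gene": g, "score": table.scores[g]} for g in genes]
        ).to_csv(out / f"global_set_{cond}.tsv", sep="\t", index=False)
        if len(genes) >= 2:
            wc = wave_clusters(genes, dataset, cond, cut_height=params.cut_height)
            clusterings[cond] = wc
            pd.DataFrame(
                [{"gene": g, "cluster": wc.labels[g]} for g in genes if g in wc.labels]
            ).to_csv(out / f"clusters_{cond}.tsv", sep="\t", index=False)
            wave_rows = []
            for c in sorted(wc.whole_body):
                mean, sd = wc.whole_body[c]
                for t_i, t_h in enumerate(wc.timepoints_h):
                    wave_rows.append(
                        {
                            "cluster": c,
                            "timepoint_h": t_h,
                            "mean": mean[t_i],
                            "sd": sd[t_i],
                        }
                    )
            pd.DataFrame(wave_rows).to_csv(
                out / f"cluster_waveforms_{cond}.tsv", sep="\t", index=False
            )
    _write_json(
        out / "calibration.json",
        {
            cond: {
                "strategy": c.strategy,
                "threshold": c.threshold,
                "boundary_genes": list(c.boundary_genes) if c.boundary_genes else None,
                "benchmark_scores": list(c.benchmark_scores),
            }
            for cond, c in calibs.items()
        },
    )
    overlap = None
    if len(dataset.conditions) == 2:
        cond_a, cond_b = dataset.conditions
        ov = overlap_sets(sets[cond_a], sets[cond_b])
        overlap = {
            "n_shared": ov.n_shared,
            f"n_unique_{cond_a}": ov.n_unique_a,
            f"n_unique_{cond_b}": ov.n_unique_b,
        }
        _write_json(
            out / "overlap.json",
            {**overlap, "shared": list(ov.shared)},
        )
    summary = {
        "set_sizes": {c: len(g) for c, g in sets.items()},
        "thresholds": {c: calibs[c].threshold for c in calibs},
        "n_waves": {c: clusterings[c].n_clusters for c in clusterings},
        "overlap": overlap,
    }
    return {
        "summary": summary,
        "tables": tables,
        "sets": sets,
        "clusterings": clusterings,
    }


def _stage_pathways(global_info, sim_config, params: RunParams, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    all_genes = None
    # annotate the full simulated gene universe
    some_table = next(iter(global_info["tables"].values()))
    all_genes = sorted(some_table.scores)
    annotation = simulate_annotation(all_genes, seed=sim_config.seed)
    n_rows = 0
    for cond, wc in global_info["clusterings"].items():
        rows = []
        for c in range(1, wc.n_clusters + 1):
            members = [g for g, lab in wc.labels.items() if lab == c]
            enr = enrich_cluster(f"{cond}_C{c}", members, annotation, k=params.k_terms)
            for rank, term in enumerate(enr.top_by_frequency, start=1):
                rows.append(
                    {
                        "cluster": c,
                        "ranking": "frequency",
                        "rank": rank,
                        "term": term,
                    }
                )
            for rank, term in enumerate(enr.top_by_ratio, start=1):
                rows.append(
                    {"cluster": c, "ranking": "ratio", "rank": rank, "term": term}
                )
            enr.table.assign(cluster=c).to_csv(
                out / f"enrichment_{cond}_C{c}.tsv", sep="\t", index=False
            )
        pd.DataFrame(rows).to_csv(out / f"top_terms_{cond}.tsv", sep="\t", index=False)
        n_rows += len(rows)
    return {"n_top_term_rows": n_rows}


def _stage_amplitude(dataset: StudyDataset, global_info, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    conds = dataset.conditions
    # focus gene: top-scoring gene of the last condition's global set
    focus_cond = conds[-1]
    focus_set = global_info["sets"].get(focus_cond) or []
    if not focus_set:
        table = global_info["tables"][focus_cond]
        focus_set = [table.ranked()[0][0]]
    gene = focus_set[0]
    rows = []
    recs = {}
    for cond in conds:
        for rec in tissue_amplitudes(gene, dataset, cond):
            recs[(cond, rec.tissue)] = rec
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "tissue": rec.tissue,
                    "amplitude": rec.amplitude,
                    "peak_time_h": rec.peak_time_h,
                    "trough_time_h": rec.trough_time_h,
                }
            )
    pd.DataFrame(rows).to_csv(out / "amplitudes.tsv", sep="\t", index=False)
    comparison: dict = {"gene": gene}
    if len(conds) == 2:
        cond_a, cond_b = conds
        log2_ratios = []
        for tissue in dataset.tissues:
            a = recs.get((cond_a, tissue))
            b = recs.get((cond_b, tissue))
            if a is None or b is None or a.amplitude == 0 or b.amplitude == 0:
                continue
            log2_ratios.append(amplitude_change(a, b, mode="log2_ratio"))
        if len(log2_ratios) >= 2 and np.ptp(log2_ratios) > 0:
            t, p = one_sample_ttest(log2_ratios, 0.0)
            comparison.update(
                {
                    "n_tissues": len(log2_ratios),
                    "mean_log2_ratio": float(np.mean(log2_ratios)),
                    "t": t,
                    "p": p,
                }
            )
    _write_json(out / "comparison.json", comparison)
    return {"focus_gene": gene, "n_amplitude_rows": len(rows)}
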