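"""End-to-end orchestration: filter -> classify -> alpha -> beta ->
metaphylogeography, with every intermediate written to disk and a run
manifest recording seeds, thresholds and versions.

Each stage is usable standalone on saved intermediates (the CLI maps
subcommands onto these functions), and all randomness flows from one
master seed: per-stage seeds are derived deterministically from it, so
re-running with an identical manifest reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha_diversity import alpha_table, compare_alpha, composition_summary
from .beta_diversity import (
    bray_curtis,
    compare_mean_dissimilarity,
    membership_patterns,
    membership_summary,
    nmds,
    permanova,
    permdisp,
    presence_by_locality,
    sorensen_between_localities,
    temporal_turnover,
)
from .filtering import FilterConfig, run_cascade
from .metaphylogeography import (
    esv_richness,
    mean_d_between_localities,
    motu_genetic_summaries,
    randomization_balance_test,
    rarefy_motu_reads,
    reads_esvs_regression,
)
from .nis_classification import NISThresholds, assign_nis, curate_nat
from .synthetic_data import SimConfig, SimBundle, simulate
from .tables_io import (
    ESVTable,
    MOTUTable,
    SampleFrame,
    comm_ids,
    partition_datasets,
    read_esv_table,
    read_hit_table,
    read_motu_table,
    read_sample_frame,
    validate_linkage,
    write_esv_table,
    write_motu_table,
    write_sample_frame,
    write_hit_table,
)

log = logging.getLogger("metaport")

STAGES = ("simulate", "filter", "classify", "alpha", "beta", "metaphylo")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_json(data: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# bundle I/O


def save_bundle(bundle: SimBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_frame(bundle.samples, outdir / "samples.tsv")
    write_esv_table(bundle.esvs, outdir / "esv_table.tsv", outdir / "esv_sequences.fasta")
    write_motu_table(bundle.motus, outdir / "motu_table.tsv")
    if bundle.hits is not None:
        write_hit_table(bundle.hits, outdir / "nis_hits.tsv")
    if bundle.truth:
        truth = dict(bundle.truth)
        cfg = truth.pop("config", None)
        if cfg is not None:
            truth["config"] = dataclasses.asdict(cfg)
        write_json(truth, outdir / "ground_truth.json")


def load_bundle(indir: Path, with_hits: bool = True) -> SimBundle:
    samples = read_sample_frame(indir / "samples.tsv")
    fasta = indir / "esv_sequences.fasta"
    esvs = read_esv_table(
        indir / "esv_table.tsv", samples, fasta if fasta.exists() else None
    )
    motus = read_motu_table(indir / "motu_table.tsv", samples)
    hits = None
    if with_hits and (indir / "nis_hits.tsv").exists():
        hits = read_hit_table(indir / "nis_hits.tsv")
    return SimBundle(esvs, motus, samples, hits, {})


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, outdir: Path, seed: int) -> SimBundle:
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs["seed"] = stage_seed(seed, "simulate")
    bundle = simulate(SimConfig(**sim_kwargs))
    save_bundle(bundle, outdir / "simulated")
    log.info(
        "simulated %d ESVs / %d MOTUs / %d samples",
        len(bundle.esvs.esv_ids),
        len(bundle.motus.motu_ids),
        len(bundle.samples.sample_ids),
    )
    return bundle


def stage_filter(bundle: SimBundle, config: dict, outdir: Path) -> SimBundle:
    fcfg = FilterConfig(**config.get("filter", {}))
    result = run_cascade(bundle.esvs, bundle.motus, bundle.samples, fcfg)
    report = validate_linkage(result.esvs, result.motus)
    if not report.ok:
        raise RuntimeError("filter stage broke ESV/MOTU linkage")
    d = outdir / "filtered"
    d.mkdir(parents=True, exist_ok=True)
    result.log.to_csv(d / "removal_log.tsv", sep="\t", index=False)
    result.stage_counts.to_csv(d / "stage_counts.tsv", sep="\t", index=False)
    filtered = SimBundle(
        result.esvs, result.motus, result.samples, bundle.hits, bundle.truth
    )
    save_bundle(
        SimBundle(result.esvs, result.motus, result.samples, bundle.hits, {}),
        d,
    )
    return filtered


def stage_classify(bundle: SimBundle, config: dict, outdir: Path) -> SimBundle:
    if bundle.hits is None or bundle.hits.data.empty:
        log.warning(
            "no NIS hit table: classification skipped, NIS analyses disabled"
        )
        return bundle
    ncfg = NISThresholds(**config.get("nis", {}))
    nis_ids, nis_species = assign_nis(bundle.hits, ncfg)
    nis_ids &= set(bundle.motus.motu_ids)
    exclusion = set(config.get("nat_exclusion", []) or [])
    labeled = partition_datasets(bundle.motus, nis_ids, set())
    nat_ids = curate_nat(labeled, exclusion, nis_ids)
    labeled = partition_datasets(bundle.motus, nis_ids, nat_ids)
    nominal = labeled.nominal_species.copy()
    for m in nis_ids:
        nominal[m] = nis_species[m]
    labeled = MOTUTable(labeled.reads, labeled.taxonomy, nominal, labeled.dataset_labels)
    d = outdir / "classified"
    d.mkdir(parents=True, exist_ok=True)
    write_motu_table(labeled, d / "motu_table.tsv")
    write_json(
        {
            "n_nis": len(nis_ids),
            "n_nat": len(nat_ids),
            "n_comm_other": len(labeled.ids_with_label("COMM_other")),
        },
        d / "dataset_sizes.json",
    )
    return SimBundle(bundle.esvs, labeled, bundle.samples, bundle.hits, bundle.truth)


def _scope_ids(motus: MOTUTable, dataset: str) -> list[str]:
    if dataset == "COMM":
        return comm_ids(motus)
    return motus.ids_with_label(dataset)


def stage_alpha(bundle: SimBundle, config: dict, outdir: Path, seed: int) -> dict:
    acfg = config.get("alpha", {})
    d = outdir / "alpha"
    d.mkdir(parents=True, exist_ok=True)
    results = {}
    s = stage_seed(seed, "alpha")
    for dataset in acfg.get("datasets", ["COMM", "NIS"]):
        ids = _scope_ids(bundle.motus, dataset)
        if not ids:
            continue
        res = alpha_table(
            bundle.motus,
            bundle.samples,
            ids,
            dataset,
            seed=s,
            n_draws=int(acfg.get("n_shannon_draws", 1)),
        )
        res.table.to_csv(d / f"alpha_{dataset}.tsv", sep="\t", index=False)
        tests = {}
        if res.table["locality"].nunique() >= 2:
            for metric in ("shannon", "richness"):
                cmp = compare_alpha(res.table, metric)
                tests[metric] = {
                    "test": cmp.test,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                }
                cmp.pairwise.to_csv(
                    d / f"pairwise_{metric}_{dataset}.tsv", sep="\t", index=False
                )
        comp = composition_summary(bundle.motus, bundle.samples, ids)
        comp.to_csv(d / f"composition_{dataset}.tsv", sep="\t")
        results[dataset] = {
            "mean_shannon": float(res.table["shannon"].mean()),
            "mean_richness": float(res.table["richness"].mean()),
            "depth_used": int(res.table["depth_used"].iloc[0]) if len(res.table) else None,
            "tests": tests,
        }
    write_json(results, d / "alpha_summary.json")
    return results


def stage_beta(bundle: SimBundle, config: dict, outdir: Path, seed: int) -> dict:
    bcfg = config.get("beta", {})
    n_perm = int(bcfg.get("n_permutations", 999))
    d = outdir / "beta"
    d.mkdir(parents=True, exist_ok=True)
    s = stage_seed(seed, "beta")
    results: dict = {}
    matrices = {}
    for dataset in bcfg.get("datasets", ["COMM", "NIS"]):
        ids = _scope_ids(bundle.motus, dataset)
        reads = bundle.motus.reads.loc[ids].T  # sample x MOTU
        reads = reads.loc[reads.sum(axis=1) > 0]
        dm = bray_curtis(reads)
        matrices[dataset] = dm
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            d / f"bray_curtis_{dataset}.tsv", sep="\t"
        )
        presence = presence_by_locality(bundle.motus.reads.loc[ids], bundle.samples)
        sor_table, sor_mean = sorensen_between_localities(presence)
        sor_table.to_csv(d / f"sorensen_{dataset}.tsv", sep="\t", index=False)
        patterns = membership_patterns(presence)
        patterns.to_csv(d / f"membership_{dataset}.tsv", sep="\t", index=False)
        ord_res = nmds(dm, seed=s)
        ord_res.coordinates.to_csv(d / f"nmds_{dataset}.tsv", sep="\t")
        meta = bundle.samples.data.loc[list(dm.ids)]
        tests = {}
        for factor, series in (
            ("site", meta["locality"]),
            ("month", meta["time_point"]),
        ):
            if series.nunique() < 2 or (series.value_counts() < 2).any():
                continue
            pa = permanova(dm, series, n_perm=n_perm, seed=s)
            pdisp = permdisp(dm, series, n_perm=n_perm, seed=s)
            tests[factor] = {
                "permanova_F": pa.statistic,
                "permanova_p": pa.p_value,
                "permdisp_F": pdisp.statistic,
                "permdisp_p": pdisp.p_value,
            }
        turnover = temporal_turnover(dm, bundle.samples)
        turnover.to_csv(d / f"turnover_{dataset}.tsv", sep="\t", index=False)
        results[dataset] = {
            "mean_bray_curtis": float(
                dm.condensed_form().mean()
            ),
            "sorensen_mean": sor_mean,
            "membership": membership_summary(
                patterns, len(bundle.samples.localities)
            ),
            "nmds_stress": ord_res.stress,
            "tests": tests,
        }
    if len(matrices) == 2:
        keys = list(matrices)
        shared = [
            i for i in matrices[keys[0]].ids if i in set(matrices[keys[1]].ids)
        ]
        cmp = compare_mean_dissimilarity(
            matrices[keys[0]].filter(shared), matrices[keys[1]].filter(shared)
        )
        results["mean_bc_comparison"] = {
            f"mean_{keys[0]}": cmp.mean_1,
            f"mean_{keys[1]}": cmp.mean_2,
            "t": cmp.t_statistic,
            "p": cmp.p_value,
        }
    write_json(results, d / "beta_summary.json")
    return results


def stage_metaphylo(
    bundle: SimBundle, config: dict, outdir: Path, seed: int
) -> dict:
    mcfg = config.get("metaphylo", {})
    d = outdir / "metaphylo"
    d.mkdir(parents=True, exist_ok=True)
    s = stage_seed(seed, "metaphylo")
    datasets = tuple(mcfg.get("datasets", ("NIS", "NAT")))
    if not all(bundle.motus.ids_with_label(ds) for ds in datasets):
        log.warning("metaphylogeography skipped: a dataset is empty")
        return {}
    summaries, reports = esv_richness(
        bundle.esvs, bundle.motus, bundle.samples, "none", datasets
    )
    summaries.to_csv(d / "motu_summaries.tsv", sep="\t", index=False)
    results: dict = {
        "richness_tests": [dataclasses.asdict(r) for r in reports],
    }
    enough = all(
        (summaries["dataset"] == ds).sum() >= 3 for ds in datasets
    )
    if enough:
        reg = reads_esvs_regression(summaries)
        results["regression"] = {
            "slopes": reg.slopes,
            "pearson_r": reg.pearson_r,
            "interaction_p": reg.interaction_p,
        }
    else:
        log.warning("too few MOTUs for the reads-richness regression")
    thresholds = mcfg.get("rarefaction_thresholds", ["mean", "median"])
    results["rarefaction"] = {}
    for t in thresholds:
        rarefied, report = rarefy_motu_reads(
            bundle.esvs, summaries, threshold=t, seed=s
        )
        r_summ, r_reports = esv_richness(
            rarefied, bundle.motus, bundle.samples, "none", datasets
        )
        results["rarefaction"][str(t)] = {
            "threshold_reads": report["threshold"],
            "eliminated_pct": report["eliminated_pct"],
            "mann_whitney_p": r_reports[0].p_value if r_reports else None,
        }
    n_small = min(
        (summaries["dataset"] == datasets[0]).sum(),
        (summaries["dataset"] == datasets[1]).sum(),
    )
    rand = randomization_balance_test(
        summaries, int(n_small), datasets=datasets, seed=s
    )
    results["randomization"] = {
        "target_size": int(n_small),
        "fraction_significant": rand["fraction_significant"],
    }
    drep = mean_d_between_localities(
        bundle.esvs, bundle.samples, bundle.motus, datasets
    )
    drep.pair_means.to_csv(d / "jost_d_pairs.tsv", sep="\t", index=False)
    results["jost_d"] = {
        "mean_d": {
            ds: float(drep.pair_means[f"mean_d_{ds}"].mean()) for ds in datasets
        },
        "paired_t": drep.t_statistic,
        "paired_p": drep.p_value,
        "pattern_r": drep.pearson_r,
        "pattern_r_p": drep.pearson_p,
    }
    write_json(results, d / "metaphylo_summary.json")
    return results


# ---------------------------------------------------------------------------
# full run


def run(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int = 0,
    bundle: SimBundle | None = None,
) -> dict:
    """Execute the full pipeline and return the combined summary.

    ``config`` may be a dict or a YAML path.  If no ``bundle`` is given
    and the config has input paths they are loaded; otherwise a
    synthetic dataset is generated.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        inputs = config.get("inputs")
        if inputs:
            bundle = load_bundle(Path(inputs))
        else:
            bundle = stage_simulate(config, outdir, seed)
    summary: dict = {"seed": seed, "version": __version__}
    try:
        filtered = stage_filter(bundle, config, outdir)
        classified = stage_classify(filtered, config, outdir)
        summary["alpha"] = stage_alpha(classified, config, outdir, seed)
        summary["beta"] = stage_beta(classified, config, outdir, seed)
        summary["metaphylo"] = stage_metaphylo(classified, config, outdir, seed)
    except Exception as exc:  # abort with stage context
        raise RuntimeError(f"pipeline aborted: {exc}") from exc
    manifest = {
        "seed": seed,
        "stage_seeds": {st: stage_seed(seed, st) for st in STAGES},
        "version": __version__,
        "config": _jsonable(config),
    }
    write_json(manifest, outdir / "manifest.json")
    write_json(summary, outdir / "summary.json")
    return summary
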