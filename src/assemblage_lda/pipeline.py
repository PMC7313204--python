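"""End-to-end orchestration: simulate -> preprocess -> fit -> enterotype ->
stats -> associate -> functional, driven by one YAML config, with a manifest
recording seeds, per-trial scores, and output-file digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import pearson_assemblage_function
from .datatypes import CountTable
from .enterotype import name_clusters_by_dominant_feature, pairwise_jsd, pam_cluster
from .functional import category_abundance, fit_functional_lda, match_assemblages, read_ko_category_map
from .lda import LDAFit, fit_lda
from .preprocess import (
    drop_empty_features,
    normalize_to_constant,
    read_count_table,
    to_relative_abundance,
    write_count_table,
)
from .stats import average_by_group, compute_assemblage_stats, entropy_histogram
from .synthetic import (
    GenerativeConfig,
    make_enterotype_design,
    sample_functional_profiles,
    sample_lda_corpus,
    write_dataset,
)

DEFAULT_CONFIG = {
    "out_dir": "run",
    "seed": 0,
    "input_counts": None,          # path to counts.tsv; if absent, simulate
    "input_labels": None,          # optional sample -> group TSV
    "ko_counts": None,             # optional KO count table path
    "ko_category_map": None,       # optional KO -> category TSV
    "simulate": {
        "design": "enterotype",
        "n_samples": 300,
        "n_features": 50,
        "k": 4,
        "reads": 5000,
    },
    "normalize_constant": 10_000,
    "k_list": [2, 3, 4, 5],
    "report_k": 4,
    "lda_trials": 10,
    "lda_tol": 1e-6,
    "lda_tol_mode": "abs",
    "lda_init_alpha": 0.1,
    "lda_init_beta": 0.05,
    "lda_max_iter": 1000,
    "pam_k": 3,
    "pam_trials": 10,
    "function_ids": None,          # defaults to butyrate KOs when simulating
    "association_alpha": 0.01,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix(path: Path, matrix: np.ndarray, index: list[str], columns: list[str], index_name: str) -> None:
    df = pd.DataFrame(matrix, index=index, columns=columns)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_fit(fit: LDAFit, out: Path, prefix: str = "") -> list[Path]:
    names = [f"assemblage_{k + 1}" for k in range(fit.K)]
    paths = [out / f"{prefix}theta.tsv", out / f"{prefix}phi.tsv", out / f"{prefix}fit.json"]
    _write_matrix(paths[0], fit.theta, fit.sample_ids, names, "sample_id")
    _write_matrix(paths[1], fit.phi, names, fit.feature_ids, "assemblage")
    with open(paths[2], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "K": fit.K,
                "best_trial_seed": fit.best_trial_seed,
                "final_vlb": fit.final_vlb,
                "n_iterations": fit.n_iterations,
                "trial_vlbs": {str(s): v for s, v in fit.trial_vlbs.items()},
                "alpha": fit.hyperparams.alpha.tolist(),
                "beta": fit.hyperparams.beta,
            },
            fh,
            indent=1,
        )
    return paths


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every stage under one output directory; returns the manifest.

    All randomness derives from ``seed``; rerunning an identical config
    reproduces byte-identical numeric outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **config}
    if "simulate" in config:
        cfg["simulate"] = {**DEFAULT_CONFIG["simulate"], **(config["simulate"] or {})}
    if cfg["input_counts"] is None and cfg["simulate"] is None:
        raise PipelineError("config", "either input_counts or a simulate block is required")
    if cfg["input_counts"] is not None and not Path(cfg["input_counts"]).exists():
        raise PipelineError("config", f"input_counts not found: {cfg['input_counts']}")

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "config": {k: v for k, v in cfg.items()},
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stage_seeds": {},
        "outputs": {},
    }
    written: list[Path] = []

    def record(stage: str, paths: list[Path]) -> None:
        written.extend(paths)
        manifest["outputs"].update({str(p): _digest(p) for p in paths})
        manifest.setdefault("stages", []).append(stage)

    # --- simulate or load -------------------------------------------------
    labels = None
    ko_table = None
    function_ids = cfg["function_ids"]
    if cfg["input_counts"] is not None:
        table = read_count_table(cfg["input_counts"])
        if cfg["input_labels"]:
            lab = pd.read_csv(cfg["input_labels"], sep="\t", index_col=0)
            labels = lab.iloc[:, 0].reindex(table.sample_ids).to_numpy()
        if cfg["ko_counts"]:
            ko_table = read_count_table(cfg["ko_counts"])
    else:
        sim = cfg["simulate"]
        manifest["stage_seeds"]["simulate"] = seed
        try:
            if sim["design"] == "enterotype":
                design = make_enterotype_design(
                    n_features=int(sim["n_features"]),
                    n_samples=int(sim["n_samples"]),
                    reads_per_sample=int(sim["reads"]),
                    seed=seed,
                )
            else:
                k = int(sim["k"])
                rng = np.random.default_rng(seed)
                phi = rng.dirichlet(np.full(int(sim["n_features"]), 0.5), size=k)
                design = GenerativeConfig(
                    n_samples=int(sim["n_samples"]),
                    n_features=int(sim["n_features"]),
                    n_assemblages=k,
                    reads_per_sample=int(sim["reads"]),
                    alpha_true=np.full(k, 1.0),
                    phi_true=phi,
                    seed=seed,
                )
            dataset = sample_lda_corpus(design)
            dataset = sample_functional_profiles(dataset, seed=seed + 1) if sim["design"] == "enterotype" else dataset
            write_dataset(dataset, out / "simulated")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", str(exc)) from exc
        record("simulate", sorted((out / "simulated").glob("*")))
        table = dataset.counts
        labels = dataset.group_labels
        ko_table = dataset.function_counts
        if function_ids is None and dataset.butyrate_ko_ids:
            function_ids = dataset.butyrate_ko_ids

    # --- preprocess -------------------------------------------------------
    try:
        norm = drop_empty_features(normalize_to_constant(table, int(cfg["normalize_constant"])))
        write_count_table(norm, out / "normalized.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", str(exc)) from exc
    record("preprocess", [out / "normalized.tsv"])

    # --- fit LDA per K ----------------------------------------------------
    fits: dict[int, LDAFit] = {}
    manifest["trial_vlbs"] = {}
    for K in cfg["k_list"]:
        manifest["stage_seeds"][f"fit_lda_k{K}"] = seed
        try:
            fit = fit_lda(
                norm,
                int(K),
                init_alpha=float(cfg["lda_init_alpha"]),
                init_beta=float(cfg["lda_init_beta"]),
                tol=float(cfg["lda_tol"]),
                n_trials=int(cfg["lda_trials"]),
                base_seed=seed,
                max_iter=int(cfg["lda_max_iter"]),
                tol_mode=cfg["lda_tol_mode"],
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"fit-lda K={K}", str(exc)) from exc
        fits[int(K)] = fit
        manifest["trial_vlbs"][str(K)] = {str(s): v for s, v in fit.trial_vlbs.items()}
        kdir = out / f"lda_k{K}"
        kdir.mkdir(exist_ok=True)
        record(f"fit-lda K={K}", write_fit(fit, kdir))

    report_k = int(cfg["report_k"])
    fit = fits.get(report_k, fits[max(fits)])

    # --- enterotype -------------------------------------------------------
    try:
        profiles = to_relative_abundance(norm)
        dissim = pairwise_jsd(profiles)
        clustering = pam_cluster(dissim, int(cfg["pam_k"]), int(cfg["pam_trials"]), seed)
        cluster_names = name_clusters_by_dominant_feature(clustering, profiles)
        lab_df = pd.DataFrame(
            {
                "sample_id": norm.sample_ids,
                "cluster": clustering.labels + 1,
                "cluster_name": [cluster_names[c] for c in clustering.labels],
            }
        )
        lab_df.to_csv(out / "enterotype_labels.tsv", sep="\t", index=False)
        with open(out / "clustering.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "medoid_indices": clustering.medoid_indices.tolist(),
                    "silhouette": clustering.silhouette,
                    "seed": clustering.seed,
                    "cluster_names": cluster_names,
                },
                fh,
                indent=1,
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enterotype", str(exc)) from exc
    manifest["stage_seeds"]["enterotype"] = seed
    manifest["silhouette"] = clustering.silhouette
    record("enterotype", [out / "enterotype_labels.tsv", out / "clustering.json"])

    # --- assemblage statistics ---------------------------------------------
    try:
        st = compute_assemblage_stats(fit.theta, fit.phi)
        names = [f"assemblage_{k + 1}" for k in range(fit.K)]
        _write_matrix(out / "posterior_k_given_j.tsv", st.p_k_given_j, fit.feature_ids, names, "feature_id")
        pd.DataFrame({"sample_id": fit.sample_ids, "entropy": st.sample_entropies}).to_csv(
            out / "entropy_samples.tsv", sep="\t", index=False
        )
        pd.DataFrame({"feature_id": fit.feature_ids, "entropy": st.feature_entropies}).to_csv(
            out / "entropy_features.tsv", sep="\t", index=False
        )
        stats_paths = [out / "posterior_k_given_j.tsv", out / "entropy_samples.tsv", out / "entropy_features.tsv"]
        group_source = labels if labels is not None else (clustering.labels + 1).astype(str)
        grouped = average_by_group(fit.theta, np.asarray(group_source))
        _write_matrix(out / "group_means.tsv", grouped.mean, grouped.group_ids, names, "group")
        _write_matrix(out / "group_sds.tsv", grouped.sd, grouped.group_ids, names, "group")
        stats_paths += [out / "group_means.tsv", out / "group_sds.tsv"]
        edges, counts_hist, median = entropy_histogram(st.sample_entropies, 16, fit.K)
        with open(out / "entropy_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"median_sample_entropy": median, "bin_edges": edges.tolist(), "counts": counts_hist.tolist()},
                fh,
            )
        stats_paths.append(out / "entropy_summary.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", str(exc)) from exc
    record("stats", stats_paths)

    # --- association + functional (only with KO data) -----------------------
    if ko_table is not None:
        try:
            ko_norm = drop_empty_features(normalize_to_constant(ko_table, int(cfg["normalize_constant"])))
            ko_profiles = to_relative_abundance(ko_norm)
            fids = function_ids or ko_norm.feature_ids[:3]
            assoc = pearson_assemblage_function(
                fit.theta, ko_profiles, list(fids), alpha=float(cfg["association_alpha"])
            )
            assoc.table.to_csv(out / "associations.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("associate", str(exc)) from exc
        manifest["stage_seeds"]["associate"] = seed
        record("associate", [out / "associations.tsv"])

        try:
            func_fit = fit_functional_lda(
                ko_norm,
                fit.K,
                n_trials=int(cfg["lda_trials"]),
                base_seed=seed,
                tol=float(cfg["lda_tol"]),
                max_iter=int(cfg["lda_max_iter"]),
            )
            fdir = out / "functional"
            fdir.mkdir(exist_ok=True)
            func_paths = write_fit(func_fit, fdir, prefix="func_")
            matching = match_assemblages(fit.theta, func_fit.theta)
            with open(fdir / "matching.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "mapping": {str(a): b for a, b in matching.mapping.items()},
                        "score_matrix": matching.score_matrix.tolist(),
                        "total_score": matching.total_score,
                    },
                    fh,
                    indent=1,
                )
            func_paths.append(fdir / "matching.json")
            if cfg["ko_category_map"]:
                ko_map = read_ko_category_map(cfg["ko_category_map"])
                cat = category_abundance(func_fit.phi, func_fit.feature_ids, ko_map)
                _write_matrix(
                    fdir / "category_abundance.tsv",
                    cat.abundance,
                    [f"functional_assemblage_{k + 1}" for k in range(func_fit.K)],
                    cat.categories,
                    "assemblage",
                )
                func_paths.append(fdir / "category_abundance.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("functional", str(exc)) from exc
        manifest["stage_seeds"]["functional"] = seed
        record("functional", func_paths)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
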