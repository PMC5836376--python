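"""End-to-end orchestration: simulate/load -> preprocess -> differential ->
features -> nested sets -> QC, with TSV stage outputs, a JSON report and a
run manifest.

Stage outputs are pure functions of (inputs, config); rerunning with the
same config and seed reproduces the report bundle byte-for-byte. Wall-clock
stage timings and input digests go to ``manifest.json``, which is the only
non-deterministic file in an output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import ModeratedTTest
from .errors import ConfigError, LigandqError, ValidationError
from .features import (
    assign_alleles,
    compare_hydrophobicity,
    length_distribution,
    peptides_by_allele,
)
from .io import (
    read_design,
    read_fasta,
    read_peptide_table,
    read_predictions,
    map_to_protein,
    write_peptide_table,
)
from .nested import (
    compute_deltas,
    context_frequency_matrix,
    detect_nested_pairs,
    group_and_test,
    group_means,
    pairs_to_frame,
)
from .preprocess import ImputationParams, impute_missing, log2_transform, width_normalize
from .qc import pairwise_pearson, replicate_overlap, summed_intensities
from .simulate import (
    AlleleModel,
    Effects,
    Missingness,
    Noise,
    SimConfig,
    emit_dataset,
    simulate_dataset,
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"enabled": False},
    "input": {"peptides": None, "proteome": None, "design": None, "predictions": None},
    "preprocess": {"normalize": True, "width_fraction": 0.2, "downshift": 1.8},
    "differential": {"s0": 1.0, "fdr": 0.01, "n_perm": 250, "groups": None},
    "nested": {"max_ext": 5, "delta_mode": "log2fc_diff"},
    "features": {"enrichment_length": 9, "cutoff": 0.01, "rank_threshold": 2.0},
}

_SIM_KEYS = {
    "n_proteins", "protein_length", "n_peptides", "nested_fraction", "max_ext",
    "n_replicates", "seed",
}


def load_config(source: str | Path | Mapping | None) -> dict:
    """Merge a YAML file (or mapping) over the defaults; reject unknown keys."""
    if source is None:
        user: dict = {}
    elif isinstance(source, Mapping):
        user = dict(source)
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(cfg[key], dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg["simulate"])
    sim.pop("enabled", None)
    effects = Effects(**sim.pop("effects", {}))
    noise = Noise(**sim.pop("noise", {}))
    if "missingness" in sim:
        mval = sim.pop("missingness")
        missingness = None if mval is None else Missingness(**mval)
    else:
        missingness = Missingness()
    unknown = set(sim) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
    sim.setdefault("seed", cfg["seed"])
    return SimConfig(effects=effects, noise=noise, missingness=missingness, **sim)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(
    config: str | Path | Mapping | None, outdir: str | Path
) -> dict:
    """Run all stages; returns the report dict (also written as report.json)."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    digests: dict[str, str] = {}
    report: dict[str, Any] = {"version": __version__, "config": cfg}

    # --- stage: data -------------------------------------------------------
    t0 = time.perf_counter()
    if cfg["simulate"].get("enabled"):
        dataset = simulate_dataset(_sim_config(cfg))
        emit_dataset(dataset, outdir / "simulated")
        table, design, proteome = dataset.table, dataset.design, dataset.ligandome.proteome
        load_report = {"read": len(table), "filtered": 0, "kept": len(table)}
        predictions = None
    else:
        paths = cfg["input"]
        for key in ("peptides", "design"):
            if not paths.get(key):
                raise ConfigError(f"input.{key} is required when simulate is off")
            if not Path(paths[key]).exists():
                raise ConfigError(f"input.{key}: no such file {paths[key]!r}")
        table, rep = read_peptide_table(paths["peptides"])
        load_report = {"read": rep.read, "filtered": rep.filtered, "kept": rep.kept}
        design = read_design(paths["design"])
        design.validate_against(table)
        proteome = None
        if paths.get("proteome"):
            proteome = read_fasta(paths["proteome"])
            table = map_to_protein(table, proteome)
        predictions = read_predictions(paths["predictions"]) if paths.get("predictions") else None
        for key, p in paths.items():
            if p:
                digests[key] = _digest(Path(p))
    report["load"] = load_report
    report["n_samples"] = len(table.samples)
    timings["data"] = time.perf_counter() - t0

    # --- stage: preprocess -------------------------------------------------
    t0 = time.perf_counter()
    pp = cfg["preprocess"]
    matrix = log2_transform(table, design)
    if pp["normalize"]:
        matrix = width_normalize(matrix)
    imputed = impute_missing(
        matrix,
        ImputationParams(
            width_fraction=pp["width_fraction"],
            downshift=pp["downshift"],
            seed=cfg["seed"],
        ),
    )
    imputed.values.rename_axis("sequence").to_csv(
        outdir / "intensity_matrix.tsv", sep="\t", float_format="%.10g"
    )
    imputed.imputed.rename_axis("sequence").to_csv(outdir / "imputed_mask.tsv", sep="\t")
    report["preprocess"] = {
        "normalized": bool(pp["normalize"]),
        "n_missing": int(matrix.missing.sum().sum()),
        "n_imputed": int(imputed.imputed.sum().sum()),
    }
    timings["preprocess"] = time.perf_counter() - t0

    # --- stage: qc ---------------------------------------------------------
    t0 = time.perf_counter()
    corr = pairwise_pearson(matrix, mode="observed")
    corr.to_csv(outdir / "qc_correlations.tsv", sep="\t", float_format="%.6f")
    overlap = replicate_overlap(table, design)
    pd.DataFrame(overlap).rename_axis("n_replicates").to_csv(
        outdir / "qc_overlap.tsv", sep="\t", float_format="%.6f"
    )
    off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
    report["qc"] = {
        "pearson_min": float(np.nanmin(off_diag)),
        "pearson_mean": float(np.nanmean(off_diag)),
        "summed_intensity": {k: float(v) for k, v in summed_intensities(table).items()},
    }
    timings["qc"] = time.perf_counter() - t0

    # --- stage: differential -----------------------------------------------
    t0 = time.perf_counter()
    diff_cfg = cfg["differential"]
    model = ModeratedTTest(
        imputed,
        design,
        groups=diff_cfg["groups"],
        s0=diff_cfg["s0"],
        fdr=diff_cfg["fdr"],
        n_perm=diff_cfg["n_perm"],
        seed=cfg["seed"],
    )
    results = model.fit()
    results.to_tsv(outdir / "differential.tsv")
    report["differential"] = {
        "groups": list(results.groups),
        "n_peptides": len(results.frame),
        **{f"n_{k}": v for k, v in results.counts.items()},
    }
    timings["differential"] = time.perf_counter() - t0

    # --- stage: features ---------------------------------------------------
    t0 = time.perf_counter()
    detected = table.intensities().notna()
    gmap = design.groups
    (g1, g2) = results.groups
    in_g1 = detected[gmap[g1]].any(axis=1)
    in_g2 = detected[gmap[g2]].any(axis=1)
    unique_sets = {
        g1: list(detected.index[in_g1 & ~in_g2]),
        g2: list(detected.index[in_g2 & ~in_g1]),
    }
    lengths = length_distribution({k: v for k, v in unique_sets.items() if v})
    lengths.to_csv(outdir / "length_distribution.tsv", sep="\t", index=False,
                   float_format="%.6f")
    features_report: dict[str, Any] = {
        "n_unique": {k: len(v) for k, v in unique_sets.items()},
    }
    if all(len(v) >= 2 for v in unique_sets.values()):
        features_report["hydrophobicity"] = compare_hydrophobicity(
            unique_sets[g1], unique_sets[g2]
        )
    if predictions is not None:
        assignment = assign_alleles(table, predictions, cfg["features"]["rank_threshold"])
        assignment.to_csv(outdir / "allele_assignment.tsv", sep="\t", index=False,
                          float_format="%.6g")
        features_report["allele_status"] = {
            k: int(v) for k, v in assignment["status"].value_counts().items()
        }
        features_report["peptides_per_allele"] = {
            k: len(v) for k, v in peptides_by_allele(assignment).items()
        }
    report["features"] = features_report
    timings["features"] = time.perf_counter() - t0

    # --- stage: nested -----------------------------------------------------
    t0 = time.perf_counter()
    pairs, pair_report = detect_nested_pairs(table, cfg["nested"]["max_ext"])
    means = group_means(imputed, design, groups=list(results.groups))
    compute_deltas(pairs, means, groups=list(results.groups),
                   mode=cfg["nested"]["delta_mode"])
    pairs_to_frame(pairs).to_csv(outdir / "nested_pairs.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    tests = group_and_test(pairs)
    tests.to_csv(outdir / "nested_tests.tsv", sep="\t", index=False,
                 float_format="%.10g")
    report["nested"] = {
        **pair_report,
        "tests": tests.replace({np.nan: None}).to_dict(orient="records"),
    }
    if proteome is not None and any(
        p.side == "C" and p.transition in ("T->C", "C->C") for p in pairs
    ):
        pfm = context_frequency_matrix(pairs, proteome)
        pfm.rename_axis("residue").to_csv(outdir / "cleavage_context_pfm.tsv",
                                          sep="\t", float_format="%.6f")
    timings["nested"] = time.perf_counter() - t0

    _write_json(report, outdir / "report.json")
    manifest = {
        "version": __version__,
        "config": cfg,
        "input_digests": digests,
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
        "stage_rows": {"peptides": len(table), "nested_pairs": len(pairs)},
    }
    _write_json(manifest, outdir / "manifest.json")
    return report
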