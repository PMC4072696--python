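"""End-to-end orchestration: preprocess -> DE/SVA -> GSEA -> loops -> scores -> summaries.

The pipeline is a pure function of (inputs, parameters, seed): every stage
writes its table(s) into the output directory, per-stage tallies go to the
log, and a manifest records package/library versions, parameters and input
checksums so a rerun can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffexpr, enrichment, io as mio, loops as loops_mod, scoring, summaries
from .types import PipelineConfig, SchemaError

logger = logging.getLogger(__name__)

STAGES = ["de", "gsea", "loops", "score", "summarize"]

DEFAULT_PARAMS = {
    "fdr_de": 0.05,
    "fdr_gsea": 0.25,
    "min_set_size": 8,
    "min_predictors": 2,
    "fc_threshold": 2.0,
    "seed": 0,
    "sva": True,
    "n_permutations": 100,
    "sva_alpha": 0.10,
    "quantile_normalize": False,
    "paired": False,
    "cotarget_top_k": 5,
}

INPUT_KEYS = [
    "mrna",
    "mirna",
    "mrna_design",
    "mirna_design",
    "tf_gene",
    "tf_mirna",
    "mirna_targets_predicted",
    "mirna_targets_validated",
    "pathway_edges",
    "whitelist",
]


def load_config(path) -> dict:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    doc["inputs"] = {k: str(base / v) for k, v in doc.get("inputs", {}).items()}
    if "output_dir" in doc and not Path(doc["output_dir"]).is_absolute():
        doc["output_dir"] = str(base / doc["output_dir"])
    return doc


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sva_covariates(matrix, design, params):
    if not params["sva"]:
        return np.zeros((len(matrix.sample_ids), 0))
    try:
        return diffexpr.estimate_surrogate_variables(
            matrix,
            design,
            n_permutations=int(params["n_permutations"]),
            alpha=float(params["sva_alpha"]),
            seed=int(params["seed"]),
        )
    except SchemaError as exc:
        logger.warning("surrogate-variable estimation skipped: %s", exc)
        return np.zeros((len(matrix.sample_ids), 0))


def run_pipeline(config: dict, outdir=None, stop_after: str | None = None) -> dict:
    """Run the pipeline described by ``config`` (see load_config for the schema).

    Returns a dict with every intermediate object; ``stop_after`` truncates
    after the named stage ("de", "gsea", "loops", "score", "summarize").
    """
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    pconf = PipelineConfig(
        fdr_de=float(params["fdr_de"]),
        fdr_gsea=float(params["fdr_gsea"]),
        min_set_size=int(params["min_set_size"]),
        min_predictors=int(params["min_predictors"]),
        fc_threshold=float(params["fc_threshold"]),
        seed=int(params["seed"]),
    )
    inputs = config["inputs"]
    missing = [k for k in INPUT_KEYS if k not in inputs]
    if missing:
        raise SchemaError(f"config is missing input paths: {missing}")
    outdir = Path(outdir if outdir is not None else config.get("output_dir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    stop_idx = STAGES.index(stop_after) if stop_after else len(STAGES) - 1
    results: dict = {"params": params}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # ---------------------------------------------------------------- inputs
    def _read():
        mrna = mio.read_expression(inputs["mrna"], "mRNA")
        mirna = mio.read_expression(inputs["mirna"], "miRNA")
        if params["quantile_normalize"]:
            mrna = mio.quantile_normalize(mrna)
            mirna = mio.quantile_normalize(mirna)
        design_mrna = mio.read_design(inputs["mrna_design"])
        design_mirna = mio.read_design(inputs["mirna_design"])
        priordb = mio.read_priors(
            inputs["tf_gene"],
            inputs["tf_mirna"],
            inputs["mirna_targets_predicted"],
            inputs["mirna_targets_validated"],
            pconf,
        )
        pathways = mio.read_pathway_edges(inputs["pathway_edges"])
        whitelist = mio.read_whitelist(inputs["whitelist"])
        return mrna, mirna, design_mrna, design_mirna, priordb, pathways, whitelist

    mrna, mirna, design_mrna, design_mirna, priordb, pathways, whitelist = _stage(
        "read-inputs", _read
    )
    results.update(priordb=priordb, pathways=pathways, whitelist=whitelist)

    # -------------------------------------------------------------------- de
    def _de():
        cov_mrna = _sva_covariates(mrna, design_mrna, params)
        cov_mirna = _sva_covariates(mirna, design_mirna, params)
        mrna_de, mrna_params = diffexpr.fit_moderated_t(
            mrna, design_mrna, covariates=cov_mrna
        )
        mirna_de, mirna_params = diffexpr.fit_moderated_t(
            mirna, design_mirna, covariates=cov_mirna, paired=bool(params["paired"])
        )
        return cov_mrna, cov_mirna, mrna_de, mirna_de, mrna_params, mirna_params

    cov_mrna, cov_mirna, mrna_de, mirna_de, mrna_params, mirna_params = _stage("de", _de)
    mrna_mht = diffexpr.call_differential(mrna_de, pconf.fdr_de)
    mirna_mht = diffexpr.call_differential(mirna_de, pconf.fdr_de)
    logger.info(
        "de: %d/%d mRNAs and %d/%d miRNAs significant at FDR %.3g "
        "(%d + %d surrogate variables)",
        len(mrna_mht), len(mrna_de), len(mirna_mht), len(mirna_de), pconf.fdr_de,
        cov_mrna.shape[1], cov_mirna.shape[1],
    )
    diffexpr.write_de_table(mrna_de, outdir / "mrna_de.tsv")
    diffexpr.write_de_table(mirna_de, outdir / "mirna_de.tsv")
    diffexpr.write_de_table(
        diffexpr.fold_change_filter(mrna_mht, pconf.fc_threshold),
        outdir / "mrna_de_high_fold_change.tsv",
    )
    results.update(
        mrna_de=mrna_de, mirna_de=mirna_de, mrna_mht=mrna_mht, mirna_mht=mirna_mht,
        n_sv_mrna=cov_mrna.shape[1], n_sv_mirna=cov_mirna.shape[1],
    )
    if stop_idx < 1:
        _write_manifest(config, params, inputs, outdir, results)
        return results

    # ------------------------------------------------------------------ gsea
    def _gsea():
        universe = mrna.feature_ids
        tf_sets = enrichment.build_tf_sets(priordb, universe, mrna_de, pconf)
        mirna_sets = enrichment.build_mirna_sets(
            priordb, whitelist, universe, mirna_de, pconf
        )
        path_sets = enrichment.pathway_sets(pathways, universe)
        enr = enrichment.run_gsea(tf_sets, mirna_sets, path_sets, mrna_de, mirna_de, pconf)
        combined_mrna = enrichment.combine_lists(mrna_mht, enr, mrna_de, "TF", pconf)
        combined_mirna = enrichment.combine_lists(mirna_mht, enr, mirna_de, "miRNA", pconf)
        return tf_sets, mirna_sets, path_sets, enr, combined_mrna, combined_mirna

    tf_sets, mirna_sets, path_sets, enr, combined_mrna, combined_mirna = _stage(
        "gsea", _gsea
    )
    sig_pathways = enrichment.significant_sets(enr, "pathway", pconf)
    logger.info(
        "gsea: %d TF sets, %d miRNA sets, %d pathway sets tested; "
        "%d significant pathways; combined lists %d mRNAs / %d miRNAs",
        len(tf_sets), len(mirna_sets), len(path_sets), len(sig_pathways),
        len(combined_mrna), len(combined_mirna),
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    combined_mrna.to_csv(outdir / "combined_mrna.tsv", sep="\t", index=False)
    combined_mirna.to_csv(outdir / "combined_mirna.tsv", sep="\t", index=False)
    results.update(
        enrichment=enr, combined_mrna=combined_mrna, combined_mirna=combined_mirna,
        significant_pathways=sig_pathways,
    )
    if stop_idx < 2:
        _write_manifest(config, params, inputs, outdir, results)
        return results

    # ----------------------------------------------------------------- loops
    def _loops():
        restricted = loops_mod.restrict_priors(
            priordb,
            combined_mrna["feature_id"],
            combined_mirna["feature_id"],
            mrna.feature_ids,
        )
        return restricted, loops_mod.build_all_loops(
            restricted, pathways, mrna.feature_ids, sig_pathways
        )

    restricted, raw_loops = _stage("loops", _loops)
    logger.info("loops: %d loops constructed", len(raw_loops))
    results.update(restricted_priors=restricted, raw_loops=raw_loops)
    if stop_idx < 3:
        scoring.write_loops(raw_loops, outdir / "loops.tsv")
        _write_manifest(config, params, inputs, outdir, results)
        return results

    # ----------------------------------------------------------------- score
    def _score():
        annotated = scoring.annotate_loops(raw_loops, mrna_de, mirna_de)
        return scoring.rank_and_group(annotated)

    scored = _stage("score", _score)
    scoring.write_loops(scored, outdir / "loops.tsv")
    for group in scoring.GROUPS:
        sub = scored[scored["group"] == group] if not scored.empty else scored
        if len(sub):
            safe = group.replace("-", "_").lower()
            scoring.write_loops(sub, outdir / f"loops_{safe}.tsv")
    if not scored.empty:
        counts = scored["group"].value_counts()
        logger.info(
            "score: loops per group %s",
            {g: int(counts.get(g, 0)) for g in scoring.GROUPS},
        )
    results["loops"] = scored
    if stop_idx < 4:
        _write_manifest(config, params, inputs, outdir, results)
        return results

    # ------------------------------------------------------------- summaries
    def _summarize():
        out = {}
        ffl = scored[scored["loop_type"].isin(["I", "II"])]
        if len(ffl):
            out["subtype_fractions"] = summaries.subtype_fractions(scored)
            mirna_directions = mirna_de["direction"].to_dict()
            per_mirna, cumulative = summaries.mirna_attribution(
                scored, mrna_mht, mirna_directions
            )
            out["mirna_attribution"] = per_mirna
            out["mirna_attribution_cumulative"] = cumulative
            top = list(per_mirna["mirna"].head(int(params["cotarget_top_k"])))
            out["cotargeting"] = summaries.cotargeting_overlap(top, scored)
            out["mirna_tf_pairs"] = summaries.extract_mirna_tf_pairs(scored)
        return out

    tables = _stage("summarize", _summarize)
    for name, tab in tables.items():
        tab.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    results.update(tables)
    _write_manifest(config, params, inputs, outdir, results)
    return results


def _write_manifest(config, params, inputs, outdir, results) -> None:
    manifest = {
        "mirloop_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "params": {k: params[k] for k in sorted(params)},
        "input_checksums": {k: _sha256(v) for k, v in sorted(inputs.items())},
        "counts": {
            "mrna_de": int(len(results.get("mrna_mht", []))),
            "mirna_de": int(len(results.get("mirna_mht", []))),
            "combined_mrna": int(len(results.get("combined_mrna", []))),
            "combined_mirna": int(len(results.get("combined_mirna", []))),
            "loops": int(len(results.get("loops", results.get("raw_loops", [])))),
        },
    }
    with open(Path(outdir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
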