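"""End-to-end orchestration: derive -> map -> preprocess -> score ->
associate -> survival, from a single YAML/JSON config.

Stages run in dependency order; any stage failure aborts with a
stage-named error. Outputs are deterministic given config (plus seed for
simulation inputs): re-running into a clean directory reproduces
byte-identical files. Warnings raised by library calls are collected into
the run summary and echoed to the log.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import scoring, signature as sigmod, stats
from .errors import ConfigError, MycsigError
from .version import __version__

log = logging.getLogger("mycsig")

_DEFAULTS = {
    "expression": {"orientation": "genes_in_rows", "scale": "raw"},
    "preprocess": {"log2": True, "pseudocount": 1.0, "centering": "all"},
    "signature": {},
    "derive": {"padj_threshold": 0.05, "lfc_threshold": 0.0, "policy": "keep_all"},
    "scoring": {
        "min_overlap": 3,
        "gene_set_methods": ["mean", "ssgsea"],
        "ssgsea": {"alpha": 0.25, "normalize": False},
    },
    "dichotomize": {"cutpoint": 0.0},
    "associations": {"method": "pearson", "targets": []},
    "survival": {"cox": True, "tie_method": "breslow"},
}


def load_config(path: str | Path) -> dict:
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise mio.FormatError(f"{path}: cannot parse config ({exc})") from None
    if not isinstance(cfg, dict):
        raise mio.FormatError(f"{path}: config must be a mapping")
    return cfg


def _merged(cfg: dict, section: str) -> dict:
    out = dict(_DEFAULTS.get(section, {}))
    sub = cfg.get(section) or {}
    if isinstance(sub, dict):
        for k, v in sub.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = {**out[k], **v}
            else:
                out[k] = v
    return out


def validate_config(cfg: dict | str | Path) -> list[str]:
    """Return every detected problem (empty list = OK)."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    problems: list[str] = []

    expr = _merged(cfg, "expression")
    if not expr.get("path"):
        problems.append("expression.path is required")
    elif not Path(expr["path"]).exists():
        problems.append(f"expression.path does not exist: {expr['path']}")
    if expr.get("orientation") not in ("genes_in_rows", "samples_in_rows"):
        problems.append("expression.orientation must be genes_in_rows or samples_in_rows")
    if expr.get("scale") not in ("raw", "log2", "log2-centered"):
        problems.append("expression.scale must be raw, log2 or log2-centered")

    prep = _merged(cfg, "preprocess")
    if prep["pseudocount"] is None or float(prep["pseudocount"]) < 0:
        problems.append("preprocess.pseudocount must be nonnegative")
    if prep["centering"] not in ("all", "signature", "none"):
        problems.append("preprocess.centering must be all, signature or none")

    sig = cfg.get("signature") or {}
    derive = sig.get("derive")
    if sig.get("path") and derive:
        problems.append("signature: give either path or derive, not both")
    if not sig.get("path") and not derive:
        problems.append("signature.path or signature.derive is required")
    if sig.get("path") and not Path(sig["path"]).exists():
        problems.append(f"signature.path does not exist: {sig['path']}")
    if derive:
        tabs = derive.get("de_tables") or []
        if len(tabs) < 2:
            problems.append("signature.derive.de_tables needs at least 2 paths")
        for p in tabs:
            if not Path(p).exists():
                problems.append(f"DE table does not exist: {p}")
        om = derive.get("ortholog_map")
        if om and not Path(om).exists():
            problems.append(f"ortholog map does not exist: {om}")

    gmt = cfg.get("gene_sets")
    if gmt and not Path(gmt).exists():
        problems.append(f"gene_sets does not exist: {gmt}")

    sc = _merged(cfg, "scoring")
    if int(sc["min_overlap"]) < 1:
        problems.append("scoring.min_overlap must be >= 1")
    if float(sc["ssgsea"]["alpha"]) < 0:
        problems.append("scoring.ssgsea.alpha must be nonnegative")
    for meth in sc["gene_set_methods"]:
        if meth not in ("mean", "ssgsea"):
            problems.append(f"unknown gene-set scoring method {meth!r}")

    dich = _merged(cfg, "dichotomize")
    try:
        if not np.isfinite(float(dich["cutpoint"])):
            problems.append("dichotomize.cutpoint must be finite")
    except (TypeError, ValueError):
        problems.append("dichotomize.cutpoint must be a number")

    assoc = _merged(cfg, "associations")
    if assoc["method"] not in ("pearson", "spearman"):
        problems.append("associations.method must be pearson or spearman")

    surv = cfg.get("survival") or {}
    if surv:
        if not surv.get("path"):
            problems.append("survival.path is required when survival is configured")
        elif not Path(surv["path"]).exists():
            problems.append(f"survival.path does not exist: {surv['path']}")
        if _merged(cfg, "survival")["tie_method"] not in ("breslow", "efron"):
            problems.append("survival.tie_method must be breslow or efron")

    if not cfg.get("output_dir"):
        problems.append("output_dir is required")
    return problems


@dataclass
class RunSummary:
    """Machine-readable record of one pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    associations: list[dict] = field(default_factory=list)
    survival: dict | None = None

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
            "outputs": self.outputs,
            "associations": self.associations,
            "survival": self.survival,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(cfg: dict | str | Path, output_dir: str | Path | None = None) -> RunSummary:
    """Execute the configured analysis; see module docstring for stages."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    summary = RunSummary(config=cfg)
    caught: list[str] = []

    def record(stage: str, **info):
        summary.stages.append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    def emit(path: Path):
        summary.outputs.append(path.name)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            _run_stages(cfg, outdir, summary, record, emit)
        finally:
            for w in wlist:
                msg = str(w.message)
                caught.append(msg)
                log.warning("%s", msg)
    summary.warnings = caught

    summary_path = outdir / "summary.json"
    summary.outputs.append(summary_path.name)
    summary_path.write_text(summary.to_json() + "\n")
    return summary


def _run_stages(cfg, outdir, summary, record, emit):
    # --- signature ------------------------------------------------------
    sig_cfg = cfg.get("signature") or {}
    if sig_cfg.get("path"):
        signature = mio.read_signature(sig_cfg["path"])
        record("signature", source=str(sig_cfg["path"]), size=len(signature))
    else:
        dcfg = {**_DEFAULTS["derive"], **sig_cfg["derive"]}
        tables = [sigmod.read_de_table(p) for p in dcfg["de_tables"]]
        result = sigmod.derive_shared_signature(
            tables,
            padj_threshold=float(dcfg["padj_threshold"]),
            lfc_threshold=float(dcfg["lfc_threshold"]),
        )
        if result.signature is None:
            raise MycsigError("signature stage: derivation produced an empty signature")
        signature = result.signature
        if result.conflicts:
            path = outdir / "sign_conflicts.tsv"
            result.conflict_frame().to_csv(path, sep="\t", index=False)
            emit(path)
        record(
            "derive",
            n_tables=len(tables),
            size=len(signature),
            conflicts=len(result.conflicts),
        )
        if dcfg.get("ortholog_map"):
            omap = sigmod.read_ortholog_map(dcfg["ortholog_map"])
            mres = sigmod.map_orthologs(signature, omap, policy=dcfg["policy"])
            if mres.signature is None:
                raise MycsigError("map-orthologs stage: no genes mapped")
            signature = mres.signature
            record(
                "map_orthologs",
                size=len(signature),
                unmapped=len(mres.unmapped),
                conflicts=len(mres.conflicts),
            )
    sig_path = outdir / "signature_used.tsv"
    mio.write_signature(signature, sig_path)
    emit(sig_path)

    # --- expression + preprocessing -------------------------------------
    expr_cfg = _merged(cfg, "expression")
    matrix = mio.read_expression(
        expr_cfg["path"],
        orientation=expr_cfg["orientation"],
        scale=expr_cfg["scale"],
    )
    record("read_expression", genes=matrix.n_genes, samples=matrix.n_samples,
           scale=matrix.scale)

    prep = _merged(cfg, "preprocess")
    if matrix.scale == "raw":
        if not prep["log2"]:
            raise ConfigError(
                "preprocess stage: raw input requires preprocess.log2: true"
            )
        matrix = mio.log2_transform(matrix, pseudocount=float(prep["pseudocount"]))
    centering = prep["centering"]
    if centering == "signature" :
        matrix = mio.median_center(matrix.subset_genes(signature.genes))
    elif centering == "all":
        matrix = mio.median_center(matrix)
    record("preprocess", centering=centering, scale=matrix.scale,
           genes=matrix.n_genes)

    overlap = sigmod.signature_overlap_report(signature, matrix)
    overlap_small = {k: v for k, v in overlap.items() if k != "absent_genes"}
    record("signature_overlap", **overlap_small)

    # --- scoring ---------------------------------------------------------
    sc = _merged(cfg, "scoring")
    score_vectors: dict[str, scoring.ScoreVector] = {}
    myc_scores = scoring.score_direction_correlation(
        matrix,
        signature,
        min_overlap=int(sc["min_overlap"]),
        require_centered=centering != "none",
    )
    score_vectors[signature.name] = myc_scores
    gene_sets = mio.read_gmt(cfg["gene_sets"]) if cfg.get("gene_sets") else []
    for gs in gene_sets:
        if "mean" in sc["gene_set_methods"]:
            score_vectors[f"{gs.name}_mean"] = scoring.score_mean(
                matrix, gs, min_overlap=int(sc["min_overlap"])
            )
        if "ssgsea" in sc["gene_set_methods"]:
            score_vectors[f"{gs.name}_ssgsea"] = scoring.score_ssgsea(
                matrix,
                gs,
                alpha=float(sc["ssgsea"]["alpha"]),
                normalize=bool(sc["ssgsea"]["normalize"]),
            )
    scores_path = outdir / "scores.tsv"
    frames = []
    for name, sv in score_vectors.items():
        frame = sv.to_frame()
        frame.insert(0, "name", name)
        frames.append(frame)
    pd.concat(frames).to_csv(scores_path, sep="\t", index_label="sample")
    emit(scores_path)
    record("scoring", scores=sorted(score_vectors), n_samples=len(myc_scores))

    # --- dichotomization -------------------------------------------------
    cutpoint = float(_merged(cfg, "dichotomize")["cutpoint"])
    groups = scoring.dichotomize(myc_scores, cutpoint=cutpoint)
    groups_path = outdir / "groups.tsv"
    groups.to_frame().to_csv(groups_path, sep="\t", index_label="sample")
    emit(groups_path)
    record(
        "dichotomize",
        cutpoint=cutpoint,
        high=int((groups == "High").sum()),
        low=int((groups == "Low").sum()),
    )

    # --- associations ----------------------------------------------------
    assoc_cfg = _merged(cfg, "associations")
    targets = list(assoc_cfg["targets"]) or [
        n for n in score_vectors if n != signature.name
    ]
    results = []
    norm_index = {mio.normalize_symbol(g): g for g in matrix.gene_ids}
    for target in targets:
        if target in score_vectors:
            y = score_vectors[target].scores
        elif mio.normalize_symbol(target) in norm_index:
            y = matrix.data.loc[norm_index[mio.normalize_symbol(target)]]
        else:
            raise ConfigError(
                f"association target {target!r} is neither a score nor a matrix gene"
            )
        results.append(
            stats.correlate(
                myc_scores.scores,
                y,
                method=assoc_cfg["method"],
                name_x=signature.name,
                name_y=target,
            )
        )
    if results:
        stats.adjust_family(results)
        assoc_frame = stats.association_frame(results)
        assoc_path = outdir / "associations.tsv"
        assoc_frame.to_csv(assoc_path, sep="\t", index=False)
        emit(assoc_path)
        summary.associations = assoc_frame.to_dict(orient="records")
    record("associate", n_tests=len(results), method=assoc_cfg["method"])

    # --- survival ---------------------------------------------------------
    surv_cfg = cfg.get("survival") or {}
    if not surv_cfg:
        record("survival", skipped=True)
        return
    table = mio.read_survival(surv_cfg["path"]).with_groups(groups)
    out: dict = {"n": len(table), "groups": {}}
    for label in sorted(set(table.group)):
        curve = stats.km_estimate(table, group=label)
        km_path = outdir / f"km_{label}.tsv"
        curve.to_frame().to_csv(km_path, sep="\t", index=False)
        emit(km_path)
        med = stats.median_survival(curve)
        out["groups"][label] = {
            "n": int((table.group == label).sum()),
            "events": int(table.data.loc[table.group == label, "event"].sum()),
            "median_survival": med,
        }
    lr = stats.logrank_test(table)
    out["logrank"] = {
        "chi2": lr.chi2,
        "p_value": lr.p_value,
        "observed": lr.observed,
        "expected": lr.expected,
    }
    if _merged(cfg, "survival")["cox"]:
        cox = stats.cox_binary(table, tie_method=_merged(cfg, "survival")["tie_method"])
        out["cox"] = {
            "log_hr": cox.log_hr,
            "hr": cox.hr,
            "se": cox.se,
            "ci95": list(cox.ci95),
            "p_value": cox.p_value,
            "n_events": cox.n_events,
            "tie_method": cox.tie_method,
            "exposed_group": cox.exposed_group,
        }
    surv_path = outdir / "survival.json"
    surv_path.write_text(json.dumps(out, indent=2, sort_keys=True, default=_jsonable) + "\n")
    emit(surv_path)
    summary.survival = out
    record("survival", n=len(table), logrank_p=lr.p_value)
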