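"""Orchestration of the standardised evaluation and report rendering.

``run_evaluation`` executes, for each configured trait and PRS source:
raw-score distribution summaries, per-ancestry effect metrics (gated at
100 cases), cumulative-incidence curves per percentile band (gated at
more than 40 cases), Enhanced-vs-comparator paired bootstrap comparisons,
cross-ancestry relative performance, and — when the inputs allow — the
carrier-equivalence and multivariate mortality blocks.  Any per-block
failure is captured as an error entry; the report is always emitted
unless cohort I/O itself fails.

The report is a plain nested dict serialisable to JSON, with a versioned
schema shipped in ``prsbench/schema``; every suppressed estimate carries
its gating reason, and provenance records the config hash, seed and
package version so a rerun can be checked byte for byte (timestamp
excluded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import ancestry_relative_change, average_relative_change, bootstrap_compare
from .carriers import carrier_cumulative_risk, case_ratio_by_age, match_percentile
from .cohort import (
    AnalysisConfig,
    BinaryPhenotype,
    CarrierTable,
    CohortTable,
    QuantPhenotype,
    ScoreSet,
    align,
    distribution_summary,
)
from .errors import EstimationError, PrsBenchError
from .incidence import PercentileBand, assign_bands, km_curve
from .metrics import auc, beta_per_sd, hr_per_sd, or_per_sd
from .multivariate import (
    cluster_order,
    harrells_c_difference,
    prs_correlation_matrix,
    royston_r2,
    stepwise_mortality,
)

SCHEMA_VERSION = "1.0"


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _err(exc: Exception) -> dict:
    return {"error": type(exc).__name__, "message": str(exc)}


def run_evaluation(
    config: AnalysisConfig,
    cohort: CohortTable,
    scores: ScoreSet,
    phenotypes: dict[str, BinaryPhenotype | QuantPhenotype],
    carriers: dict[str, CarrierTable] | None = None,
    multivariate: bool = True,
) -> dict:
    """Run the standardised evaluation; returns the report dict."""
    carriers = carriers or {}
    bands = [PercentileBand(lo, hi) for lo, hi in config.band_definitions]
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.random_seed,
            "incidence_mode": config.incidence_mode,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "cohort_diagnostics": list(cohort.diagnostics),
            "n_rejected_rows": cohort.n_rejected,
        },
        "distribution": {},
        "traits": {},
        "carrier_equivalence": {},
        "multivariate": {},
    }

    try:
        report["distribution"] = distribution_summary(scores, cohort).to_dict(orient="records")
    except PrsBenchError as exc:
        report["distribution"] = _err(exc)

    ancestries = [a for a in config.ancestries if a in set(cohort.data["ancestry"])]

    # group score columns by trait
    by_trait: dict[str, list[str]] = {}
    for name in scores.score_names:
        trait = scores.metadata.get(name, {}).get("trait", name)
        by_trait.setdefault(trait, []).append(name)

    for trait, pheno in phenotypes.items():
        trait_block: dict = {"kind": "binary" if isinstance(pheno, BinaryPhenotype) else "quant",
                             "sources": {}, "comparisons": [], "relative_change": {}}
        report["traits"][trait] = trait_block
        score_cols = by_trait.get(trait, [])
        if not score_cols:
            trait_block["error"] = f"no score column for trait {trait!r}"
            continue
        try:
            frame = align(cohort, scores, pheno)
        except PrsBenchError as exc:
            trait_block["error"] = _err(exc)
            continue
        trait_block["dropped"] = frame.dropped

        for col in score_cols:
            source = scores.source_of(col)
            src_block: dict = {"score": col, "metrics": {}, "incidence": {}}
            trait_block["sources"][col] = src_block
            per_anc_estimates = {}
            for anc in ancestries:
                sub = frame.subset((frame.data["ancestry"] == anc).to_numpy())
                if sub.n == 0:
                    src_block["metrics"][anc] = {"error": "EmptyStratum",
                                                 "message": f"no {anc} individuals"}
                    continue
                anc_block = {}
                stratum = {"trait": trait, "ancestry": anc, "source": source}
                try:
                    if frame.kind == "binary":
                        est = or_per_sd(sub, col, covariates=config.covariates,
                                        min_cases=config.min_cases_metric, stratum=stratum)
                        anc_block["or_per_sd"] = est.to_dict()
                        per_anc_estimates[anc] = est
                        anc_block["hr_per_sd"] = hr_per_sd(
                            sub, col, covariates=config.covariates,
                            incident=config.incidence_mode == "incident",
                            min_cases=config.min_cases_metric, stratum=stratum,
                        ).to_dict()
                        anc_block["auc"] = auc(
                            sub, col, min_cases=config.min_cases_metric, stratum=stratum
                        ).to_dict()
                    else:
                        est = beta_per_sd(sub, col, covariates=config.covariates,
                                          stratum=stratum)
                        anc_block["beta_per_sd"] = est.to_dict()
                        per_anc_estimates[anc] = est
                except PrsBenchError as exc:
                    anc_block["error"] = _err(exc)
                src_block["metrics"][anc] = anc_block

                if frame.kind == "binary" and sub.n > 0:
                    curves = {}
                    try:
                        masks = assign_bands(sub.data[col], bands, sub.data["individual_id"])
                        for band in bands:
                            curve = km_curve(
                                sub, masks[band.label], mode=config.incidence_mode,
                                band=band, min_cases_curve=config.min_cases_curve,
                            )
                            curves[band.label] = curve.to_dict()
                    except PrsBenchError as exc:
                        curves = _err(exc)
                    src_block["incidence"][anc] = curves

            # cross-ancestry relative change vs the reference (first ancestry)
            ref = ancestries[0] if ancestries else None
            if ref in per_anc_estimates:
                for anc, est in per_anc_estimates.items():
                    if anc == ref or est.suppressed:
                        continue
                    try:
                        rc = ancestry_relative_change(est, per_anc_estimates[ref], trait=trait)
                        trait_block["relative_change"].setdefault(col, {})[anc] = rc.to_dict()
                    except PrsBenchError as exc:
                        trait_block["relative_change"].setdefault(col, {})[anc] = _err(exc)

        # sex-stratified effects and female-vs-male difference (reference
        # ancestry, first source)
        ref = ancestries[0] if ancestries else None
        if ref is not None and frame.sex_restriction is None:
            from .strata import sex_difference_test, sex_stratified_effect

            metric = "or_per_sd" if frame.kind == "binary" else "beta_per_sd"
            sub = frame.subset((frame.data["ancestry"] == ref).to_numpy())
            strata_block: dict = {"ancestry": ref, "metric": metric}
            try:
                per_sex = {
                    label: sex_stratified_effect(
                        sub, sex, metric=metric, score=score_cols[0],
                        min_cases=config.min_cases_metric if frame.kind == "binary" else None,
                    )
                    for label, sex in (("all", None), ("female", "female"), ("male", "male"))
                }
                strata_block["effects"] = {
                    k: v.to_dict() for k, v in per_sex.items()
                }
                strata_block["female_vs_male"] = sex_difference_test(
                    per_sex["female"], per_sex["male"]
                ).to_dict()
            except PrsBenchError as exc:
                strata_block["error"] = _err(exc)
            trait_block["sex_strata"] = strata_block

        # paired bootstrap comparison between the first two sources
        if len(score_cols) >= 2 and frame.kind == "binary":
            ref_anc = ancestries[0] if ancestries else None
            sub = frame.subset((frame.data["ancestry"] == ref_anc).to_numpy()) if ref_anc else frame
            try:
                comp = bootstrap_compare(
                    sub, score_cols[0], score_cols[1], metric="or_per_sd",
                    n_bootstrap=config.n_bootstrap, seed=config.random_seed,
                )
                trait_block["comparisons"].append(comp.to_dict())
            except PrsBenchError as exc:
                trait_block["comparisons"].append(_err(exc))

    # pooled cross-trait average of relative changes, per target ancestry
    pooled: dict = {}
    for anc in ancestries[1:]:
        changes = []
        for trait, tb in report["traits"].items():
            for col, per_anc in tb.get("relative_change", {}).items():
                d = per_anc.get(anc)
                if d and "change" in d:
                    from .benchmark import RelativeChange
                    changes.append(RelativeChange(**d))
        if changes:
            try:
                pooled[anc] = average_relative_change(changes).to_dict()
            except PrsBenchError as exc:
                pooled[anc] = _err(exc)
    report["relative_change_pooled"] = pooled

    # carrier equivalence per disease with a carrier table
    for trait, ct in carriers.items():
        pheno = phenotypes.get(trait)
        if pheno is None or not isinstance(pheno, BinaryPhenotype):
            continue
        cols = by_trait.get(trait, [])
        if not cols:
            continue
        col = cols[0]
        try:
            frame = align(cohort, scores, pheno)
            risk, ci, curve = carrier_cumulative_risk(frame, ct, anchor_age=70.0,
                                                      mode=config.incidence_mode)
            eq = match_percentile(
                frame, col, target_risk=risk, anchor_age=70.0,
                mode=config.incidence_mode, carrier_ci=ci,
                n_carriers=int((ct.data["carrier_flag"] == 1).sum()),
            )
            ratios = case_ratio_by_age(frame, col, eq.matched_fraction, ct)
            report["carrier_equivalence"][trait] = {
                "carrier_risk_age70": risk,
                "carrier_ci": list(ci),
                "equivalence": eq.to_dict(),
                "case_ratios": ratios.to_dict(),
            }
        except PrsBenchError as exc:
            report["carrier_equivalence"][trait] = _err(exc)

    # multivariate block: correlations + mortality models
    if multivariate and len(scores.score_names) >= 2:
        try:
            cm = prs_correlation_matrix(scores, subgroup="all")
            if not cm.undefined:
                cluster_order(cm)  # annotates cm.order
            report["multivariate"]["correlations"] = cm.to_dict()
        except PrsBenchError as exc:
            report["multivariate"]["correlations"] = _err(exc)
        if cohort.data["death_age"].notna().any() if "death_age" in cohort.data else False:
            try:
                own = stepwise_mortality(cohort, scores, target="own")
                report["multivariate"]["mortality_own"] = own.to_dict()
                if cohort.parents is not None and not cohort.parents.empty:
                    par = stepwise_mortality(cohort, scores, target="parental")
                    report["multivariate"]["mortality_parental"] = par.to_dict()
            except PrsBenchError as exc:
                report["multivariate"]["mortality"] = _err(exc)

    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def validate_report(report: dict) -> None:
    """Structural validation against the shipped schema (required keys and
    basic types); raises EstimationError on violation."""
    schema = json.loads(
        resources.files("prsbench").joinpath("schema/report-v1.json").read_text()
    )
    def check(obj, spec, path="report"):
        for key, kind in spec.get("required", {}).items():
            if key not in obj:
                raise EstimationError(f"report invalid: {path}.{key} missing")
            if kind == "object" and not isinstance(obj[key], dict):
                raise EstimationError(f"report invalid: {path}.{key} not an object")
    check(report, schema)
    if report.get("schema_version") != SCHEMA_VERSION:
        raise EstimationError(
            f"schema version mismatch: {report.get('schema_version')} != {SCHEMA_VERSION}"
        )


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    validate_report(report)
    text = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    if path is not None:
        Path(path).write_text(text)
    return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def report_to_tsv(report: dict, path: str | Path | None = None) -> pd.DataFrame:
    """Flat summary table: one row per (trait, ancestry, source, metric)."""
    rows = []
    for trait, tb in report.get("traits", {}).items():
        for col, src_block in tb.get("sources", {}).items():
            for anc, metrics_block in src_block.get("metrics", {}).items():
                for metric, d in metrics_block.items():
                    if not isinstance(d, dict) or "estimate" not in d:
                        continue
                    rows.append({
                        "trait": trait, "ancestry": anc, "score": col,
                        "source": d.get("stratum", {}).get("source", ""),
                        "metric": metric,
                        "estimate": d["estimate"], "ci_low": d["ci_low"],
                        "ci_high": d["ci_high"], "n_total": d["n_total"],
                        "n_cases": d["n_cases"], "suppressed": d["suppressed"],
                        "gate_reason": d["gate_reason"],
                    })
    df = pd.DataFrame(rows, columns=[
        "trait", "ancestry", "score", "source", "metric", "estimate",
        "ci_low", "ci_high", "n_total", "n_cases", "suppressed", "gate_reason",
    ])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df


def plot_incidence(report: dict, trait: str, score: str, ancestry: str, path: str | Path):
    """Three-band cumulative-incidence plot (top band red, middle green,
    bottom blue, shaded 95% CIs)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    block = report["traits"][trait]["sources"][score]["incidence"][ancestry]
    colors = {"top": "tab:red", "bottom": "tab:blue"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, cd in block.items():
        if cd.get("suppressed") or "curve" not in cd:
            continue
        color = next((c for k, c in colors.items() if label.startswith(k)), "tab:green")
        c = cd["curve"]
        ax.step(c["age"], 100 * np.asarray(c["cum_inc"]), where="post",
                label=label, color=color)
        ax.fill_between(c["age"], 100 * np.asarray(c["ci_low"]),
                        100 * np.asarray(c["ci_high"]), step="post",
                        alpha=0.2, color=color)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Cumulative incidence (%)")
    ax.set_title(f"{trait} ({ancestry}, {score})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_summary(report: dict, fmt: str, outdir: str | Path) -> list[Path]:
    """Render the report as json, tsv or plots; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        p = outdir / "report.json"
        report_to_json(report, p)
        written.append(p)
    elif fmt == "tsv":
        p = outdir / "summary.tsv"
        report_to_tsv(report, p)
        written.append(p)
    elif fmt == "plots":
        for trait, tb in report.get("traits", {}).items():
            for col, src in tb.get("sources", {}).items():
                for anc, block in src.get("incidence", {}).items():
                    if not isinstance(block, dict):
                        continue
                    if any(isinstance(v, dict) and "curve" in v for v in block.values()):
                        p = outdir / f"incidence_{trait}_{col}_{anc}.png"
                        plot_incidence(report, trait, col, anc, p)
                        written.append(p)
    else:
        raise EstimationError(f"unknown render format {fmt!r}")
    return written
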