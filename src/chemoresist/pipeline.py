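"""Track orchestration: wiring the stages into reproducible analyses.

Each track reads plain TSV/CSV inputs, executes a fixed stage sequence,
writes every intermediate as a flat TSV artifact so any stage can be
inspected or re-run independently, and returns a
:class:`PipelineReport`. Identical config and inputs produce
byte-identical outputs.

Tracks
------
``pdx_molecular``
    raw RPPA matrix → species filter → log2 → bidirectional median
    centering → PAS per signed gene set → normality-gated two-group
    comparison (e.g. sensitive vs resistant PDX).
``paired_delta``
    paired pre/post normalized matrices → per-patient delta-PAS with
    Up/Down calls → cross-pathway Pearson correlation when two or more
    pathways are scored.
``survival_strat``
    expression matrix + survival table → percentile-union High/Low
    stratification → Kaplan-Meier curves, medians, log-rank, O/E
    hazard ratio.
``growth``
    caliper table → inclusion filtering → relative-volume trapezoid
    AUC per tumor → relative AUC vs the untreated-control arm.
``hubs``
    DEG table + confidence-scored edge list → top-n |LFC| selection →
    degree-filtered hub network.
``simulate``
    synthetic inputs for any of the above, with a truth sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import simulate as sim
from .growth import partition_by_inclusion, relative_auc
from .io import InvariantError, RunConfig
from .network import extract_hubs, select_top_deg
from .pathway import compare_groups, compute_pas, correlate_deltas, delta_pas
from .rppa import filter_species, log2_transform, median_center_bidirectional
from .survival import StratificationRule, km_fit, km_median, logrank_test, stratify

logger = logging.getLogger("chemoresist")

TRACKS = ("pdx_molecular", "paired_delta", "survival_strat", "growth", "hubs", "simulate")


@dataclass
class PipelineReport:
    """Record of one track run: file paths, parameter echo, warnings."""

    track: str
    seed: int
    parameters: dict
    inputs: dict
    outputs: dict
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _require(inputs: dict, key: str) -> Path:
    if key not in inputs:
        raise InvariantError(f"track input {key!r} not provided")
    path = Path(inputs[key])
    if not path.exists():
        raise InvariantError(f"input file does not exist: {path}")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def write_truth(truth: sim.SimTruth, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# simulate track


def simulate_to_files(kind: str, config: RunConfig, out_dir: str | Path) -> PipelineReport:
    """Generate one input class and write it plus a truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if kind == "rppa":
        matrix, truth = sim.gen_rppa(config)
        cio.write_matrix(matrix, out / "rppa_raw.tsv")
        cio.write_signed_sets(truth.pathways, out / "pathways.gmtx")
        groups = pd.DataFrame(sorted(truth.group_labels.items()), columns=["sample_id", "group"])
        groups.to_csv(out / "groups.tsv", sep="\t", index=False)
        outputs = {"matrix": "rppa_raw.tsv", "sets": "pathways.gmtx", "groups": "groups.tsv"}
    elif kind == "survival":
        matrix, cohort, truth = sim.gen_survival(config)
        cio.write_matrix(matrix, out / "expression.tsv")
        cio.write_survival_table(cohort, out / "survival.tsv")
        outputs = {"matrix": "expression.tsv", "survival": "survival.tsv"}
    elif kind == "growth":
        series, truth = sim.gen_growth(config)
        cio.write_growth_table(series, out / "growth.csv")
        outputs = {"growth": "growth.csv"}
    elif kind == "paired":
        pre, post, truth = sim.gen_paired(config)
        cio.write_matrix(pre, out / "pre.tsv")
        cio.write_matrix(post, out / "post.tsv")
        cio.write_signed_sets(truth.pathways, out / "pathways.gmtx")
        pairs = pd.DataFrame(
            [(p, s_pre, s_post) for p, (s_pre, s_post) in sorted(truth.pairing.items())],
            columns=["patient", "pre_sample", "post_sample"],
        )
        pairs.to_csv(out / "pairing.tsv", sep="\t", index=False)
        outputs = {"pre": "pre.tsv", "post": "post.tsv", "pairing": "pairing.tsv",
                   "sets": "pathways.gmtx"}
    elif kind == "edges":
        edges, truth = sim.gen_edges(config)
        cio.write_edge_list(edges, out / "edges.tsv")
        genes = pd.DataFrame({"gene": sorted({*edges.edges["gene_a"], *edges.edges["gene_b"]})})
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        outputs = {"edges": "edges.tsv", "genes": "genes.tsv"}
    else:
        raise InvariantError(f"unknown simulate kind {kind!r}; expected one of "
                             "rppa/survival/growth/paired/edges")

    write_truth(truth, out / "truth.json")
    outputs["truth"] = "truth.json"
    outputs = {k: str(out / v) for k, v in outputs.items()}
    return PipelineReport("simulate", config.seed, {"kind": kind}, {}, outputs)


# ---------------------------------------------------------------------------
# analysis tracks


def _track_pdx_molecular(config: RunConfig, inputs: dict, out: Path) -> PipelineReport:
    matrix = cio.read_matrix(_require(inputs, "matrix"), scale=cio.LINEAR)
    sets = cio.read_signed_sets(_require(inputs, "sets"))
    groups_df = pd.read_csv(_require(inputs, "groups"), sep="\t")
    labels = pd.Series(groups_df["group"].astype(str).to_numpy(),
                       index=groups_df["sample_id"].astype(str).to_numpy())

    warnings: list[str] = []
    filtered = filter_species(matrix, keep="human")
    dropped = set(matrix.analyte_ids) - set(filtered.analyte_ids)
    if dropped:
        warnings.append(f"species filter removed {len(dropped)} analyte(s): {sorted(dropped)}")
    normalized = median_center_bidirectional(log2_transform(filtered))
    cio.write_matrix(normalized, out / "normalized.tsv")

    pas_rows = []
    cmp_rows = []
    for s in sets:
        res = compute_pas(normalized, s, missing_policy="skip")
        for sample, score in res.scores.items():
            pas_rows.append({"sample": sample, "pathway": s.name, "score": score})
        comparison = compare_groups(res.scores, labels, alpha=config.alpha)
        cmp_rows.append({
            "pathway": s.name, "test_used": comparison.test_used,
            "statistic": comparison.statistic, "p_value": comparison.p_value,
            **{f"normality_p_{g}": p for g, p in comparison.normality_p.items()},
        })
    pd.DataFrame(pas_rows).to_csv(out / "pas.tsv", sep="\t", index=False)
    pd.DataFrame(cmp_rows).to_csv(out / "comparison.tsv", sep="\t", index=False)
    return PipelineReport(
        "pdx_molecular", config.seed, {"alpha": config.alpha},
        {k: str(v) for k, v in inputs.items()},
        {"normalized": str(out / "normalized.tsv"), "pas": str(out / "pas.tsv"),
         "comparison": str(out / "comparison.tsv")},
        warnings,
    )


def _track_paired_delta(config: RunConfig, inputs: dict, out: Path) -> PipelineReport:
    pre = cio.read_matrix(_require(inputs, "pre"), scale=cio.LOG2)
    post = cio.read_matrix(_require(inputs, "post"), scale=cio.LOG2)
    sets = cio.read_signed_sets(_require(inputs, "sets"))
    pairs_df = pd.read_csv(_require(inputs, "pairing"), sep="\t")
    pairing = {str(r.patient): (str(r.pre_sample), str(r.post_sample))
               for r in pairs_df.itertuples()}

    warnings: list[str] = []
    delta_rows = []
    deltas = {}
    for s in sets:
        res = delta_pas(pre, post, pairing, s, missing_policy="skip")
        deltas[s.name] = res
        if res.excluded_pre or res.excluded_post:
            warnings.append(f"{s.name}: unpaired samples excluded — "
                            f"pre {res.excluded_pre}, post {res.excluded_post}")
        for p in res.delta.index:
            delta_rows.append({"patient": p, "pathway": s.name,
                               "delta": res.delta[p], "direction": res.direction[p]})
    pd.DataFrame(delta_rows).to_csv(out / "delta.tsv", sep="\t", index=False)
    outputs = {"delta": str(out / "delta.tsv")}

    names = [s.name for s in sets]
    if len(names) >= 2:
        corr_rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r, p, n = correlate_deltas(deltas[names[i]], deltas[names[j]])
                corr_rows.append({"pathway_a": names[i], "pathway_b": names[j],
                                  "pearson_r": r, "p_value": p, "n": n})
        pd.DataFrame(corr_rows).to_csv(out / "correlation.tsv", sep="\t", index=False)
        outputs["correlation"] = str(out / "correlation.tsv")
    return PipelineReport("paired_delta", config.seed, {}, {k: str(v) for k, v in inputs.items()},
                          outputs, warnings)


def _track_survival_strat(config: RunConfig, inputs: dict, out: Path) -> PipelineReport:
    matrix = cio.read_matrix(_require(inputs, "matrix"), scale=cio.LOG2)
    cohort = cio.read_survival_table(_require(inputs, "survival"))
    genes = inputs.get("genes")
    if genes is None:
        raise InvariantError("track input 'genes' not provided (comma-separated panel)")
    gene_list = [g.strip() for g in str(genes).split(",") if g.strip()]

    rule = StratificationRule(gene_list, q=config.quantile_q)
    labels = stratify(matrix, rule)
    shared = [s for s in cohort.records["sample_id"] if s in labels.index]
    warnings = []
    if len(shared) < cohort.n:
        missing = sorted(set(cohort.records["sample_id"]) - set(shared))
        warnings.append(f"survival records without expression dropped: {missing}")
    cohort = cohort.__class__(
        cohort.records[cohort.records["sample_id"].isin(shared)].reset_index(drop=True),
        group=labels[shared],
    )
    pd.DataFrame({"sample_id": labels.index, "group": labels.to_numpy()}).to_csv(
        out / "stratification.tsv", sep="\t", index=False)

    curves = km_fit(cohort)
    km_rows = []
    for g, c in sorted(curves.items()):
        for t, s_val, r in zip(c.event_times, c.survival, c.at_risk):
            km_rows.append({"group": g, "time": t, "survival": s_val, "at_risk": r})
    pd.DataFrame(km_rows).to_csv(out / "km.tsv", sep="\t", index=False)

    result = logrank_test(cohort, group_order=("Low", "High"))
    medians = {g: km_median(c) for g, c in curves.items()}
    summary = pd.DataFrame([{
        "n_high": int((cohort.group == "High").sum()),
        "n_low": int((cohort.group == "Low").sum()),
        "median_high": medians.get("High"),
        "median_low": medians.get("Low"),
        "chi_square": result.chi_square,
        "p_value": result.p_value,
        "hazard_ratio_high_vs_low": result.hazard_ratio,
    }])
    summary.to_csv(out / "logrank.tsv", sep="\t", index=False, na_rep="NA")
    return PipelineReport(
        "survival_strat", config.seed,
        {"quantile_q": config.quantile_q, "genes": gene_list},
        {k: str(v) for k, v in inputs.items()},
        {"stratification": str(out / "stratification.tsv"), "km": str(out / "km.tsv"),
         "logrank": str(out / "logrank.tsv")},
        warnings,
    )


def _track_growth(config: RunConfig, inputs: dict, out: Path) -> PipelineReport:
    series = cio.read_growth_table(_require(inputs, "growth"))
    control_arm = str(inputs.get("control_arm", "control"))
    end_day = int(inputs.get("end_day", max(int(s.days.max()) for s in series)))

    included, excluded = partition_by_inclusion(series, config.auc_inclusion_window)
    warnings = [f"excluded by inclusion window {config.auc_inclusion_window}: "
                f"{[s.animal_id for s in excluded]}"] if excluded else []
    controls = [s for s in included if s.arm == control_arm]
    treated = [s for s in included if s.arm != control_arm]
    result = relative_auc(treated, controls, end_day)
    result.per_tumor.to_csv(out / "per_tumor.tsv", sep="\t", index=False)
    result.arm_summary.to_csv(out / "arm_summary.tsv", sep="\t", index=False, na_rep="NA")
    return PipelineReport(
        "growth", config.seed,
        {"end_day": end_day, "control_arm": control_arm,
         "inclusion_window": list(config.auc_inclusion_window)},
        {k: str(v) for k, v in inputs.items()},
        {"per_tumor": str(out / "per_tumor.tsv"), "arm_summary": str(out / "arm_summary.tsv")},
        warnings,
    )


def _track_hubs(config: RunConfig, inputs: dict, out: Path) -> PipelineReport:
    edges = cio.read_edge_list(_require(inputs, "edges"))
    if "deg" in inputs:
        degs = cio.read_deg_table(_require(inputs, "deg"))
        genes = select_top_deg(degs, n=config.top_n_deg, padj_max=config.alpha)
    elif "genes" in inputs:
        genes = pd.read_csv(_require(inputs, "genes"), sep="\t")["gene"].astype(str).tolist()
    else:
        raise InvariantError("hubs track needs either a 'deg' table or a 'genes' list input")
    net = extract_hubs(edges, genes, conf_min=config.edge_confidence_min,
                       min_degree_exclusive=config.hub_min_degree)
    nodes = pd.DataFrame({
        "gene": sorted(net.degrees),
        "degree": [net.degrees[g] for g in sorted(net.degrees)],
    })
    nodes["retained"] = nodes["gene"].isin(net.retained)
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    net.edges.to_csv(out / "hub_edges.tsv", sep="\t", index=False)
    return PipelineReport(
        "hubs", config.seed,
        {"conf_min": config.edge_confidence_min, "min_degree": config.hub_min_degree,
         "top_n_deg": config.top_n_deg},
        {k: str(v) for k, v in inputs.items()},
        {"nodes": str(out / "nodes.tsv"), "hub_edges": str(out / "hub_edges.tsv")},
    )


_TRACK_FUNCS = {
    "pdx_molecular": _track_pdx_molecular,
    "paired_delta": _track_paired_delta,
    "survival_strat": _track_survival_strat,
    "growth": _track_growth,
    "hubs": _track_hubs,
}


def run_track(track: str, config: RunConfig, inputs: dict,
              out_dir: str | Path) -> PipelineReport:
    """Execute one analysis track; any stage error aborts with the track name.

    ``inputs`` maps input roles (e.g. ``matrix``, ``survival``) to file
    paths plus scalar options (``genes``, ``end_day``...). All
    intermediates are written under ``out_dir`` along with a
    ``report.json``.
    """
    if track == "simulate":
        report = simulate_to_files(str(inputs.get("kind", "rppa")), config, out_dir)
    else:
        if track not in _TRACK_FUNCS:
            raise InvariantError(f"unknown track {track!r}; expected one of {TRACKS}")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            report = _TRACK_FUNCS[track](config, inputs, out)
        except Exception as exc:
            raise InvariantError(f"track {track!r} failed: {exc}") from exc
    report.write(Path(out_dir) / "report.json")
    report.outputs["report"] = str(Path(out_dir) / "report.json")
    return report
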