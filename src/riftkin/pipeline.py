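"""End-to-end orchestration: preprocess -> fit -> summarize -> operons
-> probes -> cluster, with a reproducibility manifest.

Every stage writes a TSV under the output directory; the manifest
records the effective configuration, input digests, per-stage row
counts and output digests, so two runs with the same seed and inputs
are byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from riftkin.cluster import ClusterConfig, enrichment_test, fuzzy_cmeans, standardize_profiles
from riftkin.decay import estimate_all, format_capped, summarize_decay
from riftkin.io_preprocess import (
    PipelineConfig, collapse_replicates, filter_low_expression,
    read_annotation, read_expression, scale_matrix,
)
from riftkin.operons import classify_all_operons, distance_to_operon_start, \
    correlate_position_stability, validate_operons
from riftkin.probes import probe_decay_fits, select_probe_genes, velocity_summary

__all__ = ["run_pipeline", "make_report", "file_digest"]

_version = "0.1.0"


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(expression_path, out_dir, *,
                 config: Optional[PipelineConfig] = None,
                 annotation_path=None, probes_path=None,
                 cluster_config: Optional[ClusterConfig] = None,
                 n_clusters: Optional[int] = 12,
                 timestamps: bool = True) -> dict:
    """Run all stages on an expression table; returns the manifest dict.

    Stages needing the annotation or probe tables are skipped with a
    warning entry when those inputs are absent; a failing stage is
    isolated and recorded rather than aborting the rest.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": _version,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": {},
        "warnings": [],
    }
    if timestamps:
        manifest["started"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    manifest["inputs"]["expression"] = file_digest(expression_path)

    # preprocess
    series = read_expression(expression_path)
    series = scale_matrix(series, config.scaling_scheme, config.reference_ids)
    kept, excluded = filter_low_expression(series, config.expression_threshold)
    n_kept = kept.index.get_level_values("gene_id").nunique()
    manifest["stages"]["preprocess"] = {
        "n_genes_kept": int(n_kept),
        "n_genes_excluded": int(excluded.index.get_level_values("gene_id").nunique()),
    }

    # fit
    estimates = estimate_all(kept, config)
    _write(estimates, out / "decay.tsv")
    manifest["stages"]["fit"] = {"n_rows": int(len(estimates))}

    # summarize
    summary = summarize_decay(estimates, config)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest["stages"]["summarize"] = summary

    annotation = None
    if annotation_path is not None:
        manifest["inputs"]["annotation"] = file_digest(annotation_path)
        annotation = read_annotation(annotation_path)

    # operons
    if annotation is not None and (annotation["operon_id"] != "").any():
        try:
            records = validate_operons(annotation, kept, config)
            calls = classify_all_operons(records, kept, config.operon_rise_threshold)
            _write(calls, out / "operons.tsv")
            op_genes = annotation.index[annotation["operon_id"] != ""]
            dists = pd.Series(
                {g: distance_to_operon_start(annotation, g)[0] for g in op_genes})
            corr = {}
            for metric in ("half_life", "decay_rate"):
                try:
                    c = correlate_position_stability(estimates, dists, metric)
                    corr[metric] = {"r": c.r, "p": c.p, "p_text": c.p_text, "n": c.n}
                except ValueError as e:
                    corr[metric] = {"error": str(e)}
            manifest["stages"]["operons"] = {
                "n_operons": int(len(calls)),
                "n_retained": int(calls["retained"].sum()),
                "n_type_I": int((calls["type"] == "I").sum()),
                "n_type_II": int((calls["type"] == "II").sum()),
                "exclusions": calls.loc[~calls["retained"], "reason"]
                    .value_counts().to_dict(),
                "position_stability": corr,
            }
        except Exception as e:  # isolate the stage
            manifest["warnings"].append(f"operons stage failed: {e}")
    else:
        manifest["warnings"].append("operons stage skipped: no annotation/operons")

    # probes
    if probes_path is not None and annotation is not None:
        manifest["inputs"]["probes"] = file_digest(probes_path)
        try:
            probe_table, probe_series = read_probe_table(probes_path)
            eligible = set(select_probe_genes(annotation))
            probe_table = probe_table[probe_table["gene_id"].isin(eligible)]
            probe_series = probe_series.loc[
                probe_series.index.get_level_values(0).isin(probe_table["probe_id"])]
            fits = probe_decay_fits(probe_series, probe_table, config)
            _write(fits, out / "probe_fits.tsv")
            vel = velocity_summary(fits)
            with open(out / "velocity.json", "w") as fh:
                json.dump(vel, fh, indent=2, sort_keys=True)
            manifest["stages"]["probes"] = vel
        except Exception as e:
            manifest["warnings"].append(f"probes stage failed: {e}")
    else:
        manifest["warnings"].append("probes stage skipped: no probe table")

    # cluster
    try:
        mean, _ = collapse_replicates(kept)
        profiles, dropped = standardize_profiles(np.log2(mean))
        ccfg = cluster_config or ClusterConfig(seed=config.seed)
        c = n_clusters if n_clusters is not None else ccfg.candidates[0]
        asg = fuzzy_cmeans(profiles, c, ccfg)
        clusters = asg.to_frame()
        _write(clusters, out / "clusters.tsv")
        stage = {"n_clusters": int(c), "n_profiles": int(len(profiles)),
                 "n_constant_dropped": len(dropped)}
        if annotation is not None and "category" in annotation.columns:
            cats = annotation["category"].reindex(profiles.index).dropna()
            enr = enrichment_test(asg, cats, alpha=ccfg.alpha)
            _write(enr, out / "enrichment.tsv")
            stage["n_enriched_pairs"] = int(enr["significant"].sum())
        manifest["stages"]["cluster"] = stage
    except Exception as e:
        manifest["warnings"].append(f"cluster stage failed: {e}")

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if f.name == "manifest.json":
            continue
        manifest["outputs"][f.name] = file_digest(f)
    if timestamps:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_probe_table(path):
    """Read the probe TSV (probe_id, gene_id, position_nt + time columns)."""
    from riftkin.design import parse_time_column

    df = pd.read_csv(path, sep="\t")
    for col in ("probe_id", "gene_id", "position_nt", "replicate"):
        if col not in df.columns:
            raise ValueError(f"probe table is missing column {col!r}")
    probe_table = df[["probe_id", "gene_id", "position_nt"]].drop_duplicates("probe_id")
    time_cols = [c for c in df.columns if c.startswith("t") and c != "replicate"]
    series = df[["probe_id", "replicate"] + time_cols].set_index(["probe_id", "replicate"])
    series.columns = [parse_time_column(c) for c in series.columns]
    return probe_table, series


def make_report(out_dir, expression_path=None, max_panels: int = 12) -> Path:
    """Human-readable run report: summary text plus t0-normalized panels.

    Numbers are re-read from the stage outputs (the report never
    recomputes), and decay rates above the reporting cap are rendered
    with the ``>cap`` convention.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    cap = manifest["config"]["decay_rate_report_cap"]
    lines = ["riftkin run report", "=" * 40]
    summ = manifest["stages"].get("summarize", {})
    if summ:
        lines += [
            f"genes analysed:        {summ['n_genes']}",
            f"median half-life:      {summ['median_half_life_min']:.1f} min",
            f"median decay rate:     {format_capped(summ['median_decay_rate_min'], cap)} min",
            f"80% of half-lives in:  {summ['half_life_p10_min']:.1f}"
            f"-{summ['half_life_p90_min']:.1f} min",
            f"stable fraction:       {100 * summ['fraction_stable']:.1f}%",
        ]
    ops = manifest["stages"].get("operons")
    if ops:
        lines += [
            f"operons retained:      {ops['n_retained']}/{ops['n_operons']}"
            f" (type I {ops['n_type_I']}, type II {ops['n_type_II']})",
        ]
        ps = ops.get("position_stability", {}).get("half_life")
        if ps and "r" in ps:
            lines.append(f"distance vs half-life: Spearman r = {ps['r']:.2f},"
                         f" P {ps['p_text']} (n = {ps['n']})")
    vel = manifest["stages"].get("probes")
    if vel:
        for metric, s in vel.items():
            if s.get("n_pairs"):
                lines.append(
                    f"polymerase velocity ({metric}): mean "
                    f"{s['mean_nt_per_s']:.1f} +/- {s['se_nt_per_s']:.1f}, median "
                    f"{s['median_nt_per_s']:.1f} nt/s ({s['n_pairs']} pairs)")
    for w in manifest.get("warnings", []):
        lines.append(f"warning: {w}")
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")

    if expression_path is not None:
        series = read_expression(expression_path)
        mean, _ = collapse_replicates(series)
        norm = mean.div(mean[mean.columns[0]], axis=0).head(max_panels)
        n = len(norm)
        if n:
            ncols = min(4, n)
            nrows = (n + ncols - 1) // ncols
            fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                                     squeeze=False)
            t = np.asarray(norm.columns, dtype=float)
            for ax, (gid, row) in zip(axes.ravel(), norm.iterrows()):
                ax.plot(t, row.to_numpy(), "o-", ms=3)
                ax.axhline(1.0, color="grey", lw=0.5)
                ax.set_title(str(gid), fontsize=8)
            for ax in axes.ravel()[n:]:
                ax.axis("off")
            fig.suptitle("decay profiles (normalized to t0)")
            fig.tight_layout()
            fig.savefig(out / "profiles.png", dpi=100)
            plt.close(fig)
    return report
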