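"""Reading, filtering, scaling and qPCR handling for chase experiments.

In-memory convention: an expression collection is a pandas DataFrame
whose rows are a (gene_id, replicate) MultiIndex and whose columns are
the chase timepoints as float minutes.  On disk the same data is a TSV
with columns ``gene_id, replicate, t0, t2.5, ...``; a GEO series-matrix
file (recognized by its ``!series_matrix_table_begin`` sentinel) is
accepted as an alternative input dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from riftkin.design import ChaseDesign, format_time_column, parse_time_column

__all__ = [
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "write_geo_series_matrix",
    "read_qpcr",
    "filter_low_expression",
    "scale_matrix",
    "collapse_replicates",
    "qpcr_relative_expression",
    "qpcr_series",
    "concordance_score",
]

SCALING_SCHEMES = ("none", "all_genes_median", "spike_median", "rna_gene_median")

ANNOTATION_COLUMNS = [
    "gene_id", "start", "end", "strand", "length_nt", "category",
    "operon_id", "operon_position", "dist_to_operon_start_nt",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    ``expression_threshold`` is the minimum mean t = 0 signal for a gene
    to enter the genome-wide analysis (the array intensity floor below
    which decay fits are unreliable).  ``stability_cutoff_min`` flags
    transcripts whose half-life exceeds the chase horizon as stable.
    ``decay_rate_report_cap`` is the reporting cap: rates above it are
    rendered ``>cap`` in summary tables.
    """

    expression_threshold: float = 100.0
    scaling_scheme: str = "none"
    reference_ids: tuple = ()
    stability_cutoff_min: float = 60.0
    decay_rate_report_cap: float = 20.0
    probe_t0_threshold: float = 100.0
    min_unmasked_points: int = 4
    operon_rho_min: float = 0.7
    operon_rise_threshold: float = 0.2
    qpcr_reference_gene: str = "rnpB"
    seed: int = 0

    def __post_init__(self):
        if self.expression_threshold < 0:
            raise ValueError("expression_threshold must be >= 0")
        if self.stability_cutoff_min <= 0 or self.decay_rate_report_cap <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.scaling_scheme not in SCALING_SCHEMES:
            raise ValueError(f"unknown scaling scheme {self.scaling_scheme!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("_comment", None)
        if "reference_ids" in data and data["reference_ids"] is not None:
            data["reference_ids"] = tuple(data["reference_ids"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["reference_ids"] = list(d["reference_ids"])
        return d


# ---------------------------------------------------------------------------
# readers / writers


def write_expression(series: pd.DataFrame, path, design: Optional[ChaseDesign] = None):
    """Write a collection to the TSV dialect (gene_id, replicate, t...)."""
    wide = series.copy()
    wide.columns = [format_time_column(float(t)) for t in wide.columns]
    wide.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _finish_collection(frame: pd.DataFrame) -> pd.DataFrame:
    times = [parse_time_column(c) for c in frame.columns]
    order = np.argsort(times)
    frame = frame.iloc[:, order]
    frame.columns = [times[i] for i in order]
    if frame.isna().all(axis=None):
        raise ValueError("expression table contains no numeric signal")
    return frame


def read_expression(path) -> pd.DataFrame:
    """Read an expression table (fixture TSV or GEO series-matrix).

    Returns the (gene_id, replicate) x timepoint collection.  Raises
    ``ValueError`` on missing id/time columns or non-numeric signal.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096)
    if "!series_matrix_table_begin" in head or head.startswith("!"):
        return _read_geo_series_matrix(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "replicate"):
        if col not in df.columns:
            raise ValueError(f"expression table is missing column {col!r}")
    time_cols = [c for c in df.columns if c.startswith("t") and c != "replicate"]
    parsed = {}
    for c in time_cols:
        try:
            parsed[c] = parse_time_column(c)
        except ValueError:
            continue
    if len(parsed) < 2:
        raise ValueError("expression table has fewer than two time columns")
    sub = df[["gene_id", "replicate"] + list(parsed)].copy()
    for c in parsed:
        sub[c] = pd.to_numeric(sub[c], errors="raise")
    sub = sub.set_index(["gene_id", "replicate"])
    # all replicates of a gene must cover the same timepoints
    counts = sub.groupby(level="gene_id").size()
    if counts.nunique() > 1:
        raise ValueError("inconsistent replicate counts across genes")
    return _finish_collection(sub)


def _read_geo_series_matrix(path) -> pd.DataFrame:
    """Parse a GEO series-matrix file into the collection layout.

    Sample time/replicate assignment comes from
    ``!Sample_characteristics_ch1`` entries of the form ``time: <min>``
    and ``replicate: <n>``, with a fallback to ``!Sample_title`` strings
    containing ``t<min>`` and ``rep<n>`` tokens.
    """
    import re

    titles, char_lines = [], []
    table_lines = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_title"):
                titles = [t.strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!Sample_characteristics_ch1"):
                char_lines.append([t.strip('"') for t in line.split("\t")[1:]])
    if not table_lines:
        raise ValueError("no series-matrix table found")
    from io import StringIO
    tab = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
    tab = tab.rename(columns={tab.columns[0]: "gene_id"})
    tab["gene_id"] = tab["gene_id"].astype(str).str.strip('"')
    n_samples = tab.shape[1] - 1

    times = [None] * n_samples
    reps = [None] * n_samples
    for chars in char_lines:
        for i, c in enumerate(chars[:n_samples]):
            m = re.match(r"time(?: \(min\))?\s*:\s*([0-9.]+)", c)
            if m:
                times[i] = float(m.group(1))
            m = re.match(r"replicate\s*:\s*([0-9]+)", c)
            if m:
                reps[i] = int(m.group(1))
    for i in range(n_samples):
        if (times[i] is None or reps[i] is None) and i < len(titles):
            m = re.search(r"rep(\d+)[_ ]t([0-9.]+)", titles[i])
            if m:
                reps[i] = int(m.group(1))
                times[i] = float(m.group(2))
    if any(t is None for t in times) or any(r is None for r in reps):
        raise ValueError("could not assign time/replicate to every GEO sample")

    long = []
    for i, col in enumerate(tab.columns[1:]):
        part = pd.DataFrame({
            "gene_id": tab["gene_id"],
            "replicate": reps[i],
            "time": times[i],
            "signal": pd.to_numeric(tab[col], errors="raise"),
        })
        long.append(part)
    long = pd.concat(long)
    pivot = long.pivot_table(index=["gene_id", "replicate"], columns="time",
                             values="signal", sort=True)
    pivot.columns = [float(c) for c in pivot.columns]
    pivot.columns.name = None
    return pivot.sort_index()


def write_geo_series_matrix(series: pd.DataFrame, path, accession: str = "GSE0"):
    """Write a collection as a minimal GEO series-matrix file.

    One sample per (replicate, timepoint) array with
    ``!Sample_characteristics_ch1`` time/replicate fields; used to test
    the benchmark input path without network access.
    """
    reps = sorted(series.index.get_level_values("replicate").unique())
    times = list(series.columns)
    samples = [(r, t) for r in reps for t in times]
    genes = series.index.get_level_values("gene_id").unique()
    with open(path, "w") as fh:
        fh.write(f"!Series_geo_accession\t\"{accession}\"\n")
        fh.write("!Sample_title\t" + "\t".join(
            f"\"rep{r}_t{t:g}\"" for r, t in samples) + "\n")
        fh.write("!Sample_characteristics_ch1\t" + "\t".join(
            f"\"time: {t:g}\"" for r, t in samples) + "\n")
        fh.write("!Sample_characteristics_ch1\t" + "\t".join(
            f"\"replicate: {r}\"" for r, t in samples) + "\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("ID_REF\t" + "\t".join(f"GSM{i + 1}" for i in range(len(samples))) + "\n")
        for g in genes:
            vals = [repr(float(series.at[(g, r), t])) for r, t in samples]
            fh.write(f"\"{g}\"\t" + "\t".join(vals) + "\n")
        fh.write("!series_matrix_table_end\n")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"operon_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns {missing}")
    df["operon_id"] = df["operon_id"].fillna("")
    return df.set_index("gene_id")


def write_annotation(annotation: pd.DataFrame, path):
    annotation.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qpcr(path) -> pd.DataFrame:
    """Read a qPCR Ct table: columns gene_id, t<min>... holding mean Ct."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("qPCR table is missing column 'gene_id'")
    df = df.set_index("gene_id")
    df.columns = [parse_time_column(c) for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# preprocessing


def filter_low_expression(series: pd.DataFrame, threshold: float):
    """Partition genes by mean replicate signal at t = 0 (kept iff >= threshold)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t0 = series.columns[0]
    means = series[t0].groupby(level="gene_id").mean()
    kept_ids = means.index[means >= threshold]
    excl_ids = means.index[means < threshold]
    kept = series.loc[series.index.get_level_values("gene_id").isin(kept_ids)]
    excluded = series.loc[series.index.get_level_values("gene_id").isin(excl_ids)]
    return kept, excluded


def scale_matrix(series: pd.DataFrame, scheme: str,
                 reference_ids: Sequence[str] = ()) -> pd.DataFrame:
    """Per-array median scaling.

    Every array (one replicate at one timepoint) is multiplied by a
    single constant so that the median signal of the reference set (all
    genes, spike controls, or designated stable RNA genes) is the same
    across arrays, equal to the grand median of the per-array reference
    medians.  ``none`` is the identity.
    """
    if scheme not in SCALING_SCHEMES:
        raise ValueError(f"unknown scaling scheme {scheme!r}")
    if scheme == "none":
        return series.copy()
    if scheme == "all_genes_median":
        ref = series
    else:
        reference_ids = list(reference_ids)
        if not reference_ids:
            raise ValueError(f"scheme {scheme!r} needs a non-empty reference set")
        mask = series.index.get_level_values("gene_id").isin(reference_ids)
        if not mask.any():
            raise ValueError("no reference ids present in the collection")
        ref = series.loc[mask]

    out = series.copy()
    # arrays are (replicate, timepoint) pairs
    replicates = series.index.get_level_values("replicate").unique()
    medians = {}
    for r in replicates:
        sub = ref.xs(r, level="replicate")
        for t in series.columns:
            medians[(r, t)] = float(sub[t].median())
    target = float(np.median(list(medians.values())))
    for r in replicates:
        idx = out.index.get_level_values("replicate") == r
        for t in series.columns:
            out.loc[idx, t] = out.loc[idx, t] * (target / medians[(r, t)])
    return out


def collapse_replicates(series: pd.DataFrame):
    """Mean over replicates per timepoint, plus the standard error.

    Masked (NaN) values are ignored; a timepoint with every replicate
    masked raises.  Returns ``(mean_frame, se_frame)`` indexed by
    gene_id.
    """
    g = series.groupby(level="gene_id", sort=False)
    mean = g.mean()
    if mean.isna().any(axis=None):
        bad = mean.index[mean.isna().any(axis=1)][0]
        raise ValueError(f"all replicates masked at some timepoint for {bad!r}")
    n = g.count()
    sd = g.std(ddof=1)
    se = sd / np.sqrt(n)
    return mean, se


# ---------------------------------------------------------------------------
# qPCR


def qpcr_relative_expression(qpcr: pd.DataFrame, gene: str, timepoint: float,
                             reference: str = "rnpB") -> float:
    """Relative quantity 2^-(dCt_gene - dCt_ref) at one timepoint."""
    if reference not in qpcr.index:
        raise ValueError(f"reference gene {reference!r} missing from qPCR table")
    if timepoint not in qpcr.columns:
        raise ValueError(f"timepoint {timepoint} missing from qPCR table")
    dct_g = qpcr.at[gene, timepoint]
    dct_r = qpcr.at[reference, timepoint]
    if pd.isna(dct_r):
        raise ValueError(f"reference gene not measured at t={timepoint}")
    return float(2.0 ** (-(dct_g - dct_r)))


def qpcr_series(qpcr: pd.DataFrame, gene: str, reference: str = "rnpB") -> pd.Series:
    """Per-timepoint relative expression of one gene (eligible for decay fits)."""
    vals = {t: qpcr_relative_expression(qpcr, gene, t, reference) for t in qpcr.columns}
    return pd.Series(vals, name=gene)


# ---------------------------------------------------------------------------
# concordance


def concordance_score(array_profiles: pd.DataFrame, qpcr_profiles: pd.DataFrame,
                      gene_set: Iterable[str]) -> float:
    """Mean per-gene Spearman correlation between array and qPCR profiles.

    Profiles are matched on shared timepoints (at least 3 required).
    Used to rank scaling schemes: higher means the array tracks the
    qPCR standard better.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set must be non-empty")
    shared = [t for t in array_profiles.columns if t in qpcr_profiles.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared timepoints")
    rs = []
    for g in genes:
        a = array_profiles.loc[g, shared].to_numpy(dtype=float)
        b = qpcr_profiles.loc[g, shared].to_numpy(dtype=float)
        rs.append(stats.spearmanr(a, b).statistic)
    return float(np.mean(rs))
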