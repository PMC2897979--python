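"""Seeded synthetic rifampicin-chase data with known kinetic ground truth.

The generative model per transcript is a continuous piecewise curve:
an optional linear ramp (delayed decay onset, with or without a
transient rise), a first exponential decay phase, and a second decay
phase joined continuously at a phase break.  Replicate measurements add
multiplicative log-normal noise and are hard-clipped at a saturation
cap.  Operon fixtures impose a 5'->3' wave: genes further from the
transcriptional start decay later and more slowly; probe-level fixtures
do the same within a single long gene.

Every fixture is deterministic given a seed.  Gene streams are split
from the base seed by stable hashing of the gene id, so adding genes to
a fixture does not perturb the draws of existing genes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from riftkin.design import ChaseDesign, format_time_column

__all__ = [
    "TrueKinetics",
    "GroundTruthTable",
    "noiseless_signal",
    "simulate_gene",
    "simulate_operon",
    "simulate_probe_level",
    "simulate_genome",
    "velocity_fixture",
    "write_fixture",
    "gene_rng",
]

TRUTH_COLUMNS = [
    "gene_id", "E0", "onset_delay", "fast_half_life", "slow_half_life",
    "phase_break", "rise_amplitude", "operon_id", "operon_position",
    "distance_from_operon_start", "gene_length",
]


@dataclass(frozen=True)
class TrueKinetics:
    """True kinetic parameters of one transcript (or probe) in a fixture.

    ``onset_delay`` is the lag (min) before decay begins; during the lag
    the signal either stays flat (``rise_amplitude`` = 0) or ramps
    linearly to ``(1 + rise_amplitude) * E0``.  Decay then proceeds with
    half-life ``fast_half_life`` until ``phase_break`` and continues
    with ``slow_half_life`` afterwards; the curve is continuous
    throughout.
    """

    gene_id: str
    E0: float
    onset_delay: float = 0.0
    fast_half_life: float = 2.4
    slow_half_life: float = 2.4
    phase_break: float = 30.0
    rise_amplitude: float = 0.0
    operon_id: Optional[str] = None
    operon_position: int = 1
    distance_from_operon_start: float = 0.0
    gene_length: int = 900

    def __post_init__(self):
        if not self.E0 > 0:
            raise ValueError("E0 must be > 0")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        if not 0 < self.fast_half_life <= self.slow_half_life:
            raise ValueError("need 0 < fast_half_life <= slow_half_life")
        if not self.phase_break > self.onset_delay:
            raise ValueError("phase_break must exceed onset_delay")
        if self.rise_amplitude < 0:
            raise ValueError("rise_amplitude must be >= 0")


@dataclass
class GroundTruthTable:
    """Per-gene true kinetics of a fixture plus the design that produced it."""

    kinetics: list
    design: ChaseDesign

    def __post_init__(self):
        ids = [k.gene_id for k in self.kinetics]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids in a ground-truth table must be unique")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.kinetics:
            d = asdict(k)
            rows.append({
                "gene_id": d["gene_id"],
                "E0": d["E0"],
                "onset_delay": d["onset_delay"],
                "fast_half_life": d["fast_half_life"],
                "slow_half_life": d["slow_half_life"],
                "phase_break": d["phase_break"],
                "rise_amplitude": d["rise_amplitude"],
                "operon_id": d["operon_id"] or "",
                "operon_position": d["operon_position"],
                "distance_from_operon_start": d["distance_from_operon_start"],
                "gene_length": d["gene_length"],
            })
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    def __len__(self):
        return len(self.kinetics)

    def __getitem__(self, gene_id: str) -> TrueKinetics:
        for k in self.kinetics:
            if k.gene_id == gene_id:
                return k
        raise KeyError(gene_id)


def noiseless_signal(k: TrueKinetics, t) -> np.ndarray:
    """Evaluate the continuous piecewise decay curve at times ``t`` (min)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    d, b = k.onset_delay, k.phase_break
    peak = k.E0 * (1.0 + k.rise_amplitude)
    out = np.empty(t.shape, dtype=float)

    ramp = t < d
    if d > 0:
        out[ramp] = k.E0 * (1.0 + k.rise_amplitude * t[ramp] / d)
    phase1 = (t >= d) & (t < b)
    out[phase1] = peak * 2.0 ** (-(t[phase1] - d) / k.fast_half_life)
    phase2 = t >= b
    at_break = peak * 2.0 ** (-(b - d) / k.fast_half_life)
    out[phase2] = at_break * 2.0 ** (-(t[phase2] - b) / k.slow_half_life)
    return out


def _stable_hash(gene_id: str) -> int:
    return int.from_bytes(hashlib.blake2b(gene_id.encode(), digest_size=8).digest(), "big")


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene random stream split from the fixture seed by id hashing."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _stable_hash(gene_id)]))


def simulate_gene(k: TrueKinetics, design: ChaseDesign,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate one gene's replicate series on the design grid.

    Returns a DataFrame indexed by replicate (1-based) with the design's
    timepoints (float minutes) as columns.  Noise is multiplicative
    log-normal; values are clipped at the design's saturation cap.
    """
    if rng is None:
        rng = gene_rng(design.seed, k.gene_id)
    clean = noiseless_signal(k, design.times)
    rows = []
    for _ in range(design.replicates):
        if design.noise_sigma > 0:
            eps = rng.normal(0.0, design.noise_sigma, size=clean.shape)
            sig = clean * np.exp(eps)
        else:
            sig = clean.copy()
        rows.append(np.minimum(sig, design.saturation_cap))
    return pd.DataFrame(rows, index=pd.RangeIndex(1, design.replicates + 1, name="replicate"),
                        columns=design.times)


def _collection(kinetics: Sequence[TrueKinetics], design: ChaseDesign) -> pd.DataFrame:
    """Simulate a set of genes into one (gene_id, replicate) x time frame."""
    frames = {}
    for k in kinetics:
        frames[k.gene_id] = simulate_gene(k, design)
    out = pd.concat(frames, names=["gene_id", "replicate"])
    out.columns = design.times
    return out


def simulate_operon(n_genes: int, spacing_nt: float, velocity_nt_per_s: float,
                    profile_type: str, design: ChaseDesign, *,
                    base_half_life: float = 2.5,
                    stability_gain_per_kb: float = 0.3,
                    rise_max: float = 1.0,
                    base_E0: float = 500.0,
                    operon_id: str = "op1",
                    gene_length: int = 900):
    """Simulate a polycistronic transcript with a 5'->3' decay wave.

    Gene ``g`` sits ``(g-1) * spacing_nt`` downstream of the operon's
    first start codon; its decay onset is delayed by ``s / (60 v)``
    minutes and its half-life grows with distance (``stability_gain_per_kb``
    fractional increase per kb).  ``profile_type`` "I" keeps transcript
    levels flat before decay; "II" lets distal genes rise transiently, the
    amplitude growing with distance up to ``rise_max``.
    """
    if n_genes < 2:
        raise ValueError("an operon needs at least 2 genes")
    if profile_type not in ("I", "II"):
        raise ValueError("profile_type must be 'I' or 'II'")
    kin = []
    s_max = (n_genes - 1) * spacing_nt
    for g in range(1, n_genes + 1):
        s = (g - 1) * spacing_nt
        d = s / (60.0 * velocity_nt_per_s)
        h1 = base_half_life * (1.0 + stability_gain_per_kb * s / 1000.0)
        a = 0.0
        if profile_type == "II" and s_max > 0:
            a = rise_max * s / s_max
        kin.append(TrueKinetics(
            gene_id=f"{operon_id}_g{g}", E0=base_E0,
            onset_delay=d, fast_half_life=h1, slow_half_life=h1,
            phase_break=d + 4.0 * h1, rise_amplitude=a,
            operon_id=operon_id, operon_position=g,
            distance_from_operon_start=s, gene_length=gene_length,
        ))
    truth = GroundTruthTable(kin, design)
    return truth, _collection(kin, design)


def simulate_probe_level(gene_length_nt: int, base: TrueKinetics,
                         design: ChaseDesign, *,
                         probe_spacing_nt: int = 80,
                         velocity_nt_per_s: float = 5.0,
                         onset_weight: float = 1.0,
                         stability_weight: float = 1.0,
                         enforce_min_length: bool = True):
    """Simulate tiled single-probe series along one long gene.

    Probes sit at 0, ``probe_spacing_nt``, ... < ``gene_length_nt``.  The
    5'->3' degradation wave reaches position ``p`` after ``p / (60 v)``
    minutes; ``onset_weight`` routes that shift into a delayed decay
    onset and ``stability_weight`` into increased persistence (longer
    half-life), reflecting that distal transcript segments both start to
    decay later and decay more slowly.

    Returns ``(truth, series, positions)`` where ``series`` is indexed by
    (probe_id, replicate).
    """
    if enforce_min_length and gene_length_nt < 2000:
        raise ValueError("polymerase-rate fixtures require genes >= 2 kb")
    positions = np.arange(0, gene_length_nt, probe_spacing_nt)
    kin = []
    for p in positions:
        shift = p / (60.0 * velocity_nt_per_s)
        d = base.onset_delay + onset_weight * shift
        h1 = base.fast_half_life + stability_weight * shift
        h2 = max(base.slow_half_life + stability_weight * shift, h1)
        kin.append(TrueKinetics(
            gene_id=f"{base.gene_id}_p{int(p):05d}", E0=base.E0,
            onset_delay=d, fast_half_life=h1, slow_half_life=h2,
            phase_break=d + 4.0 * h1, rise_amplitude=base.rise_amplitude,
            operon_id=None, operon_position=1,
            distance_from_operon_start=float(p), gene_length=gene_length_nt,
        ))
    truth = GroundTruthTable(kin, design)
    series = _collection(kin, design)
    series.index = series.index.set_names(["probe_id", "replicate"])
    return truth, series, positions


def velocity_fixture(design: ChaseDesign, *, n_genes: int = 20,
                     velocity_nt_per_s: float = 5.0,
                     min_length: int = 2000, max_length: int = 4600,
                     probe_spacing_nt: int = 80):
    """Canonical probe-level benchmark for polymerase-velocity recovery.

    Each gene carries the 5'->3' degradation wave as a persistence
    shift: the wave reaches position ``p`` at ``p / (60 v)`` minutes, so
    the probe's measured half-life exceeds the first probe's by exactly
    that lag.  This is the grid-resolvable observable of the wave (a
    pure onset plateau is quantized to the sampling grid and is not
    identifiable by the twofold fit; see docs).  Probe and gene-level
    truth tables are merged into one truth table; returns
    ``(truth, series, probe_table, annotation)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x76656C]))
    all_kin, probe_rows, ann_rows = [], [], []
    coord = 1
    for g in range(1, n_genes + 1):
        gid = f"vg{g:03d}"
        length = int(rng.integers(min_length // 80, max_length // 80 + 1) * 80)
        h0 = float(np.exp(rng.normal(np.log(2.4), 0.3)))
        base = TrueKinetics(gene_id=gid, E0=float(2 ** rng.uniform(7, 11)),
                            onset_delay=0.0, fast_half_life=h0,
                            slow_half_life=h0, phase_break=60.0,
                            gene_length=length)
        truth, series, positions = simulate_probe_level(
            length, base, design, probe_spacing_nt=probe_spacing_nt,
            velocity_nt_per_s=velocity_nt_per_s,
            onset_weight=0.0, stability_weight=1.0)
        all_kin.extend(truth.kinetics)
        for k, p in zip(truth.kinetics, positions):
            probe_rows.append((k.gene_id, gid, float(p)))
        ann_rows.append({
            "gene_id": gid, "start": coord, "end": coord + length - 1,
            "strand": "+", "length_nt": length, "category": "unknown",
            "operon_id": "", "operon_position": 1,
            "dist_to_operon_start_nt": 0.0,
        })
        coord += length + 200
        if g == 1:
            combined = [series]
        else:
            combined.append(series)
    series = pd.concat(combined)
    probe_table = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id", "position_nt"])
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")
    truth = GroundTruthTable(all_kin, design)
    return truth, series, probe_table, annotation


_CATEGORIES = [
    "photosynthesis", "ribosomal protein", "amino acid biosynthesis",
    "cell envelope", "energy metabolism", "transport", "regulation",
    "DNA replication", "translation", "unknown",
]


def simulate_genome(design: ChaseDesign, *, n_genes: int = 1000,
                    n_operons: int = 50, n_type2: int = 9,
                    operon_sizes=(3, 6), spacing_nt: float = 1000.0,
                    velocity_nt_per_s: float = 5.0,
                    stability_gain_per_kb: float = 0.3,
                    median_half_life: float = 2.4,
                    log_half_life_sigma: float = 0.8,
                    stable_fraction: float = 0.03,
                    low_expression_fraction: float = 0.0):
    """Genome-scale fixture: monocistrons plus operons with decay waves.

    Returns ``(truth, series, annotation, categories)``.  Monocistron
    half-lives are log-normal around ``median_half_life``; a
    ``stable_fraction`` of genes get half-lives far beyond the chase
    horizon (and the "RNA gene" category, emulating rRNA/tRNA-like
    stability).  ``low_expression_fraction`` genes fall below a baseline
    signal of 100 at t = 0 so threshold filtering is exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x67656E]))
    kin, ann_rows, cats = [], [], {}
    coord = 1

    def _ann(gid, length, category, operon_id, pos, dist):
        nonlocal coord
        ann_rows.append({
            "gene_id": gid, "start": coord, "end": coord + length - 1,
            "strand": "+" if rng.random() < 0.5 else "-",
            "length_nt": length, "category": category,
            "operon_id": operon_id or "", "operon_position": pos,
            "dist_to_operon_start_nt": dist,
        })
        coord += length + 150

    # operons first: positions within an operon share a strand and run
    # consecutively so start-codon distances match the generative ones
    op_count = 0
    for o in range(1, n_operons + 1):
        size = int(rng.integers(operon_sizes[0], operon_sizes[1] + 1))
        ptype = "II" if o <= n_type2 else "I"
        base_h = float(np.exp(rng.normal(np.log(median_half_life), 0.4)))
        truth_o, _ = simulate_operon(
            size, spacing_nt, velocity_nt_per_s, ptype, design,
            base_half_life=base_h, stability_gain_per_kb=stability_gain_per_kb,
            base_E0=float(2 ** rng.uniform(7, 12)), operon_id=f"op{o:03d}",
            gene_length=int(spacing_nt * 0.85))
        strand = "+" if rng.random() < 0.5 else "-"
        op_start = coord
        for k in truth_o.kinetics:
            kin.append(k)
            cats[k.gene_id] = _CATEGORIES[o % len(_CATEGORIES)]
            length = k.gene_length
            s = k.distance_from_operon_start
            if strand == "+":
                start = op_start + int(s)
                end = start + length - 1
            else:
                end = op_start + int((size - 1) * spacing_nt) + length - 1 - int(s)
                start = end - length + 1
            ann_rows.append({
                "gene_id": k.gene_id, "start": start, "end": end,
                "strand": strand, "length_nt": length,
                "category": cats[k.gene_id], "operon_id": k.operon_id,
                "operon_position": k.operon_position,
                "dist_to_operon_start_nt": s,
            })
        coord = op_start + int((size - 1) * spacing_nt) + int(spacing_nt) + 300
        op_count += size

    n_mono = max(n_genes - op_count, 0)
    n_stable = int(round(stable_fraction * n_mono))
    n_low = int(round(low_expression_fraction * n_mono))
    for i in range(1, n_mono + 1):
        gid = f"gene{i:04d}"
        stable = i <= n_stable
        low = n_stable < i <= n_stable + n_low
        h = 400.0 if stable else float(np.exp(rng.normal(
            np.log(median_half_life), log_half_life_sigma)))
        h = max(h, 0.4)
        E0 = float(2 ** rng.uniform(2, 6)) if low else float(2 ** rng.uniform(7, 14))
        length = int(rng.integers(3, 25) * 60)
        k = TrueKinetics(gene_id=gid, E0=E0, onset_delay=0.0,
                         fast_half_life=h, slow_half_life=h,
                         phase_break=60.0, gene_length=length)
        kin.append(k)
        cats[gid] = "RNA gene" if stable else _CATEGORIES[int(rng.integers(len(_CATEGORIES)))]
        _ann(gid, length, cats[gid], None, 1, 0.0)

    truth = GroundTruthTable(kin, design)
    series = _collection(kin, design)
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")
    categories = pd.Series(cats, name="category")
    categories.index.name = "gene_id"
    return truth, series, annotation, categories


def write_fixture(directory, *, series: pd.DataFrame, design: ChaseDesign,
                  annotation: Optional[pd.DataFrame] = None,
                  truth: Optional[GroundTruthTable] = None,
                  probe_series: Optional[pd.DataFrame] = None,
                  probe_table: Optional[pd.DataFrame] = None) -> dict:
    """Write a fixture to TSV files that round-trip through the readers.

    Returns a dict of the paths written (keys: expression, annotation,
    truth, probes when applicable).
    """
    from riftkin.io_preprocess import write_expression, write_annotation

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["expression"] = directory / "expression.tsv"
    write_expression(series, paths["expression"], design)
    if annotation is not None:
        paths["annotation"] = directory / "annotation.tsv"
        write_annotation(annotation, paths["annotation"])
    if truth is not None:
        paths["truth"] = directory / "truth.tsv"
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    if probe_series is not None:
        paths["probes"] = directory / "probes.tsv"
        wide = probe_series.copy()
        wide.columns = [format_time_column(t) for t in wide.columns]
        wide = wide.reset_index()
        if probe_table is not None:
            wide = probe_table.merge(wide, on="probe_id", how="right")
        wide.to_csv(paths["probes"], sep="\t", index=False, float_format="%.10g")
    return {k: str(v) for k, v in paths.items()}
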