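"""RNA half-life and decay-rate estimation.

Two estimators are applied to each transcript's chase profile:

* **Twofold decay step** — an exponential is fit between the first
  timepoint and the earliest later timepoint showing a >= 2-fold signal
  decrease; its time-per-twofold is the half-life.  Series that never
  halve within the horizon fall back to an all-point fit (which can
  yield a negative or very large value for flat/rising profiles) and
  are flagged stable.

* **Relative two-phase decay model** — decline is measured relative to
  the last timepoint of maximal expression (the decay onset), and two
  successive exponentials are fit with the breakpoint chosen over all
  admissible sampled timepoints to minimize the pooled mean squared
  error of the log2 data.  The reported decay rate is the first
  phase's time-per-twofold, so delayed-onset transcripts get a decay
  rate that reflects degradation speed rather than onset lag.

All fits are ordinary least squares of log2 signal on time; with two
points the fit is exact.  Signals must be positive (mask non-positive
values upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from riftkin.io_preprocess import PipelineConfig, collapse_replicates

__all__ = [
    "SegmentFit",
    "TwoPhaseFit",
    "DecayModel",
    "DecayResults",
    "fit_exponential_segment",
    "twofold_half_life",
    "two_phase_fit",
    "estimate_all",
    "summarize_decay",
    "format_capped",
]

ESTIMATE_COLUMNS = [
    "gene_id", "half_life_min", "half_life_se", "decay_rate_min",
    "decay_rate_se", "t_on", "breakpoint", "stable", "n_points_used", "flags",
]


@dataclass(frozen=True)
class SegmentFit:
    """One exponential segment: OLS of log2 signal on time.

    ``k`` is the decline rate on the log2 scale (positive = decline);
    ``time_per_twofold`` = 1/k is the segment's half-life-equivalent in
    minutes (inf for a flat segment, negative for a rising one).
    """

    t_start: float
    t_end: float
    k: float
    mse: float
    n_points: int
    ssr: float = 0.0
    intercept: float = 0.0

    @property
    def time_per_twofold(self) -> float:
        if self.k == 0:
            return float("inf")
        return 1.0 / self.k


@dataclass(frozen=True)
class TwoPhaseFit:
    """Result of the relative two-phase decay fit for one profile."""

    t_on: float
    breakpoint: float
    phase1: SegmentFit
    phase2: SegmentFit
    mse: float

    @property
    def decay_rate(self) -> float:
        """Time per twofold decline of the first phase (minutes)."""
        return self.phase1.time_per_twofold


def fit_exponential_segment(points: Sequence) -> SegmentFit:
    """OLS fit of log2(signal) vs time over a window of (t, signal) points.

    With exactly two points the line passes through both (MSE = 0).
    Raises on fewer than two points or any non-positive signal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    t, y = pts[:, 0], pts[:, 1]
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise ValueError("signals must be positive and finite (mask upstream)")
    ly = np.log2(y)
    tm, lym = t.mean(), ly.mean()
    sxx = float(np.sum((t - tm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate window: all timepoints equal")
    slope = float(np.sum((t - tm) * (ly - lym)) / sxx)
    intercept = lym - slope * tm
    resid = ly - (intercept + slope * t)
    ssr = float(np.sum(resid ** 2))
    n = len(t)
    return SegmentFit(t_start=float(t.min()), t_end=float(t.max()),
                      k=-slope, mse=ssr / n, n_points=n, ssr=ssr,
                      intercept=intercept)


def _clean(times, signal):
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    ok = np.isfinite(y) & (y > 0)
    return t[ok], y[ok]


def twofold_half_life(times, signal, horizon: float = 60.0):
    """Half-life by the twofold decay-step method.

    Finds the earliest timepoint (within ``horizon``) whose signal is at
    most half the first timepoint's and fits the exponential through
    those two points.  If the signal never halves, falls back to an
    all-point fit whose time-per-twofold may be negative (rising
    profiles) or arbitrarily large; such series are flagged stable.

    Returns ``(half_life_min, fell_twofold)``.
    """
    t, y = _clean(times, signal)
    if len(t) < 2:
        raise ValueError("unfittable series: fewer than 2 usable points")
    y0 = y[0]
    for j in range(1, len(t)):
        if t[j] > horizon:
            break
        if y[j] <= y0 / 2.0:
            seg = fit_exponential_segment([(t[0], y0), (t[j], y[j])])
            return seg.time_per_twofold, True
    seg = fit_exponential_segment(np.column_stack([t, y]))
    return seg.time_per_twofold, False


def two_phase_fit(times, signal) -> TwoPhaseFit:
    """Relative two-phase decay fit (see module docstring).

    The onset ``t_on`` is the last timepoint attaining the profile
    maximum.  Candidate breakpoints are the sampled timepoints strictly
    between ``t_on`` and the last timepoint; the breakpoint belongs to
    both segments and the pooled MSE (both segments' squared log2
    residuals divided by the total residual count, the breakpoint
    counted twice) is minimized, ties broken to the earliest candidate.

    Raises ``ValueError`` when fewer than 4 usable points remain at or
    after the onset.
    """
    t, y = _clean(times, signal)
    if len(t) < 2:
        raise ValueError("unfittable series: fewer than 2 usable points")
    i_on = int(np.flatnonzero(y == y.max())[-1])
    t_on = float(t[i_on])
    ts, ys = t[i_on:], y[i_on:]
    if len(ts) < 4:
        raise ValueError("too few points after onset for a two-phase fit")

    candidates = []
    for i in range(1, len(ts) - 1):
        seg1 = fit_exponential_segment(np.column_stack([ts[: i + 1], ys[: i + 1]]))
        seg2 = fit_exponential_segment(np.column_stack([ts[i:], ys[i:]]))
        mse = (seg1.ssr + seg2.ssr) / (seg1.n_points + seg2.n_points)
        candidates.append((mse, float(ts[i]), seg1, seg2))
    best_mse = min(c[0] for c in candidates)
    # earliest breakpoint within floating tolerance of the minimum: exact
    # multi-way ties (e.g. a pure exponential) must break to the first x
    tol = 1e-12 * (1.0 + best_mse)
    mse, x, seg1, seg2 = next(c for c in candidates if c[0] <= best_mse + tol)
    return TwoPhaseFit(t_on=t_on, breakpoint=x, phase1=seg1, phase2=seg2, mse=mse)


# ---------------------------------------------------------------------------
# model / results objects


class DecayModel:
    """Decay kinetics of a single transcript from its chase profile.

    Parameters
    ----------
    times : array-like
        Sampling times in minutes (first must be the pre-treatment 0).
    signal : array-like
        Either a 1-D mean profile or a 2-D (replicates x timepoints)
        array of positive linear intensities.
    config : PipelineConfig, optional
        Stability cutoff and reporting conventions.

    ``fit()`` applies both estimators to the replicate mean and, when
    replicates are available, refits each replicate to obtain standard
    errors.
    """

    def __init__(self, times, signal, config: Optional[PipelineConfig] = None,
                 gene_id: str = ""):
        self.times = np.asarray(times, dtype=float)
        sig = np.asarray(signal, dtype=float)
        if sig.ndim == 1:
            sig = sig[None, :]
        if sig.shape[1] != len(self.times):
            raise ValueError("signal and times have mismatched lengths")
        self.signal = sig
        self.config = config or PipelineConfig()
        self.gene_id = gene_id

    @classmethod
    def from_dataframe(cls, series: pd.DataFrame, gene_id: str,
                       config: Optional[PipelineConfig] = None) -> "DecayModel":
        """Build from a (gene_id, replicate) x time collection frame."""
        sub = series.xs(gene_id, level="gene_id")
        return cls(np.asarray(series.columns, dtype=float), sub.to_numpy(),
                   config=config, gene_id=gene_id)

    @property
    def mean_profile(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.signal, axis=0)

    def fit(self) -> "DecayResults":
        cfg = self.config
        horizon = cfg.stability_cutoff_min
        mean = self.mean_profile
        flags = []
        try:
            hl, fell = twofold_half_life(self.times, mean, horizon=horizon)
        except ValueError:
            return DecayResults(self, np.nan, np.nan, np.nan, np.nan,
                                np.nan, np.nan, False, 0, "unfittable")
        two = None
        try:
            two = two_phase_fit(self.times, mean)
        except ValueError:
            flags.append("no_two_phase")
        stable = (not fell) or hl < 0 or hl > cfg.stability_cutoff_min

        hl_se = np.nan
        dr_se = np.nan
        if self.signal.shape[0] > 1:
            hls, drs = [], []
            for row in self.signal:
                try:
                    h, _ = twofold_half_life(self.times, row, horizon=horizon)
                    hls.append(h)
                except ValueError:
                    pass
                try:
                    drs.append(two_phase_fit(self.times, row).decay_rate)
                except ValueError:
                    pass
            if len(hls) > 1:
                hl_se = float(np.std(hls, ddof=1) / np.sqrt(len(hls)))
            if len(drs) > 1:
                dr_se = float(np.std(drs, ddof=1) / np.sqrt(len(drs)))

        n_used = int(np.sum(np.isfinite(mean) & (mean > 0)))
        return DecayResults(
            model=self,
            half_life=float(hl),
            half_life_se=hl_se,
            decay_rate=float(two.decay_rate) if two else np.nan,
            decay_rate_se=dr_se,
            t_on=float(two.t_on) if two else np.nan,
            breakpoint=float(two.breakpoint) if two else np.nan,
            stable=bool(stable),
            n_points_used=n_used,
            flags=";".join(flags),
            two_phase=two,
        )


@dataclass
class DecayResults:
    """Fitted decay kinetics of one transcript."""

    model: DecayModel
    half_life: float
    half_life_se: float
    decay_rate: float
    decay_rate_se: float
    t_on: float
    breakpoint: float
    stable: bool
    n_points_used: int
    flags: str = ""
    two_phase: Optional[TwoPhaseFit] = None

    def summary(self) -> str:
        cap = self.model.config.decay_rate_report_cap
        lines = [
            f"Decay kinetics: {self.model.gene_id or '<unnamed>'}",
            "=" * 44,
            f"half-life (twofold)    {self.half_life:10.2f} min"
            + (f"  (se {self.half_life_se:.2f})" if np.isfinite(self.half_life_se) else ""),
            f"decay rate (two-phase) {format_capped(self.decay_rate, cap):>10s} min"
            + (f"  (se {self.decay_rate_se:.2f})" if np.isfinite(self.decay_rate_se) else ""),
            f"decay onset t_on       {self.t_on:10.1f} min",
            f"phase breakpoint       {self.breakpoint:10.1f} min",
            f"stable (> {self.model.config.stability_cutoff_min:.0f} min)     "
            f"{str(self.stable):>10s}",
            f"points used            {self.n_points_used:10d}",
        ]
        if self.flags:
            lines.append(f"flags: {self.flags}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "gene_id": self.model.gene_id,
            "half_life_min": self.half_life,
            "half_life_se": self.half_life_se,
            "decay_rate_min": self.decay_rate,
            "decay_rate_se": self.decay_rate_se,
            "t_on": self.t_on,
            "breakpoint": self.breakpoint,
            "stable": self.stable,
            "n_points_used": self.n_points_used,
            "flags": self.flags,
        }

    def plot(self, ax=None):
        """Profile normalized to t = 0 with the fitted phases overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.times
        mean = self.model.mean_profile
        ax.plot(t, mean / mean[0], "o-", label="mean signal / t0")
        if self.two_phase is not None:
            tp = self.two_phase
            for seg in (tp.phase1, tp.phase2):
                tt = np.linspace(seg.t_start, seg.t_end, 20)
                yy = 2.0 ** (seg.intercept - seg.k * tt)
                ax.plot(tt, yy / mean[0], "--")
        ax.set_xlabel("minutes after rifampicin")
        ax.set_ylabel("relative signal")
        ax.set_title(self.model.gene_id)
        return ax


def format_capped(value: float, cap: float) -> str:
    """Render a decay rate with the reporting cap convention (``>20``)."""
    if np.isfinite(value) and 0 <= value <= cap:
        return f"{value:.1f}"
    return f">{cap:g}"


# ---------------------------------------------------------------------------
# genome-wide driver


def estimate_all(series: pd.DataFrame, config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Fit both estimators for every gene in a collection.

    Unfittable genes are kept as rows with NaN estimates and a flag;
    they never abort the run.
    """
    config = config or PipelineConfig()
    rows = []
    for gid in series.index.get_level_values("gene_id").unique():
        res = DecayModel.from_dataframe(series, gid, config=config).fit()
        rows.append(res.to_row())
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def summarize_decay(table: pd.DataFrame, config: Optional[PipelineConfig] = None,
                    subsets: Optional[dict] = None) -> dict:
    """Genome-wide decay summary.

    Medians are taken over genes with positive finite estimates (a
    negative fallback half-life means "no measurable decay" and has no
    place in a central-tendency statistic); the stable fraction counts
    all fitted genes.  ``subsets`` maps a name to a gene-id list; each
    subset's median decay rate is computed after excluding values above
    the reporting cap, the convention used for printed rate tables.
    """
    if table.empty:
        raise ValueError("empty estimate table")
    config = config or PipelineConfig()
    hl = table["half_life_min"]
    dr = table["decay_rate_min"]
    hl_pos = hl[np.isfinite(hl) & (hl > 0)]
    dr_pos = dr[np.isfinite(dr) & (dr > 0)]
    fitted = table[np.isfinite(hl)]
    out = {
        "n_genes": int(len(table)),
        "median_half_life_min": float(hl_pos.median()),
        "median_decay_rate_min": float(dr_pos.median()),
        "half_life_p10_min": float(np.percentile(hl_pos, 10)),
        "half_life_p90_min": float(np.percentile(hl_pos, 90)),
        "fraction_stable": float(fitted["stable"].mean()),
    }
    if subsets:
        cap = config.decay_rate_report_cap
        for name, ids in subsets.items():
            sub = table[table["gene_id"].isin(ids)]
            if sub.empty:
                raise ValueError(f"empty subset {name!r}")
            vals = sub["decay_rate_min"]
            vals = vals[np.isfinite(vals) & (vals >= 0) & (vals <= cap)]
            out[f"median_decay_rate_{name}_min"] = float(vals.median())
    return out
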