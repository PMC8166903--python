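"""The bulked-segregant mapping statistics.

Pipeline: quality/depth filters → per-SNP CB4856 allele frequencies →
300-kb non-overlapping window means → bulk-scaled log-odds statistic →
genome-wide two-tailed threshold from the Bernoulli(½) null → QTL calling.

The statistic for a window with mean CB4856 frequencies l̄ (low bulk) and
h̄ (high bulk), scaled to line-equivalents l = l̄·n_l and h = h̄·n_h, is

    log-odds = log10( (h / (n_h − h)) / (l / (n_l − l)) )

positive when the high bulk is CB4856-enriched.  The raw formula is
infinite when a bulk is fixed (l ∈ {0, n_l} or h ∈ {0, n_h}); l and h are
therefore clamped 0.5 line-equivalents away from the boundary, leaving
every interior value exactly equal to the formula.

Under the null (no linked QTL) each pooled line carries either parental
allele with probability ½, so l ~ Binomial(n_l, ½) and h ~ Binomial(n_h, ½)
independently.  The genome-wide threshold pair is the two-tailed α = 0.05
cut of this null, obtained either by Monte-Carlo simulation (the study's
procedure: one million trials) or by exact enumeration of the
(n_l+1)·(n_h+1) outcomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rilsim import BulkDesign
from .vcf_io import SnpRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 300_000
DEFAULT_CLAMP = 0.5


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """SNP quality filters: drop GQ < 40 (either bulk) and depth below the
    bulk's line count (< 22 low, < 24 high); equality passes."""

    gq_min: int = 40
    depth_min_low: int = 22
    depth_min_high: int = 24

    def validate(self) -> None:
        if self.gq_min < 0 or self.depth_min_low < 0 or self.depth_min_high < 0:
            raise ValueError("filter thresholds must be >= 0")


def _passes(r: SnpRecord, cfg: FilterConfig) -> bool:
    return (
        r.gq_low >= cfg.gq_min
        and r.gq_high >= cfg.gq_min
        and r.depth_low >= cfg.depth_min_low
        and r.depth_high >= cfg.depth_min_high
    )


def filter_snps(records: list[SnpRecord], cfg: FilterConfig) -> list[SnpRecord]:
    """Keep records passing all four criteria, preserving order."""
    cfg.validate()
    kept = [r for r in records if _passes(r, cfg)]
    if len(kept) < len(records):
        c = filter_counts(records, cfg)
        logger.info(
            "filter_snps: %d/%d kept (fail gq_low %d, gq_high %d, "
            "depth_low %d, depth_high %d)",
            len(kept), len(records),
            c["fail_gq_low"], c["fail_gq_high"],
            c["fail_depth_low"], c["fail_depth_high"],
        )
    return kept


def filter_counts(records: list[SnpRecord], cfg: FilterConfig) -> dict[str, int]:
    """Per-criterion failure tallies (a record may fail several)."""
    c = {
        "input": len(records),
        "kept": 0,
        "fail_gq_low": 0,
        "fail_gq_high": 0,
        "fail_depth_low": 0,
        "fail_depth_high": 0,
    }
    for r in records:
        if r.gq_low < cfg.gq_min:
            c["fail_gq_low"] += 1
        if r.gq_high < cfg.gq_min:
            c["fail_gq_high"] += 1
        if r.depth_low < cfg.depth_min_low:
            c["fail_depth_low"] += 1
        if r.depth_high < cfg.depth_min_high:
            c["fail_depth_high"] += 1
        if _passes(r, cfg):
            c["kept"] += 1
    return c


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyPoint:
    """CB4856 allele frequency of one SNP in each bulk."""

    chrom: str
    pos: int
    freq_low: float
    freq_high: float


def cb_allele_frequency(record: SnpRecord) -> FrequencyPoint:
    """Frequency of the CB4856 allele: alt reads over total reads, per bulk."""
    tot_low = record.alt_count_low + record.ref_count_low
    tot_high = record.alt_count_high + record.ref_count_high
    if tot_low == 0 or tot_high == 0:
        raise ValueError(
            f"{record.chrom}:{record.pos}: zero read total in a bulk "
            "(apply the depth filter first)"
        )
    return FrequencyPoint(
        chrom=record.chrom,
        pos=record.pos,
        freq_low=record.alt_count_low / tot_low,
        freq_high=record.alt_count_high / tot_high,
    )


def frequency_table(records: list[SnpRecord]) -> pd.DataFrame:
    """Vectorised cb_allele_frequency over a record list."""
    pts = [cb_allele_frequency(r) for r in records]
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in pts],
            "pos": [p.pos for p in pts],
            "freq_low": [p.freq_low for p in pts],
            "freq_high": [p.freq_high for p in pts],
        }
    )


# ---------------------------------------------------------------------------
# the log-odds statistic
# ---------------------------------------------------------------------------

def log_odds(l, h, n_l: int, n_h: int, clamp: float = DEFAULT_CLAMP):
    """Bulk-scaled log-odds ratio log10((h/(n_h−h))/(l/(n_l−l))).

    ``l`` and ``h`` are line-equivalents (mean window frequency times bulk
    size); scalars or arrays.  Values are clamped to
    [clamp, n − clamp] before evaluation so the statistic is always finite;
    interior values are untouched.
    """
    if n_l <= 2 * clamp or n_h <= 2 * clamp:
        raise ValueError("bulk sizes must exceed twice the clamp")
    l = np.clip(np.asarray(l, dtype=float), clamp, n_l - clamp)
    h = np.clip(np.asarray(h, dtype=float), clamp, n_h - clamp)
    out = np.log10((h / (n_h - h)) / (l / (n_l - l)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    """One non-overlapping window: mean bulk frequencies, scaled counts, and
    the log-odds statistic.  ``start``/``end`` are 1-based half-open."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_freq_low: float
    mean_freq_high: float
    l: float
    h: float
    log_odds: float


def window_stats(
    points: list[FrequencyPoint] | pd.DataFrame,
    design: BulkDesign,
    window: int = DEFAULT_WINDOW,
    clamp: float = DEFAULT_CLAMP,
) -> list[WindowStat]:
    """Tile each chromosome from position 1 with non-overlapping windows
    [1+k·w, 1+(k+1)·w), average the SNP frequencies per window, scale to
    line-equivalents and compute the log-odds.  Windows without SNPs are
    omitted.  Input must be sorted by (chrom, pos)."""
    if isinstance(points, pd.DataFrame):
        df = points
    else:
        df = pd.DataFrame(
            {
                "chrom": [p.chrom for p in points],
                "pos": [p.pos for p in points],
                "freq_low": [p.freq_low for p in points],
                "freq_high": [p.freq_high for p in points],
            }
        )
    if df.empty:
        return []
    # sortedness: positions non-decreasing within each chromosome block,
    # and each chromosome appears as one contiguous block
    chrom_vals = df["chrom"].to_numpy()
    block_change = np.nonzero(chrom_vals[1:] != chrom_vals[:-1])[0]
    block_names = [chrom_vals[0]] + [chrom_vals[i + 1] for i in block_change]
    if len(block_names) != len(set(block_names)):
        raise ValueError("points not sorted: chromosome blocks not contiguous")
    pos = df["pos"].to_numpy()
    same = chrom_vals[1:] == chrom_vals[:-1]
    if np.any(same & (pos[1:] < pos[:-1])):
        raise ValueError("points not sorted by position within chromosome")

    out: list[WindowStat] = []
    df = df.assign(_win=(df["pos"] - 1) // window)
    for (chrom, k), grp in df.groupby(["chrom", "_win"], sort=False):
        l_bar = float(grp["freq_low"].mean())
        h_bar = float(grp["freq_high"].mean())
        l = l_bar * design.n_low
        h = h_bar * design.n_high
        out.append(
            WindowStat(
                chrom=str(chrom),
                start=int(1 + k * window),
                end=int(1 + (k + 1) * window),
                n_snps=len(grp),
                mean_freq_low=l_bar,
                mean_freq_high=h_bar,
                l=l,
                h=h,
                log_odds=log_odds(l, h, design.n_low, design.n_high, clamp),
            )
        )
    out.sort(key=lambda w: (block_names.index(w.chrom), w.start))
    return out


def windows_frame(stats: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in stats],
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "n_snps": [w.n_snps for w in stats],
            "mean_freq_low": [w.mean_freq_low for w in stats],
            "mean_freq_high": [w.mean_freq_high for w in stats],
            "l": [w.l for w in stats],
            "h": [w.h for w in stats],
            "log_odds": [w.log_odds for w in stats],
        }
    )


# ---------------------------------------------------------------------------
# the null distribution and thresholds
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Two-tailed genome-wide threshold pair for the log-odds statistic under
    the Bernoulli(½) null, with the tail mass actually achieved.

    ``tail_low``/``tail_high`` are P(stat < threshold_low) and
    P(stat > threshold_high) under the stored distribution (exact mass for
    the enumerated null, empirical fractions for Monte Carlo).
    """

    source: str  # "monte_carlo" | "exact"
    threshold_low: float
    threshold_high: float
    alpha: float
    tail_low: float
    tail_high: float
    trials: int | None = None
    seed: int | None = None
    support: np.ndarray | None = field(default=None, repr=False)
    pmf: np.ndarray | None = field(default=None, repr=False)

    @property
    def tail_mass(self) -> float:
        """Total two-tailed probability beyond the threshold pair."""
        return self.tail_low + self.tail_high


def simulate_null_stats(
    design: BulkDesign,
    trials: int,
    rng: np.random.Generator,
    clamp: float = DEFAULT_CLAMP,
) -> np.ndarray:
    """Draw ``trials`` null window statistics: one Bernoulli(½) trial per
    pooled line, i.e. l ~ Binomial(n_l, ½), h ~ Binomial(n_h, ½)."""
    l = rng.binomial(design.n_low, 0.5, size=trials)
    h = rng.binomial(design.n_high, 0.5, size=trials)
    return log_odds(l, h, design.n_low, design.n_high, clamp)


def null_threshold_mc(
    design: BulkDesign,
    alpha: float = 0.05,
    trials: int = 1_000_000,
    seed: int | None = None,
    clamp: float = DEFAULT_CLAMP,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Monte-Carlo genome-wide threshold: simulate the Bernoulli(½) null and
    take the order statistics at ceil(α/2·trials) from each tail."""
    if trials < 1000:
        raise ValueError("trials must be >= 1000")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = np.sort(simulate_null_stats(design, trials, rng, clamp))
    k = math.ceil(alpha / 2 * trials)
    thr_low = float(values[k - 1])
    thr_high = float(values[trials - k])
    return NullDistribution(
        source="monte_carlo",
        threshold_low=thr_low,
        threshold_high=thr_high,
        alpha=alpha,
        tail_low=float(np.count_nonzero(values < thr_low)) / trials,
        tail_high=float(np.count_nonzero(values > thr_high)) / trials,
        trials=trials,
        seed=seed,
    )


def null_threshold_exact(
    design: BulkDesign,
    alpha: float = 0.05,
    clamp: float = DEFAULT_CLAMP,
) -> NullDistribution:
    """Exact enumeration of the null: all (n_l+1)·(n_h+1) outcomes with
    their binomial(½) probabilities; conservative two-tailed thresholds
    (largest/smallest support values whose outer tail mass is ≤ α/2)."""
    n_l, n_h = design.n_low, design.n_high
    l = np.arange(n_l + 1)
    h = np.arange(n_h + 1)
    p_l = sps.binom.pmf(l, n_l, 0.5)
    p_h = sps.binom.pmf(h, n_h, 0.5)
    stat = log_odds(
        np.repeat(l, n_h + 1), np.tile(h, n_l + 1), n_l, n_h, clamp
    )
    prob = np.outer(p_l, p_h).ravel()
    support, inverse = np.unique(np.round(stat, 12), return_inverse=True)
    pmf = np.bincount(inverse, weights=prob, minlength=len(support))

    cdf = np.cumsum(pmf)
    exceed = 1.0 - cdf  # P(stat > support[i])
    below = cdf - pmf  # P(stat < support[i])
    # smallest support value whose upper tail mass is <= alpha/2
    i_high = int(np.argmax(exceed <= alpha / 2))
    # largest support value whose lower tail mass is <= alpha/2
    i_low = int(len(support) - 1 - np.argmax((below <= alpha / 2)[::-1]))
    return NullDistribution(
        source="exact",
        threshold_low=float(support[i_low]),
        threshold_high=float(support[i_high]),
        alpha=alpha,
        tail_low=float(below[i_low]),
        tail_high=float(exceed[i_high]),
        support=support,
        pmf=pmf,
    )


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

@dataclass
class QtlInterval:
    """A merged run of significant same-sign windows.  ``sign`` is +1 when
    the high bulk is CB4856-enriched, −1 when the low bulk is."""

    chrom: str
    start: int
    end: int
    sign: int
    peak_start: int
    peak_end: int
    peak_log_odds: float
    n_windows: int = 1  # number of member significant windows

    @property
    def peak_mid(self) -> int:
        return (self.peak_start + self.peak_end) // 2


def call_qtls(
    stats: list[WindowStat],
    null: NullDistribution,
    max_gap: int = 0,
) -> list[QtlInterval]:
    """Call QTLs: windows beyond the threshold pair, merged into maximal
    same-sign runs.

    Runs may bridge windows that were omitted because they contained no
    SNPs; up to ``max_gap`` emitted-but-non-significant windows may also be
    bridged (default 0).  The peak is the member window with the largest
    |log-odds|, ties to the leftmost.
    """
    out: list[QtlInterval] = []
    if not stats:
        return out

    def sign_of(w: WindowStat) -> int:
        if w.log_odds > null.threshold_high:
            return 1
        if w.log_odds < null.threshold_low:
            return -1
        return 0

    # group by chromosome preserving input order
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in stats:
        by_chrom.setdefault(w.chrom, []).append(w)

    for chrom, wins in by_chrom.items():
        run: list[WindowStat] = []
        run_sign = 0

        def flush() -> None:
            nonlocal run, run_sign
            if run:
                peak = max(run, key=lambda w: (abs(w.log_odds), -w.start))
                out.append(
                    QtlInterval(
                        chrom=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        sign=run_sign,
                        peak_start=peak.start,
                        peak_end=peak.end,
                        peak_log_odds=peak.log_odds,
                        n_windows=len(run),
                    )
                )
            run, run_sign = [], 0

        pending_gap = 0
        for w in wins:
            s = sign_of(w)
            if s == 0:
                if run:
                    pending_gap += 1
                    if pending_gap > max_gap:
                        flush()
                        pending_gap = 0
                continue
            if run and s == run_sign:
                run.append(w)
                pending_gap = 0
            else:
                flush()
                run = [w]
                run_sign = s
                pending_gap = 0
        flush()
    return out


# ---------------------------------------------------------------------------
# LOESS curves (reporting only)
# ---------------------------------------------------------------------------

def loess_curve(
    positions: np.ndarray | list[int],
    freqs: np.ndarray | list[float],
    span: float = 0.1,
) -> np.ndarray:
    """LOESS-smoothed frequency track for one chromosome and one bulk.

    Local linear fit with tricube weights over the span·n nearest
    neighbours (statsmodels lowess); returns fitted values at the input
    positions, in input order.  Used for the fitted frequency curves only,
    never for QTL inference.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(freqs, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("loess_curve needs at least 10 points")
    if span * n < 3:
        raise ValueError("span too small: span*n must be >= 3")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    return lowess(y, x, frac=span, return_sorted=False)


def loess_curves_by_chrom(freq: pd.DataFrame, span: float = 0.1) -> pd.DataFrame:
    """Fitted low/high-bulk curves per chromosome, tidy frame."""
    parts = []
    for chrom, grp in freq.groupby("chrom", sort=False):
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "fit_low": loess_curve(grp["pos"], grp["freq_low"], span),
                    "fit_high": loess_curve(grp["pos"], grp["freq_high"], span),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
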