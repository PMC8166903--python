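"""Model/Results interface over the bulked-segregant mapping computation.

``BulkSegregantModel`` holds the data (two-bulk SNP records) and the design
(bulk sizes, filters, window size); ``fit`` runs filtering, allele
frequencies, window statistics, the null threshold and QTL calling, and
returns a ``BulkSegregantResults`` with the estimates and a ``summary()``
table, in the spirit of statsmodels' model objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bsa
from .bsa import (
    DEFAULT_CLAMP,
    DEFAULT_WINDOW,
    FilterConfig,
    NullDistribution,
    QtlInterval,
    WindowStat,
)
from .rilsim import BulkDesign
from .vcf_io import SnpRecord, read_bulk_vcf


class BulkSegregantModel:
    """Bulked-segregant QTL mapping of a two-bulk pooled-sequencing dataset.

    Parameters
    ----------
    records
        Biallelic SNPs with per-bulk read counts (alt = CB4856 allele),
        sorted by (chrom, pos).
    design
        Numbers of pooled lines in the low and high bulk (n_l, n_h).
    filter_config
        GQ/depth filters applied before frequency computation.
    window
        Non-overlapping window width in bp (default 300 kb).
    clamp
        Line-equivalents kept away from the bulk-size boundary so the
        log-odds statistic stays finite.
    """

    def __init__(
        self,
        records: list[SnpRecord],
        design: BulkDesign | None = None,
        filter_config: FilterConfig | None = None,
        window: int = DEFAULT_WINDOW,
        clamp: float = DEFAULT_CLAMP,
    ) -> None:
        self.records = records
        self.design = design or BulkDesign()
        self.filter_config = filter_config or FilterConfig()
        self.window = window
        self.clamp = clamp

    @classmethod
    def from_vcf(
        cls,
        path: str,
        low_sample: str,
        high_sample: str,
        **kwargs,
    ) -> "BulkSegregantModel":
        """Build the model from a two-sample VCF with AD and GQ fields."""
        return cls(read_bulk_vcf(path, low_sample, high_sample), **kwargs)

    def fit(
        self,
        null: str = "exact",
        alpha: float = 0.05,
        trials: int = 1_000_000,
        seed: int | None = None,
        max_gap: int = 0,
    ) -> "BulkSegregantResults":
        """Run the mapping pipeline and return the results object.

        ``null`` selects the threshold construction: ``"exact"`` enumerates
        the Bernoulli(½) null, ``"mc"`` simulates it with ``trials`` draws
        (the study's procedure; requires ``seed`` for reproducibility).
        """
        if null not in ("exact", "mc"):
            raise ValueError("null must be 'exact' or 'mc'")
        kept = bsa.filter_snps(self.records, self.filter_config)
        counts = bsa.filter_counts(self.records, self.filter_config)
        freq = bsa.frequency_table(kept) if kept else pd.DataFrame(
            columns=["chrom", "pos", "freq_low", "freq_high"]
        )
        windows = bsa.window_stats(freq, self.design, self.window, self.clamp) if kept else []
        if null == "exact":
            dist = bsa.null_threshold_exact(self.design, alpha, self.clamp)
        else:
            dist = bsa.null_threshold_mc(
                self.design, alpha, trials, seed=seed, clamp=self.clamp
            )
        qtls = bsa.call_qtls(windows, dist, max_gap=max_gap)
        return BulkSegregantResults(
            model=self,
            filter_counts=counts,
            frequencies=freq,
            windows=windows,
            null=dist,
            qtls=qtls,
        )


@dataclass
class BulkSegregantResults:
    """Fitted mapping results: filtered frequencies, window statistics,
    the null threshold pair, and the called QTL intervals."""

    model: BulkSegregantModel
    filter_counts: dict[str, int]
    frequencies: pd.DataFrame
    windows: list[WindowStat]
    null: NullDistribution
    qtls: list[QtlInterval]
    _loess_cache: dict = field(default_factory=dict, repr=False)

    @property
    def threshold_low(self) -> float:
        return self.null.threshold_low

    @property
    def threshold_high(self) -> float:
        return self.null.threshold_high

    @property
    def windows_frame(self) -> pd.DataFrame:
        return bsa.windows_frame(self.windows)

    @property
    def qtl_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [q.chrom for q in self.qtls],
                "start": [q.start for q in self.qtls],
                "end": [q.end for q in self.qtls],
                "sign": [q.sign for q in self.qtls],
                "peak_start": [q.peak_start for q in self.qtls],
                "peak_end": [q.peak_end for q in self.qtls],
                "peak_log_odds": [q.peak_log_odds for q in self.qtls],
                "n_windows": [q.n_windows for q in self.qtls],
            }
        )

    def loess(self, span: float = 0.1) -> pd.DataFrame:
        """LOESS-fitted frequency curves per chromosome (reporting only)."""
        key = round(span, 6)
        if key not in self._loess_cache:
            self._loess_cache[key] = bsa.loess_curves_by_chrom(
                self.frequencies, span
            )
        return self._loess_cache[key]

    def summary(self) -> str:
        """Human-readable fit summary: design, filters, thresholds, QTLs."""
        m = self.model
        c = self.filter_counts
        lines = [
            "Bulked-segregant QTL mapping",
            "=" * 60,
            f"bulk design           n_low = {m.design.n_low}, n_high = {m.design.n_high}",
            f"window                {m.window} bp, clamp {m.clamp} line-equivalents",
            f"SNPs                  {c.get('input', len(m.records))} in, "
            f"{c.get('kept', 0)} pass filters "
            f"(GQ >= {m.filter_config.gq_min}, depth >= "
            f"{m.filter_config.depth_min_low}/{m.filter_config.depth_min_high})",
            f"windows               {len(self.windows)} non-empty",
            f"null                  {self.null.source}"
            + (f", {self.null.trials} trials" if self.null.trials else ""),
            f"thresholds (alpha={self.null.alpha})   "
            f"low {self.null.threshold_low:+.4f}, high {self.null.threshold_high:+.4f} "
            f"(tail mass {self.null.tail_mass:.4f})",
            "-" * 60,
        ]
        if self.qtls:
            lines.append("called QTL intervals (log10 odds, + = high bulk CB4856-rich):")
            lines.append(
                f"{'chrom':<6}{'start':>10}{'end':>10}{'sign':>6}"
                f"{'peak_mid':>10}{'peak_LOD':>10}{'windows':>8}"
            )
            for q in self.qtls:
                lines.append(
                    f"{q.chrom:<6}{q.start:>10}{q.end:>10}{q.sign:>+6}"
                    f"{q.peak_mid:>10}{q.peak_log_odds:>10.3f}{q.n_windows:>8}"
                )
        else:
            lines.append("no QTL interval exceeds the genome-wide threshold")
        return "\n".join(lines)

    def plot(self, path: str | None = None):
        """Frequency and log-odds tracks per chromosome (needs matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        chroms = list(dict.fromkeys(self.frequencies["chrom"]))
        fig, axes = plt.subplots(
            2, len(chroms), figsize=(3 * len(chroms), 5), sharey="row", squeeze=False
        )
        wf = self.windows_frame
        for j, chrom in enumerate(chroms):
            f = self.frequencies[self.frequencies["chrom"] == chrom]
            ax = axes[0][j]
            ax.scatter(f["pos"] / 1e6, f["freq_low"], s=1, c="seagreen", alpha=0.3)
            ax.scatter(f["pos"] / 1e6, f["freq_high"], s=1, c="darkorange", alpha=0.3)
            ax.set_title(chrom)
            ax.set_ylim(0, 1)
            w = wf[wf["chrom"] == chrom]
            ax2 = axes[1][j]
            ax2.plot((w["start"] + w["end"]) / 2e6, w["log_odds"], c="black")
            ax2.axhline(self.threshold_high, ls="--", c="steelblue")
            ax2.axhline(self.threshold_low, ls="--", c="steelblue")
            ax2.set_xlabel("Mb")
        axes[0][0].set_ylabel("CB4856 SNP proportion")
        axes[1][0].set_ylabel("log-odds")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig
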