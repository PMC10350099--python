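"""Essential-gene floor analysis of per-gene transcription statistics.

Because protein noise is set by the message number alone, the message number
can stand proxy for noise in transcriptome-wide analysis.  This module
annotates gene tables with the two derived transcription statistics
(message number per cycle, transcription rate), builds log-scale class
histograms (essential vs nonessential), and quantifies the transcriptional
floor: the empirical lower edge of the essential-gene message-number
distribution, summarized as quantiles, below-threshold fractions, and the
noise ceiling ``ln2 / mu_m`` implied at the lower quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LN2, OrganismConstants

__all__ = [
    "STATISTIC_COLUMNS",
    "ClassDistribution",
    "FloorReport",
    "ClassFloorSummary",
    "annotate_gene_table",
    "class_distribution",
    "floor_report",
]

STATISTIC_COLUMNS = {
    "transcription_rate": "transcription_rate_per_h",
    "cellular_message_number": "mrna_per_cell",
    "message_number": "message_number",
}

DEFAULT_N_BINS = 40
FLOOR_QUANTILES = (0.01, 0.05, 0.5)


def annotate_gene_table(records: pd.DataFrame, org: OrganismConstants) -> pd.DataFrame:
    """Fill in message number and transcription rate from copies per cell.

    ``message_number = (T/tau_m) * mrna_per_cell`` and
    ``transcription_rate = message_number / T``.  Returns a copy; calling it
    again with the same constants is a no-op on the derived columns.
    """
    if "mrna_per_cell" not in records.columns:
        raise ValueError("records must have an 'mrna_per_cell' column")
    if org is None:
        raise ValueError("organism constants are required")
    out = records.copy()
    ratio = org.recycling_ratio
    out["message_number"] = out["mrna_per_cell"].astype(float) * ratio
    out["transcription_rate_per_h"] = out["message_number"] / org.doubling_time_h
    return out


@dataclass(frozen=True)
class ClassDistribution:
    """Log10-binned histogram of one statistic within one essentiality class.

    Zero values cannot be placed on a log axis and are tallied separately
    in ``zero_count`` (transcriptionally silent genes).
    """

    statistic: str
    gene_class: str
    bin_edges_log10: np.ndarray
    counts: np.ndarray
    zero_count: int
    n: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_log10)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if int(np.sum(self.counts)) + self.zero_count != self.n:
            raise ValueError("histogram counts must sum to the class size")


def class_distribution(
    records: pd.DataFrame,
    statistic: str,
    gene_class: str,
    n_bins: int = DEFAULT_N_BINS,
) -> ClassDistribution:
    """Histogram one transcription statistic for one essentiality class.

    ``statistic`` is one of ``transcription_rate``, ``cellular_message_number``
    or ``message_number`` (the table must already be annotated for the first
    and last).  Bins are uniform in log10 over the observed positive range;
    zeros go to the separate zero bin.
    """
    if statistic not in STATISTIC_COLUMNS:
        raise ValueError(f"unknown statistic {statistic!r}; use one of {sorted(STATISTIC_COLUMNS)}")
    if gene_class not in ("essential", "nonessential"):
        raise ValueError("gene_class must be 'essential' or 'nonessential'")
    column = STATISTIC_COLUMNS[statistic]
    if column not in records.columns:
        raise ValueError(f"records lack column {column!r}; annotate the table first")
    mask = records["essential"].astype(bool)
    if gene_class == "nonessential":
        mask = ~mask
    values = np.asarray(records.loc[mask, column], dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"no genes in class {gene_class!r}")
    zero_count = int((values == 0).sum())
    positive = values[values > 0]
    if positive.size == 0:
        edges = np.array([0.0, 1.0])
        counts = np.zeros(1, dtype=int)
    else:
        lo = np.log10(positive.min())
        hi = np.log10(positive.max())
        if lo == hi:  # single occupied bin
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(np.log10(positive), bins=edges)
    return ClassDistribution(
        statistic=statistic,
        gene_class=gene_class,
        bin_edges_log10=edges,
        counts=counts.astype(int),
        zero_count=zero_count,
        n=int(values.size),
    )


@dataclass(frozen=True)
class ClassFloorSummary:
    """Floor summary for one essentiality class."""

    n: int
    quantiles: dict[float, float]  # quantile level -> message number
    fraction_below: float
    noise_ceiling_at_q01: float


@dataclass(frozen=True)
class FloorReport:
    """Message-number floor quantification per essentiality class."""

    threshold: float
    classes: dict[str, ClassFloorSummary] = field(default_factory=dict)


def floor_report(records: pd.DataFrame, threshold: float = 1.0) -> FloorReport:
    """Quantify the message-number floor per essentiality class.

    For each class present, reports the 1%, 5% and 50% quantiles of the
    message number (linear interpolation between order statistics — class
    tails are small), the fraction of genes strictly below ``threshold``
    messages per cycle, and the noise ceiling ``ln2 / mu_m`` evaluated at
    the 1% quantile.  An empty class is omitted with a warning rather than
    raising, so single-class tables still produce a report.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if "message_number" not in records.columns:
        raise ValueError("records lack 'message_number'; annotate the table first")
    report = FloorReport(threshold=threshold, classes={})
    essential_mask = records["essential"].astype(bool)
    for name, mask in (("essential", essential_mask), ("nonessential", ~essential_mask)):
        values = np.asarray(records.loc[mask, "message_number"], dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            warnings.warn(f"no genes in class {name!r}; omitted from floor report",
                          UserWarning, stacklevel=2)
            continue
        qs = {q: float(np.quantile(values, q)) for q in FLOOR_QUANTILES}
        q01 = qs[0.01]
        report.classes[name] = ClassFloorSummary(
            n=int(values.size),
            quantiles=qs,
            fraction_below=float((values < threshold).mean()),
            noise_ceiling_at_q01=float(LN2 / q01) if q01 > 0 else float("inf"),
        )
    return report
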