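"""Count-weighted viability statistics: expansion, box stats, group
comparison, binned curves and seed-composition matrices.

The unit of every statistic here is the *expanded* viability multiset:
each table row contributes round(weight / divisor) copies of its seed
viability, where the weight is a normalized read count or an absolute
delta read count and the divisor (default 1000) tames multiset size.
Medians and hinges are therefore read-count-weighted, not per-sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "U")
QUANTILE_CONVENTION = "linear interpolation between order statistics"


@dataclass(frozen=True)
class ExpansionConfig:
    """Count-to-copies conversion: nearest integer of weight / divisor."""

    divisor: int = 1000

    def __post_init__(self) -> None:
        if self.divisor < 1:
            raise ValueError("divisor must be >= 1")


@dataclass(frozen=True)
class ExpandedViability:
    """Multiset of viability values produced by count-weighted expansion."""

    values: np.ndarray
    provenance: str
    n_dropped_rows: int

    @property
    def n(self) -> int:
        return len(self.values)

    def median(self) -> float:
        return float(np.median(self.values))


def _copies(weights: np.ndarray, divisor: int) -> np.ndarray:
    """Round half away from zero on non-negative weight/divisor ratios."""
    if (weights < 0).any():
        raise ValueError(
            "negative weights; split differential rows by delta sign first"
        )
    return np.floor(weights / divisor + 0.5).astype(np.int64)


def expand(
    table: pd.DataFrame,
    weight_column: str,
    cfg: ExpansionConfig = ExpansionConfig(),
    provenance: str | None = None,
) -> ExpandedViability:
    """Expand row viabilities into a multiset weighted by read counts.

    Rows whose weight rounds to zero copies contribute nothing; their
    number is logged and recorded.
    """
    weights = table[weight_column].to_numpy(dtype=float)
    copies = _copies(weights, cfg.divisor)
    values = np.repeat(table["viability"].to_numpy(dtype=float), copies)
    n_dropped = int(((copies == 0) & (weights > 0)).sum())
    if n_dropped:
        logger.info(
            "expand dropped %d rows with weight < %s/2", n_dropped, cfg.divisor
        )
    return ExpandedViability(
        values=values,
        provenance=provenance or weight_column,
        n_dropped_rows=n_dropped,
    )


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-and-whisker summary of an expanded viability multiset.

    Hinges are the first and third quartiles (linear-interpolation
    convention); whiskers extend to the most extreme point no further
    than 1.5 x IQR beyond the hinges; points beyond are outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


def box_stats(ev: ExpandedViability | np.ndarray) -> BoxStats:
    values = ev.values if isinstance(ev, ExpandedViability) else np.asarray(ev, float)
    if len(values) == 0:
        raise ValueError("cannot compute box statistics of an empty multiset")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    low_cap, high_cap = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= low_cap) & (values <= high_cap)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = values[(values < low_cap) | (values > high_cap)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=tuple(sorted(float(v) for v in outliers)),
        n=len(values),
    )


def compare_groups(
    groups: Sequence[ExpandedViability | np.ndarray],
) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum H (tie-corrected) and chi-square p-value.

    When every value across all groups is identical no group effect is
    possible; the degenerate (H=0, p=1) convention is returned with a
    warning instead of an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = [
        g.values if isinstance(g, ExpandedViability) else np.asarray(g, float)
        for g in groups
    ]
    for arr in arrays:
        if len(arr) == 0:
            raise ValueError("cannot compare an empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; returning p = 1")
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def split_differential(
    diff_table: pd.DataFrame, delta_column: str = "delta"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a differential table into enriched / depleted halves.

    Both halves carry a non-negative ``weight`` column equal to |delta|,
    ready for :func:`expand`, :func:`binned_curve` and
    :func:`seed_composition`.
    """
    delta = diff_table[delta_column]
    enriched = diff_table.loc[delta > 0].copy()
    enriched["weight"] = delta[delta > 0]
    depleted = diff_table.loc[delta < 0].copy()
    depleted["weight"] = -delta[delta < 0]
    return enriched, depleted


def binned_curve(
    table: pd.DataFrame,
    weight_column: str,
    bin_width: float = 1.0,
    by_rna_type: bool = False,
) -> pd.DataFrame:
    """Viability curve: collapse on (seed, rna_type), then bin the weights.

    Rows sharing a seed and RNA type are summed first; collapsed weights
    are then aggregated into left-closed right-open viability bins of
    ``bin_width`` percent anchored at 0, covering [0, max observed
    viability].  Bin totals conserve the collapsed table's total weight.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    collapsed = (
        table.groupby(["seed", "rna_type"], sort=True)
        .agg(weight=(weight_column, "sum"), viability=("viability", "first"))
        .reset_index()
    )
    n_bins = int(np.floor(collapsed["viability"].max() / bin_width)) + 1 if len(collapsed) else 0
    frames = []
    groups = collapsed.groupby("rna_type") if by_rna_type else [(None, collapsed)]
    for rna_type, sub in groups:
        idx = np.floor(sub["viability"].to_numpy() / bin_width).astype(int)
        weights = np.zeros(n_bins)
        np.add.at(weights, idx, sub["weight"].to_numpy(dtype=float))
        frame = pd.DataFrame(
            {
                "bin_left": np.arange(n_bins) * bin_width,
                "bin_right": (np.arange(n_bins) + 1) * bin_width,
                "weight": weights,
            }
        )
        if by_rna_type:
            frame.insert(0, "rna_type", rna_type)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["bin_left", "bin_right", "weight"])
    return pd.concat(frames, ignore_index=True)


def seed_composition(
    table: pd.DataFrame,
    weight_column: str,
    cfg: ExpansionConfig = ExpansionConfig(),
) -> pd.DataFrame:
    """Weighted nucleotide frequencies at seed positions 1-6 (logo matrix).

    Computed from integer expansion copies without literally replicating
    rows, but exactly equal to the tally over the expanded multiset.
    Returns a 4 x 6 DataFrame (rows A/C/G/U, columns pos1..pos6) whose
    columns each sum to 1.
    """
    copies = _copies(table[weight_column].to_numpy(dtype=float), cfg.divisor)
    total = int(copies.sum())
    if total == 0:
        raise ValueError("zero total expanded weight; no composition defined")
    matrix = np.zeros((len(NUCLEOTIDES), 6), dtype=np.int64)
    nt_index = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for seed, c in zip(table["seed"], copies):
        if c == 0:
            continue
        for pos, nt in enumerate(seed):
            matrix[nt_index[nt], pos] += c
    freq = matrix / total
    return pd.DataFrame(
        freq, index=list(NUCLEOTIDES), columns=[f"pos{i}" for i in range(1, 7)]
    )


def box_stats_frame(stats_by_group: dict[str, BoxStats]) -> pd.DataFrame:
    """Tabulate BoxStats per group for TSV output."""
    rows = []
    for name, bs in stats_by_group.items():
        rows.append(
            {
                "group": name,
                "n": bs.n,
                "median": bs.median,
                "q1": bs.q1,
                "q3": bs.q3,
                "whisker_low": bs.whisker_low,
                "whisker_high": bs.whisker_high,
                "n_outliers": len(bs.outliers),
            }
        )
    return pd.DataFrame(rows)
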