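"""Per-sample normalization and two-group differential selection.

Normalization scales every sample column to 1,000,000 total reads.
Differential selection runs a per-row two-sided equal-variance Student
t-test between the two groups on normalized counts and keeps rows with
p below alpha, reporting the delta read count (perturbed mean minus
control mean).  No multiple-testing correction is applied: the retained
set is defined by the per-row p < alpha rule, stated as-is in the output
metadata rather than silently "improved".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import sample_columns

logger = logging.getLogger(__name__)

NORM_TOTAL = 1_000_000.0

TestName = Literal["student", "welch"]


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to one million total reads.

    Annotation columns are passed through untouched.  Sample columns
    whose raw total is zero are left all-zero with a warning.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty count table")
    out = table.copy()
    for col in sample_columns(table):
        total = float(table[col].sum())
        if total == 0:
            logger.warning("sample %s has zero total reads; column left at zero", col)
            out[col] = 0.0
        else:
            out[col] = table[col].to_numpy(dtype=float) * (NORM_TOTAL / total)
    return out


@dataclass(frozen=True)
class DifferentialResult:
    """Retained rows plus the metadata needed to reproduce the selection."""

    table: pd.DataFrame
    test: str
    alpha: float
    control_samples: tuple[str, ...]
    perturbed_samples: tuple[str, ...]
    n_tested: int
    n_skipped_constant: int


def _student_p(ctrl: np.ndarray, pert: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values, row-wise.

    Rows with zero pooled variance get p = 0 when the means differ (the
    t statistic is infinite); equal-mean constant rows are handled by the
    caller and never reach the p-value.
    """
    n1, n2 = ctrl.shape[1], pert.shape[1]
    dof = n1 + n2 - 2
    v1 = ctrl.var(axis=1, ddof=1)
    v2 = pert.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
    diff = pert.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[np.isinf(t)] = 0.0
    return p


def differential(
    norm: pd.DataFrame,
    control_samples: Sequence[str],
    perturbed_samples: Sequence[str],
    alpha: float = 0.05,
    test: TestName = "student",
) -> DifferentialResult:
    """Select differentially loaded rows and express them as delta read counts.

    delta = mean(perturbed) - mean(control) on normalized counts; rows
    with p < alpha are retained.  Rows that are constant at the same
    value in both groups carry no evidence and are skipped with a logged
    count (a t statistic is undefined there).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for name, group in (("control", control_samples), ("perturbed", perturbed_samples)):
        if len(group) < 2:
            raise ValueError(
                f"{name} group has {len(group)} sample(s); >= 2 are required to"
                " estimate within-group variance"
            )
        missing = [s for s in group if s not in norm.columns]
        if missing:
            raise ValueError(f"{name} samples not in table: {missing}")

    ctrl = norm[list(control_samples)].to_numpy(dtype=float)
    pert = norm[list(perturbed_samples)].to_numpy(dtype=float)

    both_constant = (ctrl.var(axis=1) == 0) & (pert.var(axis=1) == 0)
    skipped = both_constant & (ctrl.mean(axis=1) == pert.mean(axis=1))
    n_skipped = int(skipped.sum())
    if n_skipped:
        logger.info("differential skipped %d rows constant in both groups", n_skipped)

    if test == "student":
        p = _student_p(ctrl, pert)
    elif test == "welch":
        p = stats.ttest_ind(pert, ctrl, axis=1, equal_var=False).pvalue
        p = np.where(both_constant & ~skipped, 0.0, p)
    else:
        raise ValueError(f"unknown test {test!r}")

    retained = ~skipped & (p < alpha)
    out = norm.loc[retained].copy()
    out["mean_control"] = ctrl.mean(axis=1)[retained]
    out["mean_perturbed"] = pert.mean(axis=1)[retained]
    out["delta"] = out["mean_perturbed"] - out["mean_control"]
    out["p"] = p[retained]
    return DifferentialResult(
        table=out,
        test=test,
        alpha=alpha,
        control_samples=tuple(control_samples),
        perturbed_samples=tuple(perturbed_samples),
        n_tested=int(len(norm) - n_skipped),
        n_skipped_constant=n_skipped,
    )


def write_differential(result: DifferentialResult, path) -> None:
    """Write the differential table as TSV with a ``#``-prefixed metadata block."""
    with open(path, "w") as handle:
        handle.write(f"# test: {result.test} (two-sided)\n")
        handle.write(f"# alpha: {result.alpha}\n")
        handle.write(f"# control: {','.join(result.control_samples)}\n")
        handle.write(f"# perturbed: {','.join(result.perturbed_samples)}\n")
        handle.write(f"# rows_tested: {result.n_tested}\n")
        handle.write(f"# rows_skipped_constant: {result.n_skipped_constant}\n")
        result.table.to_csv(handle, sep="\t", float_format="%.10g")
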