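"""Cohort-level aggregation of per-sample association scores.

Each image/sample yields one normalized association score; a cohort
(e.g. all images from one mouse genotype, or all images from donors aged 63-73) is
summarized by the mean score, the sample standard deviation (the figure
error bars) and a t-based 95% confidence interval for the mean — the
standard interval for the 4-9 samples per group typical of such studies.
A cohort is called "association" when the CI lies entirely above zero,
"repulsion" entirely below, "none" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ModeMismatchError

__all__ = ["GroupSummary", "summarize_group", "summarize_results",
           "compare_groups"]


@dataclass
class GroupSummary:
    """Per-sample scores aggregated to cohort level."""

    group_label: str
    scores: np.ndarray
    n_samples: int
    mean_score: float
    sd_score: float
    ci95: tuple | None
    association_call: str
    mode: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.ci95 is not None:
            self.ci95 = (float(self.ci95[0]), float(self.ci95[1]))

    def summary(self):
        ci = (
            f"({self.ci95[0]:.4g}, {self.ci95[1]:.4g})"
            if self.ci95 is not None else "n/a (n < 2)"
        )
        lines = [
            "Cohort Association Summary",
            "=" * 46,
            f"{'Group:':<24}{self.group_label:>22}",
            f"{'Samples:':<24}{self.n_samples:>22d}",
            f"{'Mean score:':<24}{self.mean_score:>22.4f}",
            f"{'s.d. (error bars):':<24}{self.sd_score:>22.4f}",
            f"{'95% CI of the mean:':<24}{ci:>22}",
            f"{'Call:':<24}{self.association_call:>22}",
            "=" * 46,
        ]
        return "\n".join(lines)


def summarize_group(scores, group_label, mode="") -> GroupSummary:
    """Mean, sample s.d. and t-based 95% CI of per-sample scores.

    CI: ``mean ± t_{0.975, n-1} * sd / sqrt(n)``; undefined for n = 1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("at least one score is required")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite score present")
    n = int(scores.size)
    mean = float(scores.mean())
    if n >= 2:
        sd = float(scores.std(ddof=1))
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - float(half), mean + float(half))
    else:
        sd = 0.0
        ci = None
    if ci is not None and ci[0] > 0:
        call = "association"
    elif ci is not None and ci[1] < 0:
        call = "repulsion"
    else:
        call = "none"
    return GroupSummary(
        group_label=group_label,
        scores=scores,
        n_samples=n,
        mean_score=mean,
        sd_score=sd,
        ci95=ci,
        association_call=call,
        mode=mode,
    )


def summarize_results(results, group_label) -> GroupSummary:
    """Aggregate AssociationResult objects, refusing to pool across modes."""
    modes = {r.observed.mode for r in results}
    if len(modes) > 1:
        raise ModeMismatchError(
            f"cannot pool scores across modes {sorted(modes)}"
        )
    return summarize_group(
        [r.score for r in results], group_label, mode=modes.pop()
    )


def compare_groups(a: GroupSummary, b: GroupSummary):
    """Welch two-sample t-test on the score vectors.

    Returns ``(mean_difference, p_value)`` with the difference taken as
    ``a - b``. Reported alongside, never instead of, the per-group CIs.
    Degenerate zero-variance pairs resolve to p = 1 for identical means
    and p = 0 otherwise.
    """
    if a.n_samples < 2 or b.n_samples < 2:
        raise ValueError("each group needs >= 2 samples")
    if a.mode and b.mode and a.mode != b.mode:
        raise ModeMismatchError(
            f"cannot compare groups of modes {a.mode!r} and {b.mode!r}"
        )
    diff = a.mean_score - b.mean_score
    if a.sd_score == 0 and b.sd_score == 0:
        return float(diff), 1.0 if diff == 0 else 0.0
    t = stats.ttest_ind(a.scores, b.scores, equal_var=False)
    return float(diff), float(t.pvalue)
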