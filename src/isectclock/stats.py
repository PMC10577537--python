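"""Group comparisons of predicted epigenetic ages and performance metrics.

A rejuvenation event is called when the mean predicted age drops between two
groups (e.g. consecutive developmental stages). Groups are compared with a
two-sided Student (equal-variance) t-test by default — Welch is available via
a flag — or a paired t-test when samples form explicit pairs (e.g. fibroblasts
and the iPSC lines derived from them). Only admitted samples (intersection
size at or above the threshold) enter any comparison. P-values are reported
raw, without multiple-testing correction, and coded with the conventional
significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .clock_core import PredictionResult


class InsufficientDataError(ValueError):
    """Fewer than two admitted samples (or pairs) in a group."""


class PairingError(ValueError):
    """Paired comparison requested but pairs are incomplete or ambiguous."""


@dataclass
class GroupComparison:
    """Two-sided t-test between the predicted ages of two sample groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    paired: bool
    stars: str


def star_code(p: float) -> str:
    """Significance stars: ns for p > 0.05, then one star per decade down to
    four stars at p <= 1e-4; upper band edges are inclusive."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p > 0.05:
        return "ns"
    if p > 1e-2:
        return "*"
    if p > 1e-3:
        return "**"
    if p > 1e-4:
        return "***"
    return "****"


def compare_groups(
    results: Sequence[PredictionResult],
    labels: Mapping[str, str],
    a: str,
    b: str,
    paired: bool = False,
    pairing_key: Mapping[str, str] | None = None,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare predicted ages between groups ``a`` and ``b``.

    ``labels`` maps sample_id to its group. Non-admitted samples are excluded.
    For a paired test, ``pairing_key`` maps sample_id to a pair identifier and
    each pair must contribute exactly one sample to each group; the test is a
    two-sided one-sample t-test on the per-pair differences (a - b).
    """
    admitted = {r.test_sample_id: r.predicted_age for r in results if r.admitted}
    ages_a = {sid: age for sid, age in admitted.items() if labels.get(sid) == a}
    ages_b = {sid: age for sid, age in admitted.items() if labels.get(sid) == b}
    if paired:
        if pairing_key is None:
            raise PairingError("paired comparison requires a pairing_key")
        pairs_a = {pairing_key[sid]: age for sid, age in ages_a.items() if sid in pairing_key}
        pairs_b = {pairing_key[sid]: age for sid, age in ages_b.items() if sid in pairing_key}
        common = sorted(set(pairs_a) & set(pairs_b))
        lone = (set(pairs_a) ^ set(pairs_b))
        if lone:
            raise PairingError(f"pair(s) missing a member in one group: {sorted(lone)}")
        if len(common) < 2:
            raise InsufficientDataError(
                f"paired comparison needs >= 2 complete pairs, got {len(common)}"
            )
        va = np.array([pairs_a[k] for k in common])
        vb = np.array([pairs_b[k] for k in common])
        t, p = _sps.ttest_rel(va, vb)
    else:
        va = np.array([ages_a[k] for k in sorted(ages_a)])
        vb = np.array([ages_b[k] for k in sorted(ages_b)])
        for label, v in ((a, va), (b, vb)):
            if len(v) < 2:
                raise InsufficientDataError(
                    f"group {label!r} has {len(v)} admitted samples; need >= 2"
                )
        t, p = _sps.ttest_ind(va, vb, equal_var=equal_var)
    t = float(t)
    p = float(p)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0
    return GroupComparison(
        group_a=a, group_b=b,
        n_a=len(va), n_b=len(vb),
        mean_a=float(va.mean()), mean_b=float(vb.mean()),
        statistic=t, p_value=p, paired=paired, stars=star_code(p),
    )


def performance_metrics(predicted: Sequence[float], true: Sequence[float]) -> tuple[float, float]:
    """Pearson r and median absolute error (years) of predictions vs true ages."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape or predicted.ndim != 1:
        raise ValueError("predicted and true ages must be equal-length 1-D vectors")
    if len(predicted) < 2:
        raise ValueError("need at least two samples")
    if np.ptp(predicted) == 0 or np.ptp(true) == 0:
        raise ValueError("Pearson r undefined: zero variance in predicted or true ages")
    r = float(_sps.pearsonr(predicted, true)[0])
    medae = float(np.median(np.abs(predicted - true)))
    return r, medae
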