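"""Pixel-level segmentation metrics and paired significance tests.

The metric suite treats object pixels as the positive class: Jaccard index
(JI), Dice coefficient (DC), volume similarity (VS), accuracy, precision,
recall, F1/F2, and power Pr(TP) = 1 - FN/(TP+FN).  Two paired tests compare
per-image metric samples between methods: a sign-flip randomization test
and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import as_binary_mask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "PairedSample",
    "confusion",
    "metric_suite",
    "power",
    "paired_randomization_test",
    "wilcoxon_signed",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    ji: float
    dc: float
    vs: float
    acc: float
    pre: float
    rec: float
    f1: float
    f2: float
    power: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ji": self.ji,
            "dc": self.dc,
            "vs": self.vs,
            "acc": self.acc,
            "pre": self.pre,
            "rec": self.rec,
            "f1": self.f1,
            "f2": self.f2,
            "power": self.power,
        }


@dataclass(frozen=True)
class PairedSample:
    """Equal-length per-image metric values for two methods."""

    values_a: tuple[float, ...]
    values_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values_a) != len(self.values_b):
            raise ValueError("paired samples must have equal length")
        if len(self.values_a) < 2:
            raise ValueError("paired samples need at least 2 pairs")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.values_a, dtype=float) - np.asarray(
            self.values_b, dtype=float
        )


def confusion(pred, truth) -> ConfusionCounts:
    """Pixelwise confusion counts with OBJECT as the positive class."""
    p = as_binary_mask(pred)
    t = as_binary_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def metric_suite(c: ConfusionCounts, f2_mode: str = "standard") -> MetricReport:
    """Full metric report from confusion counts.

    ``f2_mode="standard"`` uses the usual F-beta with beta=2,
    5*Pre*Rec/(4*Pre+Rec); ``"as_printed"`` uses 2*Pre*Rec/(4*Pre+Rec)
    for fidelity with an alternative published form.  Zero-denominator
    metrics are reported as NaN with a warning.
    """
    if f2_mode not in ("standard", "as_printed"):
        raise ValueError(f"unknown f2_mode {f2_mode!r}")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    ji = _ratio(tp, tp + fp + fn, "JI")
    dc = _ratio(2 * tp, 2 * tp + fp + fn, "DC")
    vs = 1.0 - _ratio(abs(fn - fp), 2 * tp + fp + fn, "VS")
    acc = _ratio(tp + tn, tp + tn + fp + fn, "Acc")
    pre = _ratio(tp, tp + fp, "Pre")
    rec = _ratio(tp, tp + fn, "Rec")
    f1 = _ratio(2 * rec * pre, pre + rec, "F1") if pre == pre and rec == rec else math.nan
    if pre == pre and rec == rec:  # NaN-safe
        num = (5.0 if f2_mode == "standard" else 2.0) * pre * rec
        f2 = _ratio(num, 4.0 * pre + rec, "F2")
    else:
        f2 = math.nan
    pw = power(c) if tp + fn > 0 else math.nan
    return MetricReport(ji=ji, dc=dc, vs=vs, acc=acc, pre=pre, rec=rec, f1=f1, f2=f2, power=pw)


def power(c: ConfusionCounts) -> float:
    """Pr(TP) = 1 - beta, the complement of the type-II error rate FN/(TP+FN)."""
    if c.tp + c.fn == 0:
        raise ValueError("power undefined when tp + fn = 0")
    return 1.0 - c.fn / (c.tp + c.fn)


def paired_randomization_test(
    sample: PairedSample,
    n_resamples: int = 2000,
    seed: int | None = None,
    method: str = "resample",
    alternative: str = "greater",
) -> float:
    """One-sided sign-flip permutation test on paired differences.

    The statistic is the mean difference; under the null each difference's
    sign is exchangeable.  ``method="exact"`` enumerates all 2^n sign
    patterns (n <= 20); ``"resample"`` draws ``n_resamples`` random sign
    patterns and reports the add-one p-value
    (1 + #{resampled mean >= observed}) / (1 + n_resamples).
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = sample.differences
    obs = d.mean()
    if alternative == "two-sided":
        obs = abs(obs)

    def stat(x):
        return np.abs(x) if alternative == "two-sided" else x

    if method == "exact":
        n = d.size
        if n > 20:
            raise ValueError("exact enumeration limited to 20 pairs")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        means = stat((signs * np.abs(d)).mean(axis=1))
        return float(np.mean(means >= obs - 1e-12))
    if method != "resample":
        raise ValueError(f"unknown method {method!r}")
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_resamples, d.size))
    means = stat((signs * np.abs(d)).mean(axis=1))
    hits = int(np.sum(means >= obs - 1e-12))
    return (1 + hits) / (1 + n_resamples)


def wilcoxon_signed(sample: PairedSample, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties get midranks.  The null distribution
    is enumerated exactly for up to 12 untied nonzero pairs, otherwise the
    normal approximation with continuity correction is used.  Returns
    (rank-sum statistic of positive differences, one-sided p by default).
    """
    d = sample.differences
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; no test possible")
    untied = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 12 and untied) else "approx"
    res = stats.wilcoxon(
        d, alternative=alternative, method=method, correction=(method == "approx")
    )
    return float(res.statistic), float(res.pvalue)
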