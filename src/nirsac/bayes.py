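"""JZS Bayes-factor t-tests and evidence classification.

The Bayes factor BF10 compares a Cauchy prior on the standardized effect size
(default scale sqrt(2)/2, the conventional "medium" prior) against the point
null, by numerical integration of the marginal likelihood over the prior's
scale-mixture representation.  Evidence categories follow the conventional
ten-step ladder with cut points 1/100, 1/30, 1/10, 1/3, 1, 3, 10, 30, 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate

MEDIUM_PRIOR = math.sqrt(2.0) / 2.0

EVIDENCE_LABELS = (
    "extreme_H0",
    "very_strong_H0",
    "strong_H0",
    "moderate_H0",
    "anecdotal_H0",
    "anecdotal_H1",
    "moderate_H1",
    "strong_H1",
    "very_strong_H1",
    "extreme_H1",
)

EVIDENCE_THRESHOLDS = (1 / 100, 1 / 30, 1 / 10, 1 / 3, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    t_statistic: float
    n: int
    cauchy_scale: float
    mode: str  # "one_sample" or "paired"
    degenerate: bool = False

    @property
    def evidence(self) -> str:
        return classify_evidence(self.bf10)


def jzs_bf10(t: float, n: int, cauchy_scale: float = MEDIUM_PRIOR) -> float:
    """JZS Bayes factor from a one-sample/paired t statistic.

    Integrates the g-prior mixture: with ``c = 1 + n*g*r^2``,

        BF10 = int_0^inf c^{-1/2} (1 + t^2/(c*nu))^{-(nu+1)/2} pi(g) dg
               / (1 + t^2/nu)^{-(nu+1)/2}

    where pi(g) is inverse-gamma(1/2, 1/2) and nu = n - 1.
    """
    if abs(t) > 1e6:
        # far beyond any representable Bayes factor for n >= 3
        return math.inf
    nu = n - 1
    r2 = cauchy_scale**2
    log_den = -(nu + 1) / 2.0 * math.log1p(t * t / nu)

    def log_ratio(g: float) -> float:
        c = 1.0 + n * g * r2
        log_num = (
            -0.5 * math.log(c)
            - (nu + 1) / 2.0 * math.log1p(t * t / (c * nu))
            - 0.5 * math.log(2 * math.pi)
            - 1.5 * math.log(g)
            - 1.0 / (2.0 * g)
        )
        return log_num - log_den

    # integrate in shifted log space so extreme t statistics cannot overflow
    shift = max(log_ratio(g) for g in (0.1, 1.0, 10.0, 100.0))
    val, _ = integrate.quad(
        lambda g: math.exp(min(log_ratio(g) - shift, 700.0)), 0, np.inf, limit=200
    )
    log_bf = shift + math.log(val) if val > 0 else -math.inf
    if log_bf > 700:
        return math.inf
    return float(math.exp(log_bf))


def bf_ttest(
    x: np.ndarray,
    y: np.ndarray | None = None,
    mode: str = "one_sample",
    cauchy_scale: float = MEDIUM_PRIOR,
) -> BayesResult:
    """One-sample or paired Bayes-factor t-test against a zero mean.

    Paired mode tests the element-wise differences ``x - y``.  Zero-variance
    all-zero differences are flagged degenerate and return the null-favoring
    BF at t = 0.
    """
    x = np.asarray(x, dtype=float)
    if mode == "paired":
        if y is None or len(y) != len(x):
            raise ValueError("paired mode needs equal-length x and y")
        d = x - np.asarray(y, dtype=float)
    elif mode == "one_sample":
        if y is not None:
            raise ValueError("one_sample mode takes a single sample")
        d = x
    else:
        raise ValueError("mode must be 'one_sample' or 'paired'")
    d = d[~np.isnan(d)]
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math.inf
        if math.isinf(t):
            return BayesResult(math.inf, t, n, cauchy_scale, mode, degenerate=True)
        return BayesResult(jzs_bf10(0.0, n, cauchy_scale), 0.0, n, cauchy_scale, mode, True)
    t = float(d.mean() / (sd / math.sqrt(n)))
    return BayesResult(jzs_bf10(t, n, cauchy_scale), t, n, cauchy_scale, mode)


def classify_evidence(bf10: float) -> str:
    """Step-function evidence category of a Bayes factor.

    Boundary values go to the stronger (further from 1) category; BF10 exactly
    1 counts as anecdotal evidence for H0.
    """
    if not bf10 > 0:
        raise ValueError("bf10 must be positive")
    if bf10 >= 100:
        return "extreme_H1"
    if bf10 >= 30:
        return "very_strong_H1"
    if bf10 >= 10:
        return "strong_H1"
    if bf10 >= 3:
        return "moderate_H1"
    if bf10 <= 1 / 100:
        return "extreme_H0"
    if bf10 <= 1 / 30:
        return "very_strong_H0"
    if bf10 <= 1 / 10:
        return "strong_H0"
    if bf10 <= 1 / 3:
        return "moderate_H0"
    return "anecdotal_H1" if bf10 > 1 else "anecdotal_H0"


def compare_cormats(
    cormats: dict[tuple[str, str, str], np.ndarray],
    methods: tuple[str, ...],
    tasks: tuple[str, ...],
    species: tuple[str, ...] = ("hbo", "hbr"),
    cauchy_scale: float = MEDIUM_PRIOR,
) -> pd.DataFrame:
    """Paired Bayes-factor t-tests between correlation matrices.

    For every pair of correction methods, task and species, the vectorized
    lower-triangular entries of the two group matrices are compared with a
    paired test (NaN pairs dropped listwise).  With 6 methods, 4 tasks and 2
    species this yields 15 x 4 x 2 = 120 tests.
    """
    rows = []
    for task in tasks:
        for sp in species:
            for m1, m2 in combinations(methods, 2):
                a = cormats[(m1, sp, task)]
                b = cormats[(m2, sp, task)]
                il = np.tril_indices(a.shape[0], k=-1)
                va, vb = a[il], b[il]
                ok = ~(np.isnan(va) | np.isnan(vb))
                if ok.sum() < 3:
                    rows.append(
                        dict(task=task, species=sp, method_a=m1, method_b=m2,
                             n_pairs=int(ok.sum()), bf10=np.nan, t=np.nan,
                             evidence="skipped")
                    )
                    continue
                res = bf_ttest(va[ok], vb[ok], mode="paired", cauchy_scale=cauchy_scale)
                rows.append(
                    dict(task=task, species=sp, method_a=m1, method_b=m2,
                         n_pairs=int(ok.sum()), bf10=res.bf10, t=res.t_statistic,
                         evidence=res.evidence)
                )
    return pd.DataFrame(rows)
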