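"""Consensus normality testing and routed two-sample comparison.

A sample is called normal only when Kolmogorov–Smirnov (with Lilliefors
correction for estimated parameters), Shapiro–Wilk and Anderson–Darling all
fail to reject at α = 0.05.  Two samples are compared with Welch's t test
when both pass the consensus, and with the Mann–Whitney U test otherwise;
significance at p < 0.05.  Trajectory series are subsampled on a 3-ns grid
before testing to thin autocorrelation and equalise sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors, normal_ad


class InsufficientSampleError(Exception):
    pass


@dataclass
class NormalityVerdict:
    p_ks: float
    p_shapiro: float
    p_anderson: float
    alpha: float
    consensus_normal: bool
    zero_variance: bool = False

    def as_dict(self) -> dict:
        return {
            "kolmogorov_smirnov_p": self.p_ks,
            "shapiro_wilk_p": self.p_shapiro,
            "anderson_darling_p": self.p_anderson,
            "alpha": self.alpha,
            "consensus_normal": self.consensus_normal,
            "zero_variance": self.zero_variance,
        }


def normality_consensus(sample, alpha: float = 0.05,
                        lilliefors_correction: bool = True) -> NormalityVerdict:
    """Three-test consensus; normal only if no test rejects at ``alpha``.

    ``lilliefors_correction=False`` runs the plain KS test against a normal
    fitted to the sample (anticonservative; provided for comparison).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        raise InsufficientSampleError(f"need n >= 8, got {len(x)}")
    if np.std(x) == 0:
        return NormalityVerdict(0.0, 0.0, 0.0, alpha, False, zero_variance=True)
    if lilliefors_correction:
        _, p_ks = lilliefors(x, dist="norm")
    else:
        _, p_ks = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    _, p_sw = sps.shapiro(x)
    _, p_ad = normal_ad(x)
    consensus = bool((p_ks > alpha) and (p_sw > alpha) and (p_ad > alpha))
    return NormalityVerdict(float(p_ks), float(p_sw), float(p_ad), alpha, consensus)


@dataclass
class ComparisonResult:
    test_used: str          # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    normality_a: NormalityVerdict
    normality_b: NormalityVerdict

    def as_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "median_a": self.median_a, "median_b": self.median_b,
            "normality_a": self.normality_a.as_dict(),
            "normality_b": self.normality_b.as_dict(),
        }


def compare(sample_a, sample_b, alpha: float = 0.05) -> ComparisonResult:
    """Route to Welch's t test (both normal) or Mann–Whitney U (otherwise)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na = normality_consensus(a, alpha)
    nb = normality_consensus(b, alpha)
    if na.consensus_normal and nb.consensus_normal:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        used = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann_whitney"
    return ComparisonResult(
        test_used=used, statistic=float(stat), p_value=float(p),
        significant=bool(p < alpha),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        normality_a=na, normality_b=nb,
    )


def summarize(series) -> tuple[float, float | None, float]:
    """(arithmetic mean, sample sd with n−1, median); sd is None for n = 1."""
    x = np.asarray(series, dtype=float)
    if len(x) < 1:
        raise ValueError("empty series")
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else None
    return float(np.mean(x)), sd, float(np.median(x))
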