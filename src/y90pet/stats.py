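"""Agreement and correlation statistics with patient-level clustering.

Lesions within a patient are correlated outcomes, so confidence intervals
for cohort-level statistics are computed by a cluster bootstrap: patients
are resampled with replacement and the statistic is recomputed on the
pooled lesions of the sampled patients (percentile 95% CI).  The mean
MS-vs-PS difference with a cluster-bootstrap CI is the package's substitute
for a random-intercept regression; it preserves the within-patient
correlation structure.

Lin's concordance correlation coefficient uses population (divide-by-n)
moments:  ccc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class DegenerateSampleError(ValueError):
    """Raised for samples without enough variation or clusters."""


@dataclass(frozen=True)
class PairedSample:
    """Per-lesion paired measurements with a patient (cluster) label."""

    x: np.ndarray
    y: np.ndarray
    cluster: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        cluster = np.asarray(self.cluster)
        if not (len(x) == len(y) == len(cluster)):
            raise ValueError("x, y and cluster must have equal lengths")
        if len(x) < 2:
            raise DegenerateSampleError("need at least two lesions")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "cluster", cluster)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    ccc: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def pearson(x, y) -> float:
    """Sample Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise DegenerateSampleError("need at least two observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSampleError("zero variance in one of the samples")
    return float(sps.pearsonr(x, y).statistic)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise DegenerateSampleError("need at least two observations")
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0  # both samples constant and identical
    return float(2.0 * sxy / denom)


def cluster_bootstrap(sample: PairedSample, statistic, n_boot: int = 2000,
                      seed: int = 0) -> tuple[float, float, float, np.ndarray]:
    """Patient-level bootstrap of a statistic of (x, y).

    Resamples clusters with replacement, recomputes ``statistic(x, y)`` on
    the pooled lesions of the sampled clusters, and returns the point
    estimate, the percentile 95% CI and the bootstrap distribution.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ids = np.unique(sample.cluster)
    if len(ids) < 2:
        raise DegenerateSampleError("cluster bootstrap needs at least two clusters")
    members = [np.nonzero(sample.cluster == c)[0] for c in ids]
    rng = np.random.default_rng(seed)
    estimate = float(statistic(sample.x, sample.y))
    boot = np.empty(n_boot)
    k = len(ids)
    for b in range(n_boot):
        take = rng.integers(0, k, size=k)
        idx = np.concatenate([members[t] for t in take])
        boot[b] = statistic(sample.x[idx], sample.y[idx])
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return estimate, float(ci_low), float(ci_high), boot


def paired_mean_difference(sample: PairedSample, n_boot: int = 2000,
                           seed: int = 0) -> AgreementResult:
    """Mean (y − x) with cluster-bootstrap CI and a sign-crossing p-value.

    The two-sided p-value is twice the smaller tail fraction of the
    bootstrap distribution on either side of zero.
    """
    est, lo, hi, boot = cluster_bootstrap(
        sample, lambda x, y: np.mean(y - x), n_boot=n_boot, seed=seed)
    if np.ptp(boot) == 0:
        p = 0.0 if est != 0 else 1.0
    else:
        frac_le = (np.count_nonzero(boot <= 0) + 1) / (len(boot) + 1)
        frac_ge = (np.count_nonzero(boot >= 0) + 1) / (len(boot) + 1)
        p = min(1.0, 2.0 * min(frac_le, frac_ge))
    try:
        r = pearson(sample.x, sample.y)
    except DegenerateSampleError:
        r = float("nan")  # constant metric: correlation undefined, CI still valid
    return AgreementResult(
        pearson_r=r,
        ccc=lin_ccc(sample.x, sample.y),
        mean_diff=est, ci_low=lo, ci_high=hi, p_value=float(p),
        n_boot=n_boot, seed=int(seed),
    )
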