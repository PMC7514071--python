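"""Seeded generators for the synthetic two-group benchmark scenarios.

Four families of scenarios probe complementary properties of a two-group
effect size:

1. **Shape benchmark** — six subsets with (near-)equal group means but
   clearly different distribution shapes: unimodal vs bimodal mixtures
   (balanced and 80/20), equal-mean normals with very different spread,
   and normal vs chi-square, plus mirrored variants.  A purely
   difference-based effect size is blind here.
2. **Extreme scenarios** — constant groups, identical groups, discrete
   resampled groups and a x10 rescaling, exercising zero-variance
   degeneracies and scale invariance.
3. **Component scans** — 100 subsets in which only the spread of one
   group grows (shape-only effect), and 100 in which only the mean of one
   group moves (location-only effect).
4. **Feature matrix** — a 20-variable, two-group data set: 10 pure-noise
   variables, 5 with increasing mean shifts (3..7), and 5 with
   mean-preserving bimodal shape changes of increasing mode separation
   (3..7); used for effect-size/Cohen's-d correlation analyses and for
   the classification experiment.

Generation is a pure function of (parameters, seed): the same call with
the same seed reproduces every array bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabeledSample

__all__ = [
    "ScenarioSpec",
    "SyntheticSubset",
    "Dataset4",
    "FULL_FEATURES",
    "REDUCED_FEATURES",
    "make_dataset1",
    "make_dataset2",
    "make_dataset3_variance_scan",
    "make_dataset3_mean_scan",
    "make_dataset4",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Provenance of one generated subset."""

    dataset_id: int
    subset_id: int
    n1: int
    n2: int
    parameters: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass(frozen=True)
class SyntheticSubset:
    name: str
    spec: ScenarioSpec
    sample: LabeledSample


def _subset(dataset_id, subset_id, name, x1, x2, seed=None, **parameters) -> SyntheticSubset:
    sample = LabeledSample.from_groups(x1, x2)
    spec = ScenarioSpec(dataset_id=dataset_id, subset_id=subset_id,
                        n1=len(sample.x1), n2=len(sample.x2),
                        parameters=dict(parameters), seed=seed)
    return SyntheticSubset(name=name, spec=spec, sample=sample)


def _bimodal(rng, n, offset, weight_low):
    """Gaussian mixture with unit-SD modes at -offset/+offset;
    ``weight_low`` is the share of mass in the low mode."""
    modes = rng.choice([-offset, offset], size=n, p=[weight_low, 1.0 - weight_low])
    return modes + rng.standard_normal(n)


def make_dataset1(seed: int = 0, n: int = 1000, mode_offset: float = 4.0,
                  chisq_df: float = 2.0) -> list[SyntheticSubset]:
    """Shape benchmark: equal central tendency, different shapes (6 subsets).

    1. moment-matched unimodal normal vs balanced (50/50) bimodal mixture
       with modes at -/+ ``mode_offset``;
    2. moment-matched unimodal normal vs 80/20 bimodal mixture;
    3. the mirror image of subset 2 (every value negated);
    4. standard normal vs a normal with the same mean and SD 4;
    5. chi-square (``chisq_df`` degrees of freedom) vs a normal matched
       to its mean and SD;
    6. the mirror image of subset 5.

    The unimodal comparison group in subsets 1 and 2 is matched to the
    mixture's mean *and* SD, so the groups differ essentially only in
    modality, not in any low-order moment.
    """
    rng = np.random.default_rng(seed)
    out: list[SyntheticSubset] = []

    # subset 1: balanced mixture; mixture mean 0, var 1 + offset^2
    sd_mix = float(np.sqrt(1.0 + mode_offset ** 2))
    g1 = rng.normal(0.0, sd_mix, n)
    g2 = _bimodal(rng, n, mode_offset, 0.5)
    out.append(_subset(1, 1, "unimodal_vs_bimodal_50_50", g1, g2, seed=seed,
                       mode_offset=mode_offset, weight_low=0.5))

    # subset 2: 80/20 mixture; mean -0.6*offset, var 1 + offset^2 - mean^2
    mu = 0.8 * (-mode_offset) + 0.2 * mode_offset
    sd = float(np.sqrt(1.0 + mode_offset ** 2 - mu ** 2))
    g1 = rng.normal(mu, sd, n)
    g2 = _bimodal(rng, n, mode_offset, 0.8)
    out.append(_subset(1, 2, "unimodal_vs_bimodal_80_20", g1, g2, seed=seed,
                       mode_offset=mode_offset, weight_low=0.8))

    # subset 3: exact mirror of subset 2
    prev = out[-1].sample
    out.append(_subset(1, 3, "mirrored_80_20", -prev.x1, -prev.x2, seed=seed,
                       mirrored_of=2))

    # subset 4: same mean, SD 1 vs 4
    out.append(_subset(1, 4, "normal_sd1_vs_sd4",
                       rng.normal(0.0, 1.0, n), rng.normal(0.0, 4.0, n), seed=seed))

    # subset 5: chi-square vs moment-matched normal
    mean_chi = chisq_df
    sd_chi = float(np.sqrt(2.0 * chisq_df))
    g1 = rng.chisquare(chisq_df, n)
    g2 = rng.normal(mean_chi, sd_chi, n)
    out.append(_subset(1, 5, "chisquare_vs_normal", g1, g2, seed=seed, df=chisq_df))

    prev = out[-1].sample
    out.append(_subset(1, 6, "mirrored_chisquare", -prev.x1, -prev.x2, seed=seed,
                       mirrored_of=5))
    return out


def make_dataset2(seed: int = 0, n: int = 100) -> list[SyntheticSubset]:
    """Extreme scenarios (6 subsets), n=100 per group.

    X1: the constant 1 in both groups; X2: constant 1 vs constant 2;
    X3: both groups the sequence 1..5 repeated 20 times (identical);
    X4: independent resampling with replacement from 1..100 per group;
    X5 = 10 * X4 (scale-invariance probe); X6: constant 1 vs N(2, 2).
    """
    rng = np.random.default_rng(seed)
    ones = np.ones(n)
    seq = np.tile(np.arange(1.0, 6.0), n // 5)
    x4_g1 = rng.choice(np.arange(1.0, 101.0), size=n, replace=True)
    x4_g2 = rng.choice(np.arange(1.0, 101.0), size=n, replace=True)
    return [
        _subset(2, 1, "constant_both", ones, ones.copy(), seed=seed),
        _subset(2, 2, "constant_1_vs_2", ones, 2.0 * ones, seed=seed),
        _subset(2, 3, "identical_sequences", seq, seq.copy(), seed=seed),
        _subset(2, 4, "resampled_1_100", x4_g1, x4_g2, seed=seed),
        _subset(2, 5, "resampled_x10", 10.0 * x4_g1, 10.0 * x4_g2, seed=seed),
        _subset(2, 6, "constant_vs_normal", ones, rng.normal(2.0, 2.0, n), seed=seed),
    ]


def make_dataset3_variance_scan(seed: int = 0, n: int = 100,
                                sigmas=range(1, 101)) -> list[SyntheticSubset]:
    """Shape-only scan: both groups mean 1; group 2 SD sweeps 1..100."""
    rng = np.random.default_rng(seed)
    return [
        _subset(3, i, f"variance_scan_{s:03d}",
                rng.normal(1.0, 1.0, n), rng.normal(1.0, float(s), n),
                seed=seed, sigma2=float(s))
        for i, s in enumerate(sigmas, start=1)
    ]


def make_dataset3_mean_scan(seed: int = 0, n: int = 100,
                            means=range(1, 101)) -> list[SyntheticSubset]:
    """Location-only scan: both groups SD 5; group 1 mean 5, group 2 mean
    sweeps 1..100."""
    rng = np.random.default_rng(seed)
    return [
        _subset(3, i, f"mean_scan_{m:03d}",
                rng.normal(5.0, 5.0, n), rng.normal(float(m), 5.0, n),
                seed=seed, mean2=float(m))
        for i, m in enumerate(means, start=1)
    ]


#: variable names of the 20-variable feature matrix
FULL_FEATURES = [f"var{i:04d}" for i in range(1, 21)]
#: the feature set with the mean-shifted variables (11..15) removed
REDUCED_FEATURES = [f"var{i:04d}" for i in list(range(1, 11)) + list(range(16, 21))]


@dataclass(frozen=True)
class Dataset4:
    """20-variable two-group feature matrix.

    ``frame`` holds one column per variable (2n rows); ``labels`` is the
    matching group vector (1, 2).  Individual variables are available as
    :class:`LabeledSample` via :meth:`sample`.
    """

    frame: pd.DataFrame
    labels: np.ndarray
    seed: int

    def sample(self, name: str) -> LabeledSample:
        return LabeledSample.from_arrays(self.frame[name].to_numpy(), self.labels)

    @property
    def samples(self) -> dict[str, LabeledSample]:
        return {name: self.sample(name) for name in self.frame.columns}


def make_dataset4(seed: int = 0, n: int = 1000) -> Dataset4:
    """Feature matrix with three variable regimes, n per group.

    * var0001..var0010 — standard normal in both groups (pure noise);
    * var0011..var0015 — N(0,1) vs N(m,1) with m = 3..7 (location
      effects of increasing size);
    * var0016..var0020 — N(0,1) vs an exactly mean-zero symmetric
      bimodal mixture with unit-SD modes at -/+k, k = 3..7 (shape
      effects of increasing size).  Exact zero mean is enforced by
      mirroring: half the draws are generated around +k and concatenated
      with their negatives, so the group-2 sample mean is identically 0
      and its SD is close to sqrt(1 + k^2).
    """
    if n % 2:
        raise ValueError("n must be even (the bimodal groups are mirrored in halves)")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for i in range(1, 11):
        cols[f"var{i:04d}"] = np.concatenate(
            [rng.standard_normal(n), rng.standard_normal(n)])
    for i, m in zip(range(11, 16), range(3, 8)):
        cols[f"var{i:04d}"] = np.concatenate(
            [rng.standard_normal(n), rng.normal(float(m), 1.0, n)])
    for i, k in zip(range(16, 21), range(3, 8)):
        half = rng.normal(float(k), 1.0, n // 2)
        bimodal = np.concatenate([half, -half])  # mirrored: mean is 0 by construction
        cols[f"var{i:04d}"] = np.concatenate([rng.standard_normal(n), bimodal])
    labels = np.concatenate([np.full(n, 1), np.full(n, 2)])
    return Dataset4(frame=pd.DataFrame(cols), labels=labels, seed=seed)
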