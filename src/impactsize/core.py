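"""Core formulas of the Impact effect size and a reference Cohen's d.

Impact compares two groups X1, X2 of univariate measurements and returns a
signed effect size built from two components:

* a **central-tendency component** ``CTdiff``: the absolute difference of
  the group medians normalized by the pooled Gini mean difference (GMD), a
  robust, non-parametric analogue of the standardized mean difference;
* a **shape ("morphic") component** ``MorphDiff``: the integral of the
  absolute difference between the two groups' estimated probability
  densities, bounded above by 2 for two unit-mass densities.

The two are blended by a convex weight ``min(CTdiff, 2) / 2``: once the
median shift reaches two pooled-GMD units the weight saturates and Impact
reduces to the (unbounded) central-tendency component alone; for small
median shifts the shape component dominates.  Each component carries its
own sign — the median ordering for ``CTdiff``, the ordering of the mean
log-modulus-transformed values ("momentum") for ``MorphDiff``.

Impact is forced to exactly zero when a two-sample Kolmogorov-Smirnov test
cannot reject that the two groups share one distribution ("KS gate"),
so indistinguishable groups never receive a spurious effect.

Unlike Cohen's d, Impact stays finite when group variances vanish: the
pooled-GMD case ladder falls back to the pooled-sample GMD and finally to
a small epsilon, so constant groups yield well-defined values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .density import DensityPair, estimate_pdf_pair

__all__ = [
    "ImpactConfig",
    "ImpactResult",
    "LabeledSample",
    "UndefinedEffectSizeError",
    "gmd",
    "pooled_gmd",
    "ct_diff",
    "dir_ct",
    "ct_weight",
    "log_modulus",
    "momentum",
    "dir_morph",
    "morph_diff",
    "ks_gate",
    "compute_impact",
    "impact",
    "cohens_d",
]


class UndefinedEffectSizeError(ValueError):
    """Cohen's d has no value when the pooled standard deviation is zero.

    Raised instead of silently returning NaN or infinity: a degenerate
    standardized mean difference must surface as "undefined" so that it is
    never mistaken for a measured effect.
    """


def _vector(values, name: str = "values") -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must contain only finite values")
    return x


@dataclass(frozen=True)
class ImpactConfig:
    """Tunable parameters of the Impact computation.

    Parameters
    ----------
    alpha_gate :
        Significance level of the two-sample Kolmogorov-Smirnov gate; if
        the KS p-value is at or above this level the groups are treated as
        indistinguishable and Impact is set to 0.
    epsilon :
        Positive fallback for the pooled GMD when the *entire* pooled
        sample has zero variance (0 < epsilon << 1).
    density_method :
        ``"pde"`` (Pareto density estimation, default) or ``"kde"``
        (Gaussian kernel, Silverman bandwidth).
    grid_points :
        Number of shared evaluation points for the density pair.
    pareto_percentile :
        Percentile of the pairwise-distance distribution used as the
        Pareto radius.
    distance_subsample_cap :
        Above this pooled sample size the pairwise-distance quantile is
        taken on a seeded subsample of this size.
    seed :
        Seed for the distance subsampling (the only stochastic step).
    absolute_value :
        Report |Impact| instead of the signed value.  For symmetric shape
        changes the sign is essentially arbitrary (it hinges on tiny
        median or momentum differences), so the magnitude is often the
        more honest summary.
    """

    alpha_gate: float = 0.05
    epsilon: float = 1e-7
    density_method: str = "pde"
    grid_points: int = 512
    pareto_percentile: float = 18.0
    distance_subsample_cap: int = 5000
    seed: int = 0
    absolute_value: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_gate < 1.0:
            raise ValueError("alpha_gate must be in (0, 1)")
        if not 0.0 < self.epsilon < 1e-2:
            raise ValueError("epsilon must be a small positive number")
        if self.density_method not in ("pde", "kde"):
            raise ValueError("density_method must be 'pde' or 'kde'")
        if self.grid_points < 32:
            raise ValueError("grid_points must be >= 32")
        if not 0.0 < self.pareto_percentile < 100.0:
            raise ValueError("pareto_percentile must be in (0, 100)")
        if self.distance_subsample_cap < 2:
            raise ValueError("distance_subsample_cap must be >= 2")


@dataclass(frozen=True)
class LabeledSample:
    """Univariate two-group data: numeric values plus binary group labels.

    ``levels`` fixes which label plays the role of group 1 (X1) and group
    2 (X2); the sign of Impact depends on that ordering.
    """

    values: np.ndarray
    labels: np.ndarray
    levels: tuple

    @classmethod
    def from_arrays(cls, values, labels, levels=None, order: str = "sorted") -> "LabeledSample":
        """Build and validate a sample from parallel value/label arrays.

        ``order`` chooses the default group ordering when ``levels`` is
        not given: ``"sorted"`` (default) or ``"appearance"``.
        """
        x = _vector(values)
        lab = np.asarray(labels).ravel()
        if lab.size != x.size:
            raise ValueError(
                f"values (n={x.size}) and labels (n={lab.size}) must have the same length"
            )
        uniq, first = np.unique(lab, return_index=True)
        if uniq.size != 2:
            raise ValueError(
                f"labels must have exactly 2 distinct levels, found {uniq.size}: {list(uniq)}"
            )
        if levels is not None:
            if set(levels) != set(uniq.tolist()) or len(levels) != 2:
                raise ValueError(f"levels {levels!r} do not match labels present {list(uniq)}")
            ordered = tuple(levels)
        elif order == "appearance":
            ordered = tuple(uniq[np.argsort(first)])
        elif order == "sorted":
            ordered = tuple(uniq)
        else:
            raise ValueError("order must be 'sorted' or 'appearance'")
        return cls(values=x, labels=lab, levels=ordered)

    @classmethod
    def from_groups(cls, x1, x2, levels=(1, 2)) -> "LabeledSample":
        x1 = _vector(x1, "x1")
        x2 = _vector(x2, "x2")
        values = np.concatenate([x1, x2])
        labels = np.concatenate([np.full(x1.size, levels[0]), np.full(x2.size, levels[1])])
        return cls(values=values, labels=labels, levels=tuple(levels))

    @property
    def x1(self) -> np.ndarray:
        return self.values[self.labels == self.levels[0]]

    @property
    def x2(self) -> np.ndarray:
        return self.values[self.labels == self.levels[1]]

    def swapped(self) -> "LabeledSample":
        """Same data with the group roles exchanged (negates Impact)."""
        return LabeledSample(values=self.values, labels=self.labels,
                             levels=(self.levels[1], self.levels[0]))


@dataclass(frozen=True)
class ImpactResult:
    """Impact plus every intermediate component.

    ``impact = ct_weight * dir_ct * ct_diff + (1 - ct_weight) * dir_morph
    * morph_diff`` unless ``gated_zero`` is set, in which case
    ``impact == 0``.  The components are always reported, so the
    central-tendency and shape contributions can be inspected separately.
    """

    impact: float
    ct_diff: float
    morph_diff: float
    gmd_pooled: float
    ct_weight: float
    dir_ct: int
    dir_morph: int
    gate_pvalue: float
    gated_zero: bool

    def to_dict(self) -> dict:
        return asdict(self)


def gmd(values) -> float:
    """Gini's mean difference: mean of |x_i - x_j| over all ordered pairs.

    Uses the n^2 denominator (zero self-pairs included), not the unbiased
    n(n-1) form.  Computed exactly in O(n log n) via the sorted-order
    identity ``sum_{i<j} (x_(j) - x_(i)) = sum_k (2k - n - 1) x_(k)``.
    """
    x = _vector(values)
    n = x.size
    if n == 1:
        return 0.0
    xs = np.sort(x)
    k = np.arange(1, n + 1, dtype=float)
    total = float(np.dot(2.0 * k - n - 1.0, xs))
    return 2.0 * total / (n * n)


def pooled_gmd(x1, x2, epsilon: float = 1e-7) -> float:
    """Pooled variability as a case ladder over group/pooled variances.

    * both group variances positive: quadratic (rms) mean of the two group
      GMDs — the group-size-independent pooling;
    * one group constant but the pooled sample not: GMD of the pooled
      sample;
    * pooled sample constant: ``epsilon``.

    Always strictly positive, so the normalized median difference is
    defined even for zero-variance groups.
    """
    x1 = _vector(x1, "x1")
    x2 = _vector(x2, "x2")
    if x1.var() > 0.0 and x2.var() > 0.0:
        return float(np.sqrt((gmd(x1) ** 2 + gmd(x2) ** 2) / 2.0))
    pooled = np.concatenate([x1, x2])
    if pooled.var() > 0.0:
        return gmd(pooled)
    return float(epsilon)


def ct_diff(x1, x2, gmd_pooled: float) -> float:
    """Absolute median difference in units of pooled GMD."""
    if gmd_pooled <= 0.0:
        raise ValueError("gmd_pooled must be positive")
    return float(abs(np.median(_vector(x2, "x2")) - np.median(_vector(x1, "x1"))) / gmd_pooled)


def dir_ct(x1, x2) -> int:
    """-1 if median(X2) < median(X1), else +1 (ties resolve to +1)."""
    return -1 if float(np.median(_vector(x2, "x2"))) < float(np.median(_vector(x1, "x1"))) else 1


def ct_weight(ct: float) -> float:
    """Convex weight min(CTdiff, 2)/2 balancing the two components.

    Saturates at 1 for CTdiff >= 2, matching the maximum of 2 attainable
    by the shape component; beyond saturation the shape term contributes
    exactly nothing.
    """
    if ct < 0.0:
        raise ValueError("ct_diff must be non-negative")
    return min(ct, 2.0) / 2.0


def log_modulus(values) -> np.ndarray:
    """Sign-preserving, zero-invariant log: sign(x) * log(|x| + 1)."""
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return np.sign(x) * np.log1p(np.abs(x))


def momentum(values) -> float:
    """Mean of the log-modulus-transformed values.

    A monotone location summary on the compressed scale; used only to
    order the two groups when choosing the sign of the shape component,
    so any monotone summary of L(x) would induce the same sign.
    """
    return float(np.mean(log_modulus(_vector(values))))


def dir_morph(x1, x2) -> int:
    """-1 if momentum(X2) < momentum(X1), else +1 (ties resolve to +1)."""
    return -1 if momentum(x2) < momentum(x1) else 1


def morph_diff(densities: DensityPair) -> float:
    """Integrated absolute density difference on the shared grid.

    For two unit-mass densities this total-variation-style distance is 0
    for identical densities and at most 2 (attained for disjoint
    supports).
    """
    return float(np.trapezoid(np.abs(densities.pdf2 - densities.pdf1), densities.grid))


def ks_gate(x1, x2, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sample two-sided Kolmogorov-Smirnov gate.

    Returns ``(pvalue, gated)`` where ``gated`` is True when the
    hypothesis of identical distributions cannot be rejected at level
    ``alpha`` (p >= alpha); a gated comparison forces Impact to 0.
    """
    res = stats.ks_2samp(_vector(x1, "x1"), _vector(x2, "x2"),
                         alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return p, p >= alpha


def compute_impact(sample: LabeledSample, config: ImpactConfig | None = None) -> ImpactResult:
    """Compute Impact and all of its components for a two-group sample.

    The components (normalized median difference, shape difference,
    pooled GMD, weight, directions, gate p-value) are reported even when
    the KS gate forces the headline value to zero.
    """
    cfg = config if config is not None else ImpactConfig()
    x1, x2 = sample.x1, sample.x2
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both groups must be non-empty")
    gate_p, gated = ks_gate(x1, x2, cfg.alpha_gate)
    g = pooled_gmd(x1, x2, cfg.epsilon)
    ct = ct_diff(x1, x2, g)
    w = ct_weight(ct)
    d_ct = dir_ct(x1, x2)
    d_mo = dir_morph(x1, x2)
    pair = estimate_pdf_pair(
        x1, x2,
        method=cfg.density_method,
        n_points=cfg.grid_points,
        percentile=cfg.pareto_percentile,
        cap=cfg.distance_subsample_cap,
        seed=cfg.seed,
    )
    mo = morph_diff(pair)
    value = 0.0 if gated else w * d_ct * ct + (1.0 - w) * d_mo * mo
    if cfg.absolute_value:
        value = abs(value)
    return ImpactResult(
        impact=float(value),
        ct_diff=ct,
        morph_diff=mo,
        gmd_pooled=g,
        ct_weight=w,
        dir_ct=d_ct,
        dir_morph=d_mo,
        gate_pvalue=gate_p,
        gated_zero=bool(gated),
    )


def impact(values, labels, **config_kwargs) -> ImpactResult:
    """Convenience front door: ``impact(Data, Cls)`` on raw arrays."""
    sample = LabeledSample.from_arrays(values, labels)
    return compute_impact(sample, ImpactConfig(**config_kwargs))


def cohens_d(x1, x2, pooling: str = "rms") -> float:
    """Classical standardized mean difference (mean2 - mean1) / SD_pooled.

    ``pooling="rms"`` divides by sqrt((SD1^2 + SD2^2) / 2), which is
    independent of the group sizes (and is the pooling that the Impact
    GMD ladder mirrors); ``pooling="n_weighted"`` uses the familiar
    sample-size-weighted pooled SD with n1 + n2 - 2 degrees of freedom.

    Raises
    ------
    UndefinedEffectSizeError
        If the pooled SD is zero (constant groups) — the statistic simply
        does not exist there and is never coerced to a number.
    """
    x1 = _vector(x1, "x1")
    x2 = _vector(x2, "x2")
    s1 = float(x1.std(ddof=1)) if x1.size > 1 else 0.0
    s2 = float(x2.std(ddof=1)) if x2.size > 1 else 0.0
    if pooling == "rms":
        sp = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    elif pooling == "n_weighted":
        dof = x1.size + x2.size - 2
        if dof <= 0:
            raise UndefinedEffectSizeError("need n1 + n2 > 2 for n-weighted pooling")
        sp = np.sqrt(((x1.size - 1) * s1 ** 2 + (x2.size - 1) * s2 ** 2) / dof)
    else:
        raise ValueError("pooling must be 'rms' or 'n_weighted'")
    if not sp > 0.0:
        raise UndefinedEffectSizeError("pooled standard deviation is zero; Cohen's d is undefined")
    return float((x2.mean() - x1.mean()) / sp)
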