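"""Distribution of observed per-nucleus FISH signal counts.

Each of the ``N`` true copies of a probe target is an independent point
placed uniformly in the nucleus; after sectioning, each signal survives
with the retention probability ``p`` of the section geometry.  The
observed per-nucleus count is therefore binomially thinned::

    n | N, p  ~  Binomial(N, p)

The same law applies to the target gene (e.g. HER2, MET) and the control
probe (CEP17, CEP7); since thinning scales both expectations by the same
``p``, the expected target/control *ratio* is unchanged by sectioning.

Two count laws are provided.  :func:`observed_pmf` is the mean-field
binomial ``Binomial(N, p̄)`` with the retention probability averaged over
the enumeration window — the convention behind the reference probability
curves, category grids and correction tables.  :func:`depth_mixture_pmf`
is the exact marginal under the same physical assumptions: conditional on
a nucleus at depth ``x`` the count is ``Binomial(N, V(x)/V₀)``, and the
marginal mixes these over the uniform depth.  Both have mean ``N·p̄``, but
the mixture is overdispersed (nuclei near the window edges retain little,
nuclei in the middle retain almost everything); the mean-field binomial
understates the spread at small thickness.  The Monte Carlo simulator
reproduces the mixture, not the mean-field binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    SectionSpec,
    enumeration_window,
    retained_volume,
    retention_probability,
    sphere_volume,
)

__all__ = [
    "CopyState",
    "CountsPMF",
    "ExpectedRatio",
    "MeanCountDistribution",
    "observed_pmf",
    "pmf_for_spec",
    "depth_mixture_pmf",
    "expected_observed",
    "expected_ratio",
    "mean_sampling_distribution",
    "probability_plot_data",
]


@dataclass(frozen=True)
class CopyState:
    """True per-nucleus copy numbers of target gene and control probe."""

    n_target: int  #: N_G, true target-gene copies
    n_control: int  #: N_C, true control-probe copies

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_control < 0:
            raise ValueError("copy numbers must be non-negative")


@dataclass(frozen=True)
class CountsPMF:
    """Probability mass function of the observed count of one probe.

    Support is ``0..N``; ``probs[n]`` is the probability of observing
    exactly ``n`` signals in an enumerated nucleus.
    """

    n_true: int
    p: float
    support: np.ndarray = field(repr=False)
    probs: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)

    @property
    def variance(self) -> float:
        return float((self.support - self.mean) ** 2 @ self.probs)

    def prob_at_least(self, k: float) -> float:
        """P(observed count ≥ k)."""
        return float(self.probs[self.support >= k].sum())

    def prob_between(self, lo: float, hi: float) -> float:
        """P(lo ≤ observed count < hi), half-open as in scoring guidelines."""
        mask = (self.support >= lo) & (self.support < hi)
        return float(self.probs[mask].sum())

    def prob_below(self, k: float) -> float:
        """P(observed count < k)."""
        return float(self.probs[self.support < k].sum())


def observed_pmf(n_true: int, p: float) -> CountsPMF:
    """Binomial pmf of the observed count given ``n_true`` copies and retention ``p``.

    One code path serves target and control probes (the thinning law is
    identical).  ``n_true`` must be an integer; this is the single-clone
    case — mixed populations with a fractional mean copy number are
    handled by :func:`expected_observed`.
    """
    if n_true < 0 or int(n_true) != n_true:
        raise ValueError(f"true copy number must be a non-negative integer, got {n_true}")
    if not 0 < p <= 1:
        raise ValueError(f"retention probability must be in (0, 1], got {p}")
    n_true = int(n_true)
    support = np.arange(n_true + 1)
    probs = stats.binom.pmf(support, n_true, p)
    return CountsPMF(n_true=n_true, p=p, support=support, probs=probs)


def pmf_for_spec(n_true: int, spec: SectionSpec) -> CountsPMF:
    """Observed-count pmf with ``p`` derived from the section geometry."""
    return observed_pmf(n_true, retention_probability(spec))


def depth_mixture_pmf(n_true: int, spec: SectionSpec) -> CountsPMF:
    """Exact marginal count pmf: depth-uniform mixture of conditional binomials.

    ``P(n) = (x2 − x1)⁻¹ ∫ Binomial(n; N, V(x)/V₀) dx`` over the
    enumeration window, evaluated by adaptive quadrature split at the
    geometric branch points.  Same mean ``N·p̄`` as :func:`observed_pmf`
    but overdispersed; this is the law the sectioning Monte Carlo follows.
    """
    if n_true < 0 or int(n_true) != n_true:
        raise ValueError(f"true copy number must be a non-negative integer, got {n_true}")
    from scipy.integrate import quad

    n_true = int(n_true)
    w = enumeration_window(spec)
    v0 = sphere_volume(spec.d)
    breaks = sorted({w.x1, w.x2, *(b for b in (spec.d, spec.t) if w.x1 < b < w.x2)})
    probs = np.empty(n_true + 1)
    for n in range(n_true + 1):
        total = 0.0
        for a, b in zip(breaks[:-1], breaks[1:]):
            val, _ = quad(
                lambda x: stats.binom.pmf(n, n_true, retained_volume(x, spec) / v0),
                a,
                b,
                epsabs=1e-12,
                epsrel=1e-10,
                limit=200,
            )
            total += val
        probs[n] = total / w.width
    probs /= probs.sum()  # remove residual quadrature error
    p_bar = retention_probability(spec)
    return CountsPMF(n_true=n_true, p=p_bar, support=np.arange(n_true + 1), probs=probs)


def expected_observed(n_true: float, spec: SectionSpec) -> float:
    """Expected observed per-nucleus count ``N·p(spec)``.

    Accepts real-valued ``n_true`` (the mean copy number of a mixed cell
    population); linear in ``n_true``.
    """
    if n_true < 0:
        raise ValueError("true copy number must be non-negative")
    return n_true * retention_probability(spec)


@dataclass(frozen=True)
class ExpectedRatio:
    """Target/control ratio of expectations.

    ``ratio_of_expectations`` flags that this is E[n_G]/E[n_C] — the
    quantity that is invariant under sectioning — not the expectation of
    the per-nucleus ratio n_G/n_C, which is undefined at n_C = 0.
    """

    value: float
    ratio_of_expectations: bool = True


def expected_ratio(state: CopyState, spec: SectionSpec | None = None) -> ExpectedRatio:
    """E[n_G]/E[n_C] = N_G/N_C — independent of section thickness.

    The retention probability multiplies both expectations, so it cancels;
    ``spec`` is accepted (for interface symmetry) but does not affect the
    value.
    """
    if state.n_control == 0:
        raise ValueError("control copy number must be positive to form a ratio")
    return ExpectedRatio(value=state.n_target / state.n_control)


@dataclass(frozen=True)
class MeanCountDistribution:
    """Sampling distribution of the mean observed count over ``m`` nuclei.

    Exact (m-fold convolution, support on multiples of 1/m) for small m;
    normal approximation N(N·p, N·p(1−p)/m) beyond the switchover.
    """

    n_true: int
    p: float
    m: int
    kind: str  #: "exact" or "normal"
    support: np.ndarray | None = field(default=None, repr=False)
    probs: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean(self) -> float:
        return self.n_true * self.p

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.n_true * self.p * (1.0 - self.p) / self.m))

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central probability interval of the m-nucleus mean, clipped at 0."""
        if self.kind == "normal":
            lo, hi = stats.norm.interval(level, loc=self.mean, scale=self.sd)
        else:
            cdf = np.cumsum(self.probs)
            alpha = (1.0 - level) / 2.0
            lo = float(self.support[np.searchsorted(cdf, alpha)])
            hi = float(self.support[np.searchsorted(cdf, 1.0 - alpha)])
        return max(lo, 0.0), hi


def mean_sampling_distribution(
    n_true: int, spec: SectionSpec, m: int, exact_max_m: int = 30
) -> MeanCountDistribution:
    """Distribution of the average observed count over ``m`` enumerated nuclei.

    Slide-level scoring averages 20–60 nuclei; this propagates the
    single-nucleus binomial to that average.  For ``m <= exact_max_m`` the
    exact convolution is returned (support ``0, 1/m, …, N``); above it, a
    normal approximation with the same first two moments.
    """
    if m < 1:
        raise ValueError("number of nuclei m must be >= 1")
    single = pmf_for_spec(n_true, spec)
    if m > exact_max_m:
        return MeanCountDistribution(n_true=single.n_true, p=single.p, m=m, kind="normal")
    probs = single.probs
    for _ in range(m - 1):
        probs = np.convolve(probs, single.probs)
    support = np.arange(single.n_true * m + 1) / m
    return MeanCountDistribution(
        n_true=single.n_true, p=single.p, m=m, kind="exact", support=support, probs=probs
    )


def probability_plot_data(n_true: int, specs: list[SectionSpec]) -> pd.DataFrame:
    """Long-format table of observed-count probabilities across section specs.

    One row per (spec, count): columns ``thickness_um``, ``diameter_um``,
    ``threshold_c``, ``n_observed``, ``probability``.  This is the data
    behind per-thickness probability curves and bubble plots.
    """
    if not specs:
        raise ValueError("at least one SectionSpec is required")
    frames = []
    for spec in specs:
        pmf = pmf_for_spec(n_true, spec)
        frames.append(
            pd.DataFrame(
                {
                    "thickness_um": spec.t,
                    "diameter_um": spec.d,
                    "threshold_c": spec.c,
                    "n_observed": pmf.support,
                    "probability": pmf.probs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
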