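"""Spherical-cap geometry of nuclei truncated by a microtome slab.

A formalin-fixed paraffin-embedded (FFPE) block is cut into a slab of
thickness ``t`` (μm).  Cell nuclei are modelled as spheres of diameter
``d`` (μm) whose vertical positions are uniform, so a nucleus that
intersects the slab is generally truncated: part of its volume — and a
proportional share of its FISH signals — is lost to the knife.

The depth coordinate ``x`` is the distance from the slab's *top* face to
the *lowest* point of the nucleus, measured downward.  The slab occupies
depths ``[0, t]``; a sphere of diameter ``d`` intersects it exactly when
``x ∈ [0, t + d]``.

A human scorer does not count every sliver: a nucleus is enumerated only
when its microscopic image diameter is at least a fraction ``c`` of the
full diameter (the *enumeration threshold*).  This restricts the depth to
the enumeration window ``[x1, x2]`` with::

    x1 = (d/2) (1 − √(1 − c²)),    x2 = t + (d/2) (1 + √(1 − c²))

Averaging the retained volume over that window and dividing by the full
sphere volume gives the *signal-retention probability*::

    p = V̄ / V₀

which is the per-signal probability that a uniformly placed signal
survives sectioning, averaged over enumerated nuclei.  All downstream
results (count distributions, misclassification grids, thin-section
corrections) are functions of ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "SectionSpec",
    "EnumerationWindow",
    "RetentionSummary",
    "sphere_volume",
    "cap_volume",
    "retained_volume",
    "enumeration_window",
    "mean_retained_volume",
    "retention_probability",
    "retention_summary",
    "image_diameter_fraction",
    "fraction_full_diameter",
    "fraction_image_at_least",
    "fraction_full_volume_given_image",
    "fraction_volume_at_least_given_image",
]


@dataclass(frozen=True)
class SectionSpec:
    """Governing parameters of a sectioning experiment.

    Parameters
    ----------
    t : float
        Section (slab) thickness, μm.  Must be positive.
    d : float
        Nuclear diameter, μm.  Must be positive.
    c : float
        Enumeration threshold: minimum image diameter, as a fraction of
        the full diameter, at which a scorer counts a nucleus.
        ``0 < c <= 1``; guideline scoring uses 0.8.
    """

    t: float
    d: float = 3.0
    c: float = 0.8

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError(f"section thickness t must be > 0, got {self.t}")
        if not self.d > 0:
            raise ValueError(f"nuclear diameter d must be > 0, got {self.d}")
        if not 0 < self.c <= 1:
            raise ValueError(f"enumeration threshold c must be in (0, 1], got {self.c}")

    @property
    def d_e(self) -> float:
        """Minimum acceptable image diameter ``c·d``, μm."""
        return self.c * self.d


@dataclass(frozen=True)
class EnumerationWindow:
    """Depth range ``[x1, x2]`` over which nuclei are enumerated."""

    x1: float
    x2: float

    @property
    def width(self) -> float:
        return self.x2 - self.x1


@dataclass(frozen=True)
class RetentionSummary:
    """Mean retained nuclear volume and signal-retention probability."""

    mean_volume: float  #: V̄, μm³, averaged over the enumeration window
    full_volume: float  #: V₀ = πd³/6, μm³
    p: float  #: retention probability V̄ / V₀


def sphere_volume(d: float) -> float:
    """Volume ``V₀ = πd³/6`` of a sphere of diameter ``d`` (μm³)."""
    if d < 0:
        raise ValueError(f"diameter must be non-negative, got {d}")
    return math.pi * d**3 / 6.0


def cap_volume(x: float, d: float) -> float:
    """Volume of a spherical cap of height ``x`` cut from a sphere of diameter ``d``.

    ``V_x = π((d/2)x² − x³/3)``; increases monotonically from 0 at
    ``x = 0`` to the full sphere volume at ``x = d``.
    """
    if not 0 <= x <= d:
        raise ValueError(f"cap height must lie in [0, d]=[0, {d}], got {x}")
    return math.pi * (0.5 * d * x * x - x**3 / 3.0)


def _cap(x: float, d: float) -> float:
    # unchecked cap volume, clamped to [0, d] for float-edge safety
    x = min(max(x, 0.0), d)
    return math.pi * (0.5 * d * x * x - x**3 / 3.0)


def retained_volume(x: float, spec: SectionSpec) -> float:
    """In-slab volume of a nucleus whose lowest point sits at depth ``x``.

    The retained region is the sphere minus the caps protruding above the
    top face and below the bottom face; equivalently::

        V(x) = cap(min(x, d)) − cap(clamp(x − t, 0, d))

    which reproduces both thickness regimes (``t ≥ d`` and ``t < d``) of
    the piecewise closed form.  Continuous in ``x``, symmetric about
    ``(t + d)/2``, and equal to ``V₀`` exactly on ``[d, t]`` (possible
    only when ``t ≥ d``).
    """
    t, d = spec.t, spec.d
    if not 0 <= x <= t + d:
        raise ValueError(f"depth must lie in [0, t+d]=[0, {t + d}], got {x}")
    return _cap(x, d) - _cap(x - t, d)


def enumeration_window(spec: SectionSpec) -> EnumerationWindow:
    """Depth window ``[x1, x2]`` of nuclei whose image diameter is ≥ ``c·d``."""
    half = 0.5 * spec.d
    s = math.sqrt(max(1.0 - spec.c * spec.c, 0.0))
    return EnumerationWindow(x1=half * (1.0 - s), x2=spec.t + half * (1.0 + s))


def _cap_antiderivative(x: float, d: float) -> float:
    # ∫0^x cap(u) du for x in [0, d]: π(d x³/6 − x⁴/12)
    return math.pi * (d * x**3 / 6.0 - x**4 / 12.0)


def _retained_antiderivative(x: float, spec: SectionSpec) -> float:
    """Exact antiderivative of ``retained_volume`` (piecewise quartic).

    A(x) = F(x) − F(x − t) with F(x) = ∫0^x cap(min(u, d)) du; the
    integrand of F is constant ``V₀`` past ``u = d``.
    """
    d = spec.d
    v0 = sphere_volume(d)

    def F(y: float) -> float:
        if y <= 0.0:
            return 0.0
        if y >= d:
            return _cap_antiderivative(d, d) + v0 * (y - d)
        return _cap_antiderivative(y, d)

    return F(x) - F(x - spec.t)


def mean_retained_volume(spec: SectionSpec) -> float:
    """Mean in-slab nuclear volume ``V̄`` over the enumeration window (μm³).

    Computed in closed form from the piecewise-quartic antiderivative of
    the retained-volume profile (the quadrature cross-check lives in the
    test suite, not here).
    """
    w = enumeration_window(spec)
    num = _retained_antiderivative(w.x2, spec) - _retained_antiderivative(w.x1, spec)
    return num / w.width


def retention_probability(spec: SectionSpec) -> float:
    """Signal-retention probability ``p = V̄ / V₀ ∈ (0, 1]``.

    Strictly increasing in ``t``; non-decreasing in ``c``; tends to 1 as
    the section becomes much thicker than the nucleus.
    """
    return mean_retained_volume(spec) / sphere_volume(spec.d)


def retention_summary(spec: SectionSpec) -> RetentionSummary:
    """Bundle ``V̄``, ``V₀`` and ``p`` for a spec."""
    vbar = mean_retained_volume(spec)
    v0 = sphere_volume(spec.d)
    return RetentionSummary(mean_volume=vbar, full_volume=v0, p=vbar / v0)


def image_diameter_fraction(x: float, spec: SectionSpec) -> float:
    """Largest in-slab cross-section diameter of a nucleus at depth ``x``, as a fraction of ``d``.

    Equals 1 exactly when the sphere's centre lies within the slab;
    otherwise it is the chord at the nearer slab face.  By construction it
    equals ``c`` at both edges of the enumeration window.
    """
    t, d = spec.t, spec.d
    if not 0 <= x <= t + d:
        raise ValueError(f"depth must lie in [0, t+d]=[0, {t + d}], got {x}")
    centre = x - 0.5 * d  # centre depth; may lie outside the slab
    if 0.0 <= centre <= t:
        return 1.0
    a = -centre if centre < 0 else centre - t  # distance centre → nearer face
    if a >= 0.5 * d:
        return 0.0
    return math.sqrt(max(1.0 - (2.0 * a / d) ** 2, 0.0))


def fraction_full_diameter(t: float, d: float) -> float:
    """Fraction of slab-intersecting nuclei whose image shows the full diameter.

    With the lowest point uniform over ``[0, t + d]``, the centre lies in
    the slab for a depth range of length ``t``, so the fraction is
    ``t / (t + d)``.
    """
    if t <= 0 or d <= 0:
        raise ValueError("t and d must be positive")
    return t / (t + d)


def fraction_image_at_least(t: float, d: float, c: float) -> float:
    """Fraction of slab-intersecting nuclei with image diameter ≥ ``c·d``.

    Window length over intersecting range: ``(t + d√(1−c²)) / (t + d)``.
    """
    spec = SectionSpec(t=t, d=d, c=c)
    w = enumeration_window(spec)
    return w.width / (t + d)


def fraction_full_volume_given_image(t: float, d: float, c: float) -> float:
    """Among enumerated nuclei, the fraction retaining their *full* volume.

    Full volume requires the whole sphere inside the slab (depth in
    ``[d, t]``), impossible for ``t ≤ d``: ``max(t − d, 0) / (x2 − x1)``.
    """
    spec = SectionSpec(t=t, d=d, c=c)
    w = enumeration_window(spec)
    return max(t - d, 0.0) / w.width


def fraction_volume_at_least_given_image(t: float, d: float, c: float, v: float) -> float:
    """Among enumerated nuclei, the fraction retaining at least a fraction ``v`` of their volume.

    The retained-volume profile rises monotonically to its midpoint
    ``(t + d)/2`` and is symmetric, so the qualifying depths form a
    central interval ``[xa, (t + d) − xa]`` found by bracketed root
    finding (tolerance 1e-10); for ``t ≥ d`` this reduces to the
    cap-height closed form ``xa = d − h`` with ``cap(h) = (1 − v)V₀``.
    The interval is clipped to the enumeration window.  Reduces to
    :func:`fraction_full_volume_given_image` at ``v = 1``.
    """
    if not 0 < v <= 1:
        raise ValueError(f"volume fraction v must be in (0, 1], got {v}")
    spec = SectionSpec(t=t, d=d, c=c)
    w = enumeration_window(spec)
    v0 = sphere_volume(d)
    target = v * v0
    mid = 0.5 * (t + d)
    vmax = retained_volume(mid, spec)
    if target > vmax:
        return 0.0
    if t >= d:
        # retained(x) = cap(x) on the rising branch; invert via the cap
        h = brentq(lambda hh: _cap(hh, d) - (1.0 - v) * v0, 0.0, d, xtol=1e-10)
        xa = d - h
    elif target <= retained_volume(0.0, spec):
        xa = 0.0
    else:
        xa = brentq(lambda xx: retained_volume(xx, spec) - target, 0.0, mid, xtol=1e-10)
    lo = max(xa, w.x1)
    hi = min((t + d) - xa, w.x2)
    return max(hi - lo, 0.0) / w.width
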