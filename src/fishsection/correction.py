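"""Thin-to-thick section correction of observed copy numbers.

Because the observed mean count is ``N·p(t)``, counts measured on an
improperly thin section (2–3 μm) can be rescaled to the value expected on
a guideline-thickness section (4–6 μm) by the ratio of retention
probabilities::

    n_corrected = n_observed · p(t_to) / p(t_from)

The correction is exact for the mean, linear in the observed value, and
transitive across thicknesses.  Interval estimates propagate the
finite-number-of-nuclei sampling error of slide-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import SectionSpec, retention_probability

__all__ = [
    "CorrectionRow",
    "correction_factor",
    "correct_observed",
    "estimate_true_copy_number",
    "correction_interval",
    "correction_table",
    "format_correction_table",
]


@dataclass(frozen=True)
class CorrectionRow:
    """One corrected cell: observed thin-section count → thick-section estimate."""

    observed: float
    t_from: float
    t_to: float
    corrected: float
    ci_low: float
    ci_high: float
    d: float
    c: float
    m: int


def correction_factor(t_from: float, t_to: float, d: float = 3.0, c: float = 0.8) -> float:
    """Ratio ``p(t_to) / p(t_from)`` rescaling a thin-section count.

    Equal to 1 when the thicknesses match; reciprocal under swapping the
    direction.
    """
    p_from = retention_probability(SectionSpec(t=t_from, d=d, c=c))
    p_to = retention_probability(SectionSpec(t=t_to, d=d, c=c))
    return p_to / p_from


def correct_observed(
    n_obs: float, t_from: float, t_to: float, d: float = 3.0, c: float = 0.8
) -> float:
    """Expected count on a ``t_to`` section given ``n_obs`` on a ``t_from`` section."""
    if n_obs < 0:
        raise ValueError("observed copy number must be non-negative")
    return n_obs * correction_factor(t_from, t_to, d=d, c=c)


def estimate_true_copy_number(n_obs: float, spec: SectionSpec) -> float:
    """Back-calculate the true mean copy number ``N̂ = n_obs / p(spec)``.

    Inverts the thinning mean, so correcting from a to b equals the
    expected observation of ``N̂`` on b.
    """
    if n_obs < 0:
        raise ValueError("observed copy number must be non-negative")
    return n_obs / retention_probability(spec)


def correction_interval(
    n_obs: float,
    t_from: float,
    t_to: float,
    d: float = 3.0,
    c: float = 0.8,
    m: int = 20,
    level: float = 0.95,
) -> tuple[float, float]:
    """Central interval for the ``m``-nucleus mean count on the target section.

    Normal approximation around the corrected point: with
    ``N̂ = n_obs / p(t_from)`` and ``q = p(t_to)``, the m-nucleus mean has
    mean ``N̂·q`` and variance ``N̂·q(1−q)/m``.  Width scales as 1/√m;
    clipped at 0.
    """
    if m < 1:
        raise ValueError("number of nuclei m must be >= 1")
    spec_from = SectionSpec(t=t_from, d=d, c=c)
    q = retention_probability(SectionSpec(t=t_to, d=d, c=c))
    n_hat = estimate_true_copy_number(n_obs, spec_from)
    mean = n_hat * q
    sd = np.sqrt(n_hat * q * (1.0 - q) / m)
    if sd == 0.0:
        return mean, mean
    lo, hi = stats.norm.interval(level, loc=mean, scale=sd)
    return max(float(lo), 0.0), float(hi)


def correction_table(
    t_from_list=(2.0, 3.0),
    t_to_list=(4.0, 5.0, 6.0),
    observed_grid=None,
    d: float = 3.0,
    c: float = 0.8,
    m: int = 20,
) -> pd.DataFrame:
    """Full correction table: observed thin-section counts → corrected values.

    Defaults reproduce the reference layout: observed 2.0–6.0 in steps of
    0.5 on 2 or 3 μm sections, corrected to 4, 5 and 6 μm.  Values are
    unrounded; use :func:`format_correction_table` for a 2-decimal
    facsimile.
    """
    if observed_grid is None:
        observed_grid = np.arange(2.0, 6.0 + 1e-9, 0.5)
    observed_grid = list(observed_grid)
    t_from_list = list(t_from_list)
    t_to_list = list(t_to_list)
    if not (observed_grid and t_from_list and t_to_list):
        raise ValueError("grids must be non-empty")
    rows = []
    for t_from in t_from_list:
        for obs in observed_grid:
            for t_to in t_to_list:
                corrected = correct_observed(obs, t_from, t_to, d=d, c=c)
                lo, hi = correction_interval(obs, t_from, t_to, d=d, c=c, m=m)
                rows.append(
                    {
                        "observed": obs,
                        "t_from_um": t_from,
                        "t_to_um": t_to,
                        "corrected": corrected,
                        "ci_low": lo,
                        "ci_high": hi,
                        "d_um": d,
                        "c": c,
                        "m": m,
                    }
                )
    return pd.DataFrame(rows)


def format_correction_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Rounded facsimile of the correction table (round-half-to-even).

    Rounding happens only here, at serialization — numeric consumers
    should use the unrounded :func:`correction_table` output.
    """
    out = table.copy()
    for col in ("corrected", "ci_low", "ci_high"):
        out[col] = out[col].round(decimals)
    return out
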