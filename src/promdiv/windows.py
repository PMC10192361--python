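"""Sliding event (Se) scores, the d statistic and chi-squared group contrasts.

Se is the sum of binary events in an 11-position window centred on each
position (5 nucleotides up- and downstream); edge windows are truncated
sums. Over the TATA-distal promoter window [-380, -30) — 350 positions —
the d statistic is the percentage of positions whose Se strictly exceeds
the average control Se (Se^C). Group-versus-control significance is a
1-degree-of-freedom chi-squared goodness-of-fit on the above/not-above
counts, Bonferroni-corrected across the group comparisons of one channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PROMOTER_WINDOW = (-380, -30)
DEFAULT_HALF_WINDOW = 5


class CoverageError(ValueError):
    """A profile does not cover the requested offset window."""


@dataclass
class SeProfile:
    """Sliding event scores for one gene and one channel on a TSS-offset grid."""

    gene_id: str
    channel: str
    positions: np.ndarray  # tss offsets, contiguous ascending
    se: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.se = np.asarray(self.se)
        if self.positions.shape != self.se.shape:
            raise ValueError("positions and se must have equal length")


@dataclass
class RegionStat:
    """d statistic and chi-squared contrast of one group against the control."""

    group: str
    channel: str
    N: int
    n_above: int
    d: float
    chi2: float
    p: float
    p_adj: float


def sliding_event_score(
    events,
    half_window: int = DEFAULT_HALF_WINDOW,
    positions=None,
    gene_id: str = "",
    channel: str = "all",
) -> SeProfile:
    """Windowed event sums: se[i] = sum of events over [i-hw, i+hw], truncated at edges."""
    ev = np.asarray(events, dtype=float)
    if ev.size == 0:
        raise ValueError("empty event channel")
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    kernel = np.ones(2 * half_window + 1)
    se = np.convolve(ev, kernel, mode="same")
    se = np.rint(se).astype(np.int64)
    if positions is None:
        positions = np.arange(ev.size)
    return SeProfile(gene_id=gene_id, channel=channel, positions=positions, se=se)


def promoter_window(profile: SeProfile, window: tuple[int, int] = PROMOTER_WINDOW) -> np.ndarray:
    """Se values restricted to the promoter window, in offset order."""
    lo, hi = window
    pos = profile.positions
    mask = (pos >= lo) & (pos < hi)
    if mask.sum() != hi - lo:
        raise CoverageError(
            f"profile covers [{pos.min()}, {pos.max()}], window [{lo}, {hi}) "
            f"needs {hi - lo} positions, found {int(mask.sum())}"
        )
    return profile.se[mask]


def control_threshold(
    control_profiles: Iterable[SeProfile], window: tuple[int, int] = PROMOTER_WINDOW
) -> float:
    """Se^C: flat mean of all control Se values across genes and window positions."""
    chunks = [promoter_window(p, window) for p in control_profiles]
    if not chunks:
        raise ValueError("need at least one control profile")
    return float(np.mean(np.concatenate(chunks)))


def d_statistic(window_values, sec: float) -> tuple[float, int, int]:
    """d = 100 * #{Se > Se^C} / N over the window values; ties count as not-above."""
    v = np.asarray(window_values)
    if v.size == 0:
        raise ValueError("N = 0: no window values")
    n_above = int(np.sum(v > sec))
    return 100.0 * n_above / v.size, n_above, int(v.size)


def chi_squared_vs_control(
    n_above: int,
    N: int,
    control_d: float,
    m_comparisons: int = 1,
    group: str = "",
    channel: str = "",
) -> RegionStat:
    """1-df goodness-of-fit of (above, not-above) counts against the control rate.

    Expected counts are N*control_d/100 and N*(1 - control_d/100);
    ``p_adj`` is Bonferroni: min(1, p * m_comparisons).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0.0 < control_d < 100.0):
        raise ValueError(f"degenerate control_d={control_d}: expected counts would be 0")
    exp_above = N * control_d / 100.0
    exp_below = N - exp_above
    chi2 = (n_above - exp_above) ** 2 / exp_above + ((N - n_above) - exp_below) ** 2 / exp_below
    p = float(stats.chi2.sf(chi2, df=1))
    return RegionStat(
        group=group,
        channel=channel,
        N=N,
        n_above=n_above,
        d=100.0 * n_above / N,
        chi2=float(chi2),
        p=p,
        p_adj=min(1.0, p * m_comparisons),
    )


def pooled_window_values(
    profiles: Iterable[SeProfile], window: tuple[int, int] = PROMOTER_WINDOW
) -> np.ndarray:
    """Concatenate promoter-window Se values across a group's genes."""
    return np.concatenate([promoter_window(p, window) for p in profiles])


def group_region_stats(
    profiles_by_group: Mapping[str, Sequence[SeProfile]],
    control_group: str,
    window: tuple[int, int] = PROMOTER_WINDOW,
    m_comparisons: int | None = None,
    channel: str = "",
) -> tuple[float, list[RegionStat]]:
    """d and chi-squared for every non-control group against the control.

    Returns (Se^C, stats); the control's own RegionStat is included first
    (chi2 = 0 by construction). ``m_comparisons`` defaults to the number of
    non-control groups.
    """
    if control_group not in profiles_by_group:
        raise KeyError(f"control group {control_group!r} missing")
    sec = control_threshold(profiles_by_group[control_group], window)
    control_vals = pooled_window_values(profiles_by_group[control_group], window)
    control_d, c_above, c_N = d_statistic(control_vals, sec)
    if m_comparisons is None:
        m_comparisons = max(1, len(profiles_by_group) - 1)
    out = [
        RegionStat(
            group=control_group, channel=channel, N=c_N, n_above=c_above,
            d=control_d, chi2=0.0, p=1.0, p_adj=1.0,
        )
    ]
    for group, profiles in profiles_by_group.items():
        if group == control_group:
            continue
        vals = pooled_window_values(profiles, window)
        d, n_above, N = d_statistic(vals, sec)
        out.append(
            chi_squared_vs_control(
                n_above, N, control_d, m_comparisons=m_comparisons,
                group=group, channel=channel,
            )
        )
    return sec, out


def heatmap_matrix(
    profiles_by_group: Mapping[str, Sequence[SeProfile]],
    window: tuple[int, int] = (-1000, 1000),
) -> pd.DataFrame:
    """Group-averaged Se per offset: one row per group, one column per position."""
    lo, hi = window
    rows = {}
    for group, profiles in profiles_by_group.items():
        if not profiles:
            raise ValueError(f"group {group!r} has no profiles")
        stack = np.vstack([promoter_window(p, (lo, hi)) for p in profiles])
        rows[group] = stack.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=np.arange(lo, hi))


def profiles_to_frame(profiles: Iterable[SeProfile]) -> pd.DataFrame:
    """Long-format Se table (gene_id, channel, tss_offset, se)."""
    frames = [
        pd.DataFrame(
            {"gene_id": p.gene_id, "channel": p.channel, "tss_offset": p.positions, "se": p.se}
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)


def region_stats_to_frame(stats_: Iterable[RegionStat]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats_])
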