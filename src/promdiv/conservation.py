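"""TSS-anchored conservation profiles and the d^P divergence statistic.

Per-base conservation scores (PhyloP-style, from bedGraph or fixed-step
wiggle tracks) are anchored at each gene's transcription start site as a
1300-position vector covering offsets -1000..+299 relative to the
transcription strand. Genes lacking any position in that span are omitted.
Group promoter conservation is compared by an unpaired t test on per-gene
window means, and by d^P — the percentage of window scores strictly below
the control promoter average p^C — with a 1-df chi-squared contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import GeneAnnotation
from .windows import PROMOTER_WINDOW

log = logging.getLogger(__name__)

TSS_SPAN = (-1000, 300)  # offsets covered by a TSSVector, half-open
TSS_LENGTH = TSS_SPAN[1] - TSS_SPAN[0]  # 1300


@dataclass
class ConservationTrack:
    """Sparse per-base scores on one or more contigs (0-based positions)."""

    scores: dict[str, dict[int, float]]

    def get(self, contig: str, position: int) -> float | None:
        return self.scores.get(contig, {}).get(position)

    def n_positions(self) -> int:
        return sum(len(d) for d in self.scores.values())


@dataclass
class TSSVector:
    """Strand-resolved conservation scores at offsets -1000..+299 from the TSS."""

    gene_id: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (TSS_LENGTH,):
            raise ValueError(
                f"TSSVector needs exactly {TSS_LENGTH} values, got {self.values.shape}"
            )
        if np.any(~np.isfinite(self.values)):
            raise ValueError("TSSVector values must be finite (genes with gaps are omitted)")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(*TSS_SPAN)

    def window(self, window: tuple[int, int] = PROMOTER_WINDOW) -> np.ndarray:
        lo, hi = window
        return self.values[lo - TSS_SPAN[0] : hi - TSS_SPAN[0]]


@dataclass
class DPStat:
    """d^P and its chi-squared contrast against the control below-rate."""

    group: str
    N: int
    n_below: int
    dP: float
    chi2: float
    p_value: float
    p_adj: float = 1.0


def read_scores(path) -> ConservationTrack:
    """Read a bedGraph or fixed-step wiggle file into a sparse track.

    bedGraph intervals are half-open and expanded per base; fixedStep
    declaration lines use the wiggle convention of 1-based starts.
    """
    scores: dict[str, dict[int, float]] = {}
    contig = None
    pos = step = span = None
    mode = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                try:
                    contig = fields["chrom"]
                    pos = int(fields["start"]) - 1  # wiggle starts are 1-based
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: bad fixedStep header: {exc}") from exc
                mode = "fixed"
                scores.setdefault(contig, {})
                continue
            if mode == "fixed":
                try:
                    value = float(line)
                except ValueError:
                    mode = None  # fall through to bedGraph parsing
                else:
                    for s in range(span):
                        scores[contig][pos + s] = value
                    pos += step
                    continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph fields, got {len(parts)}"
                )
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable bedGraph line") from exc
            d = scores.setdefault(chrom, {})
            for p in range(start, end):
                d[p] = value
    return ConservationTrack(scores=scores)


def write_bedgraph(track: ConservationTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal consecutive scores."""
    with open(path, "w") as fh:
        for contig in sorted(track.scores):
            d = track.scores[contig]
            positions = sorted(d)
            i = 0
            while i < len(positions):
                start = positions[i]
                value = d[start]
                j = i
                while (
                    j + 1 < len(positions)
                    and positions[j + 1] == positions[j] + 1
                    and d[positions[j + 1]] == value
                ):
                    j += 1
                fh.write(f"{contig}\t{start}\t{positions[j] + 1}\t{value:g}\n")
                i = j + 1


def anchor_scores_to_tss(
    track: ConservationTrack, annotations: Sequence[GeneAnnotation]
) -> list[TSSVector]:
    """1300-position TSS vectors per gene; genes missing any base are omitted.

    Offset o maps to genome coordinate tss + o on the + strand and tss - o
    on the - strand (upstream = larger genome coordinates there).
    """
    vectors: list[TSSVector] = []
    for ann in annotations:
        sign = 1 if ann.strand == "+" else -1
        values = np.empty(TSS_LENGTH)
        ok = True
        for i, o in enumerate(range(*TSS_SPAN)):
            v = track.get(ann.contig, ann.tss + sign * o)
            if v is None:
                ok = False
                break
            values[i] = v
        if ok:
            vectors.append(TSSVector(gene_id=ann.gene_id, group=ann.group, values=values))
        else:
            log.info("gene %s omitted: incomplete conservation data in TSS span", ann.gene_id)
    return vectors


def group_mean_profile(vectors: Sequence[TSSVector]) -> np.ndarray:
    """Arithmetic mean score per offset across a group's genes."""
    if not vectors:
        raise ValueError("empty group")
    return np.vstack([v.values for v in vectors]).mean(axis=0)


def profiles_to_frame(vectors_by_group: Mapping[str, Sequence[TSSVector]]) -> pd.DataFrame:
    frames = []
    for group, vectors in vectors_by_group.items():
        mean = group_mean_profile(vectors)
        frames.append(
            pd.DataFrame({"group": group, "tss_offset": np.arange(*TSS_SPAN), "mean_score": mean})
        )
    return pd.concat(frames, ignore_index=True)


def promoter_mean_ttest(
    group_a: Sequence[TSSVector],
    group_b: Sequence[TSSVector],
    window: tuple[int, int] = PROMOTER_WINDOW,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Unpaired t test on per-gene promoter-window mean scores."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 genes (variance undefined otherwise)")
    means_a = [float(v.window(window).mean()) for v in group_a]
    means_b = [float(v.window(window).mean()) for v in group_b]
    t, p = stats.ttest_ind(means_a, means_b, equal_var=equal_var)
    return float(t), float(p)


def dP_statistic(
    scores,
    p_c: float,
    control_below_prop: float,
    m_comparisons: int = 1,
    group: str = "",
) -> DPStat:
    """d^P = 100 * #{score < p^C} / N, with a 1-df chi-squared contrast.

    Observed (below, not-below) counts are tested against the control
    group's own below-threshold proportion; ties count as not-below.
    """
    v = np.asarray(scores, dtype=float)
    if v.size == 0:
        raise ValueError("N = 0: no scores in window")
    if not (0.0 < control_below_prop < 1.0):
        raise ValueError(f"degenerate control proportion {control_below_prop}")
    n_below = int(np.sum(v < p_c))
    N = int(v.size)
    exp_below = N * control_below_prop
    exp_above = N - exp_below
    chi2 = (n_below - exp_below) ** 2 / exp_below + ((N - n_below) - exp_above) ** 2 / exp_above
    p = float(stats.chi2.sf(chi2, df=1))
    return DPStat(
        group=group,
        N=N,
        n_below=n_below,
        dP=100.0 * n_below / N,
        chi2=float(chi2),
        p_value=p,
        p_adj=min(1.0, p * m_comparisons),
    )


def dp_contrast(
    vectors_by_group: Mapping[str, Sequence[TSSVector]],
    control_group: str,
    window: tuple[int, int] = PROMOTER_WINDOW,
    m_comparisons: int | None = None,
) -> dict[str, DPStat]:
    """d^P per group against the control group's promoter mean p^C.

    p^C is the flat mean of the control group's window scores; the control's
    own below-proportion defines the chi-squared expectation.
    """
    if control_group not in vectors_by_group:
        raise KeyError(f"control group {control_group!r} missing")
    control_scores = np.concatenate(
        [v.window(window) for v in vectors_by_group[control_group]]
    )
    p_c = float(control_scores.mean())
    control_prop = float(np.mean(control_scores < p_c))
    if m_comparisons is None:
        m_comparisons = max(1, len(vectors_by_group) - 1)
    out: dict[str, DPStat] = {}
    for group, vectors in vectors_by_group.items():
        scores = np.concatenate([v.window(window) for v in vectors])
        out[group] = dP_statistic(
            scores, p_c, control_prop,
            m_comparisons=1 if group == control_group else m_comparisons,
            group=group,
        )
    return out
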