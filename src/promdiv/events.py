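"""Binary event coding of multi-species promoter alignments.

A multiple alignment of orthologous promoter regions (one designated
reference species, the *D. melanogaster* role) is translated into three
per-column binary channels:

``base_changes``
    1 where at least one non-reference species carries a non-gap base that
    differs from the reference's non-gap base.
``indels``
    1 at the 5'-most column of every maximal gap run in any record
    (including gap runs in the reference, which represent insertions in
    other species). Interior columns of a run are 0; coincident starts in
    several species collapse to a single 1.
``all_changes``
    position-wise OR of the two.

Channels are anchored to reference (ungapped) coordinates and, optionally,
to signed offsets from a transcription start site (TSS), negative upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = b"-"
_ALLOWED = frozenset(b"ACGTN-")


class AlignmentShapeError(ValueError):
    """Records of a multiple alignment do not all have the same length."""


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,N,-}."""


@dataclass(frozen=True)
class GeneAnnotation:
    """TSS annotation for one gene: where it sits and which cohort it belongs to.

    ``tss`` is a 0-based reference-genome coordinate of the first transcribed
    base; ``group`` is an analysis cohort label (e.g. IR, OR, CF, NB, control).
    """

    gene_id: str
    contig: str
    tss: int
    strand: str
    group: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


class MultipleAlignment:
    """Equal-length gapped sequences keyed by species, with one reference.

    Sequences are upper-cased on construction and restricted to the
    alphabet ``ACGTN-``. Column count is ``L``.
    """

    def __init__(self, records: Sequence[tuple[str, str]], reference_id: str):
        if len(records) < 2:
            raise AlignmentShapeError("alignment needs at least 2 records")
        ids = [sid for sid, _ in records]
        if reference_id not in ids:
            raise LookupError(f"reference_id {reference_id!r} not among records {ids}")
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"records have unequal lengths: {sorted(len(s) for _, s in records)}"
            )
        self.reference_id = reference_id
        self.ids: list[str] = ids
        rows = []
        for sid, seq in records:
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1").copy()
            bad = ~np.isin(arr, [bytes([c]) for c in _ALLOWED])
            if bad.any():
                pos = int(np.flatnonzero(bad)[0])
                raise AlphabetError(
                    f"illegal character {arr[pos].decode()!r} in record "
                    f"{sid!r} at column {pos}"
                )
            rows.append(arr)
        self.matrix: np.ndarray = np.vstack(rows)  # shape (S, L), dtype S1

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_records(self) -> int:
        return self.matrix.shape[0]

    def sequence(self, species_id: str) -> str:
        i = self.ids.index(species_id)
        return self.matrix[i].tobytes().decode("ascii")

    @property
    def reference_row(self) -> np.ndarray:
        return self.matrix[self.ids.index(self.reference_id)]

    def records(self) -> list[tuple[str, str]]:
        return [(sid, self.matrix[i].tobytes().decode("ascii")) for i, sid in enumerate(self.ids)]


@dataclass
class EventVector:
    """Per-column binary event channels plus coordinate anchors.

    ``ref_coord[i]`` is the reference ungapped coordinate of column ``i``;
    columns that are gaps in the reference share the preceding reference
    position (leading reference gaps map to 0). ``tss_offset`` is filled by
    :func:`anchor_to_tss`.
    """

    L: int
    all_changes: np.ndarray
    indels: np.ndarray
    base_changes: np.ndarray
    ref_coord: np.ndarray
    tss_offset: np.ndarray | None = None

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"all": self.all_changes, "indel": self.indels, "base": self.base_changes}[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}; expected all/indel/base") from None


def read_alignment(path, reference_id: str) -> MultipleAlignment:
    """Read an aligned FASTA file into a validated :class:`MultipleAlignment`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return MultipleAlignment(records, reference_id=reference_id)


def write_alignment(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records():
            fh.write(f">{sid}\n{seq}\n")


def call_base_change_events(aln: MultipleAlignment) -> np.ndarray:
    """Column-wise base-change channel relative to the reference.

    A column scores 1 when some non-reference record carries a non-gap,
    non-N character different from the reference's non-gap, non-N character.
    Gap and N columns never create events in this channel.
    """
    ref = aln.reference_row
    ref_i = aln.ids.index(aln.reference_id)
    informative_ref = (ref != GAP) & (ref != b"N")
    out = np.zeros(aln.L, dtype=np.int8)
    for i in range(aln.n_records):
        if i == ref_i:
            continue
        row = aln.matrix[i]
        hit = informative_ref & (row != GAP) & (row != b"N") & (row != ref)
        out |= hit.astype(np.int8)
    return out


def _gap_run_starts(row: np.ndarray) -> np.ndarray:
    gap = row == GAP
    starts = gap.copy()
    starts[1:] &= ~gap[:-1]
    return starts


def call_indel_events(aln: MultipleAlignment) -> np.ndarray:
    """Indel channel: 1 at the 5'-most column of each maximal gap run.

    Every record is scanned, the reference included (reference gap runs are
    insertions in other species). The channel is the binary OR over records,
    so coincident run starts collapse to a single event.
    """
    out = np.zeros(aln.L, dtype=bool)
    for i in range(aln.n_records):
        out |= _gap_run_starts(aln.matrix[i])
    return out.astype(np.int8)


def combine_channels(base_changes: np.ndarray, indels: np.ndarray) -> np.ndarray:
    """Position-wise OR of the base-change and indel channels."""
    base_changes = np.asarray(base_changes)
    indels = np.asarray(indels)
    if base_changes.shape != indels.shape:
        raise ValueError(
            f"channel length mismatch: {base_changes.shape} vs {indels.shape}"
        )
    return (base_changes.astype(bool) | indels.astype(bool)).astype(np.int8)


def reference_coordinates(aln: MultipleAlignment) -> np.ndarray:
    """Map each alignment column to its reference ungapped coordinate.

    Columns that are gaps in the reference take the preceding reference
    position; leading reference gaps map to 0.
    """
    ref = aln.reference_row
    coord = np.cumsum(ref != GAP) - 1
    return np.maximum(coord, 0)


def build_event_vector(aln: MultipleAlignment) -> EventVector:
    """Call all three channels and the reference-coordinate map at once."""
    base = call_base_change_events(aln)
    indel = call_indel_events(aln)
    return EventVector(
        L=aln.L,
        all_changes=combine_channels(base, indel),
        indels=indel,
        base_changes=base,
        ref_coord=reference_coordinates(aln),
    )


def anchor_to_tss(ev: EventVector, ann: GeneAnnotation, tss_column: int) -> EventVector:
    """Fill per-column signed offsets from the TSS (negative = upstream).

    Offsets are measured in reference ungapped coordinates; for "-" strand
    genes upstream means larger genome coordinates, so the sign flips.
    """
    if not (0 <= tss_column < ev.L):
        raise IndexError(f"tss_column {tss_column} out of range [0, {ev.L})")
    delta = ev.ref_coord - ev.ref_coord[tss_column]
    offsets = delta if ann.strand == "+" else -delta
    return replace(ev, tss_offset=offsets.astype(np.int64))


def offset_channel(
    ev: EventVector, channel: str, span: tuple[int, int] = (-1000, 1000)
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a per-column channel onto a TSS-offset grid by binary OR.

    Returns ``(positions, values)`` where positions run ``span[0] ..
    span[1]-1``. Columns sharing an offset (insertions relative to the
    reference) are OR-combined. Raises if the alignment does not cover the
    requested span.
    """
    if ev.tss_offset is None:
        raise ValueError("EventVector has no tss_offset; call anchor_to_tss first")
    lo, hi = span
    if lo >= hi:
        raise ValueError("empty span")
    off = ev.tss_offset
    if off.min() > lo or off.max() < hi - 1:
        raise ValueError(
            f"alignment covers offsets [{off.min()}, {off.max()}], "
            f"requested span [{lo}, {hi})"
        )
    values = np.zeros(hi - lo, dtype=np.int8)
    ch = ev.channel(channel)
    inside = (off >= lo) & (off < hi)
    np.maximum.at(values, off[inside] - lo, ch[inside])
    positions = np.arange(lo, hi, dtype=np.int64)
    return positions, values


def events_to_frame(gene_id: str, ev: EventVector) -> pd.DataFrame:
    """Long-format event table (one row per alignment column)."""
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "tss_offset": ev.tss_offset if ev.tss_offset is not None else ev.ref_coord,
            "all": ev.all_changes,
            "indel": ev.indels,
            "base": ev.base_changes,
        }
    )


def event_positions(ev: EventVector, channel: str = "indel") -> np.ndarray:
    """0-based alignment columns where the channel is 1 (G-test input)."""
    return np.flatnonzero(ev.channel(channel))


def events_to_bed(gene_id: str, ev: EventVector, path, channel: str = "all") -> None:
    """Write event positions as 1-base BED intervals in reference coordinates."""
    with open(path, "w") as fh:
        for col in event_positions(ev, channel):
            pos = int(ev.ref_coord[col])
            fh.write(f"{gene_id}\t{pos}\t{pos + 1}\t{channel}\n")
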