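"""Synthetic promoter alignments, conservation tracks and MKT count tables.

Every downstream stage is testable without external downloads: this module
generates (a) multi-species promoter alignments in which each non-reference
species derives independently from an ungapped reference by planted
substitutions and geometric-length indels, optionally concentrated in a
hotspot window (star phylogeny — downstream statistics only use per-column
difference from the reference); (b) TSS-anchored 1300-position conservation
vectors with an optional depressed promoter window; (c) per-gene
polymorphism/divergence count tables whose pooled alpha converges to a
known target.

Planted events are recorded as ground truth, in reference coordinates and
as alignment columns, so event detection can be checked for exact recovery.
Indel footprints are kept disjoint across species (with a 1-base guard) so
gap runs never merge and every planted event remains individually visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .conservation import ConservationTrack, TSSVector, TSS_SPAN, TSS_LENGTH
from .events import GeneAnnotation, MultipleAlignment
from .mkt import MKTable
from .windows import PROMOTER_WINDOW

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class SimAlignmentConfig:
    """Parameters of the promoter-alignment simulator.

    ``sub_prob`` is the per-site substitution probability for each
    non-reference species; ``indel_rate`` the expected indel events per
    non-reference species per kb; ``indel_len_p`` the success parameter of
    the geometric length distribution (minimum length 1); ``hotspot`` an
    optional (start, end, multiplier) triple, in reference coordinates,
    multiplying the indel rate inside the window.
    """

    n_species: int = 5
    seq_length: int = 2000
    sub_prob: float = 0.02
    indel_rate: float = 2.0
    indel_len_p: float = 0.5
    hotspot: tuple[int, int, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError(f"n_species must be >= 2, got {self.n_species}")
        if self.seq_length < 2:
            raise ValueError(f"seq_length must be >= 2, got {self.seq_length}")
        if not (0.0 <= self.sub_prob <= 1.0):
            raise ValueError(f"sub_prob must be in [0, 1], got {self.sub_prob}")
        if self.indel_rate < 0:
            raise ValueError(f"indel_rate must be >= 0, got {self.indel_rate}")
        if not (0.0 < self.indel_len_p <= 1.0):
            raise ValueError(f"indel_len_p must be in (0, 1], got {self.indel_len_p}")
        if self.hotspot is not None:
            start, end, mult = self.hotspot
            if not (0 <= start < end <= self.seq_length):
                raise ValueError(f"hotspot interval {(start, end)} outside [0, {self.seq_length})")
            if mult < 0:
                raise ValueError(f"hotspot multiplier must be >= 0, got {mult}")


@dataclass
class GroundTruth:
    """Planted events, in reference coordinates and as alignment columns."""

    true_indel_starts: dict[str, list[int]] = field(default_factory=dict)
    true_substitution_sites: dict[str, list[int]] = field(default_factory=dict)
    hotspot_bounds: tuple[int, int] | None = None
    indel_details: dict[str, list[dict]] = field(default_factory=dict)
    indel_start_columns: dict[str, list[int]] = field(default_factory=dict)
    substitution_columns: dict[str, list[int]] = field(default_factory=dict)

    def all_indel_columns(self) -> set[int]:
        return {c for cols in self.indel_start_columns.values() for c in cols}

    def all_substitution_columns(self) -> set[int]:
        return {c for cols in self.substitution_columns.values() for c in cols}

    def to_json(self, path) -> None:
        d = asdict(self)
        d["hotspot_bounds"] = list(self.hotspot_bounds) if self.hotspot_bounds else None
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _overlaps(lo: int, hi: int, occupied: list[tuple[int, int]], guard: int = 1) -> bool:
    return any(lo - guard < h and l < hi + guard for l, h in occupied)


def _plant_indels(rng: np.random.Generator, cfg: SimAlignmentConfig, species: list[str]):
    """Draw indel events per species, re-drawing placements that would merge gap runs.

    Within a species, footprints keep a 1-base guard so its own runs stay
    separate. Across species only the genuinely ambiguous coincidences are
    excluded: two insertions at the same point (their gap blocks would fuse
    in the reference) and an insertion at another species' deletion start
    (the deletion's 5' boundary would shift into the inserted block). All
    other cross-species overlaps leave every run's 5' column intact, so
    they are allowed and the planted rate stays essentially unbiased.
    """
    L = cfg.seq_length
    weights = np.ones(L)
    if cfg.hotspot is not None:
        s, e, m = cfg.hotspot
        weights[s:e] = m
    lam = cfg.indel_rate / 1000.0 * weights.sum()
    probs = weights / weights.sum()
    own_footprints: dict[str, list[tuple[int, int]]] = {sp: [] for sp in species}
    insertion_points: set[int] = set()
    deletion_starts: set[int] = set()
    events: dict[str, list[dict]] = {sp: [] for sp in species}
    for sp in species:
        n_events = rng.poisson(lam)
        for _ in range(n_events):
            for _attempt in range(10_000):
                start = int(rng.choice(L, p=probs))
                kind = "deletion" if rng.random() < 0.5 else "insertion"
                length = int(rng.geometric(cfg.indel_len_p))
                if kind == "deletion":
                    lo, hi = start, start + length
                    if hi > L or start in insertion_points:
                        continue
                else:
                    if start < 1 or start >= L:
                        continue  # keep insertions interior: gap runs never lead the alignment
                    if start in insertion_points or start in deletion_starts:
                        continue
                    lo, hi = start, start + 1
                if _overlaps(lo, hi, own_footprints[sp]):
                    continue
                own_footprints[sp].append((lo, hi))
                (deletion_starts if kind == "deletion" else insertion_points).add(start)
                events[sp].append({"kind": kind, "start": start, "length": length})
                break
            else:
                raise RuntimeError("could not place indel without collision; lower the rate")
    for sp in species:
        events[sp].sort(key=lambda e: e["start"])
    return events


def simulate_promoter_alignment(
    config: SimAlignmentConfig,
) -> tuple[MultipleAlignment, GroundTruth]:
    """Simulate a multi-species promoter alignment with known planted events.

    The first record (id ``ref``) carries the ungapped reference sequence
    (gapped only where other species inserted); each further record derives
    from it independently. Deletions appear as gap runs in the derived
    record; insertions as gap runs in all other records. Identical config
    (including seed) reproduces the alignment exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    ref_seq = rng.choice(BASES, size=L)
    species = [f"sp{i}" for i in range(1, config.n_species)]

    indels = _plant_indels(rng, config, species)

    # substitutions per species, skipping that species' own deleted sites
    del_mask = {sp: np.zeros(L, dtype=bool) for sp in species}
    for sp in species:
        for e in indels[sp]:
            if e["kind"] == "deletion":
                del_mask[sp][e["start"] : e["start"] + e["length"]] = True
    subs: dict[str, dict[int, bytes]] = {}
    for sp in species:
        sites = np.flatnonzero((rng.random(L) < config.sub_prob) & ~del_mask[sp])
        sub_map = {}
        for s in sites:
            alternatives = BASES[BASES != ref_seq[s]]
            sub_map[int(s)] = rng.choice(alternatives)
        subs[sp] = sub_map

    # derived (pre-alignment) base per species and per reference position
    derived = {sp: ref_seq.copy() for sp in species}
    for sp, sub_map in subs.items():
        for s, b in sub_map.items():
            derived[sp][s] = b

    ins_at: dict[int, tuple[str, np.ndarray]] = {}
    for sp in species:
        for e in indels[sp]:
            if e["kind"] == "insertion":
                ins_at[e["start"]] = (sp, rng.choice(BASES, size=e["length"]))

    gt = GroundTruth(
        true_indel_starts={sp: [e["start"] for e in indels[sp]] for sp in species},
        true_substitution_sites={sp: sorted(subs[sp]) for sp in species},
        hotspot_bounds=tuple(config.hotspot[:2]) if config.hotspot else None,
        indel_details=indels,
        indel_start_columns={sp: [] for sp in species},
        substitution_columns={sp: [] for sp in species},
    )

    names = ["ref"] + species
    cols: dict[str, list[bytes]] = {name: [] for name in names}
    del_start = {sp: {e["start"] for e in indels[sp] if e["kind"] == "deletion"} for sp in species}
    col = 0
    for s in range(L):
        if s in ins_at:
            owner, bases = ins_at[s]
            gt.indel_start_columns[owner].append(col)
            for b in bases:
                for name in names:
                    cols[name].append(b if name == owner else b"-")
                col += 1
        cols["ref"].append(ref_seq[s])
        for sp in species:
            if del_mask[sp][s]:
                cols[sp].append(b"-")
                if s in del_start[sp]:
                    gt.indel_start_columns[sp].append(col)
            else:
                cols[sp].append(derived[sp][s])
                if s in subs[sp]:
                    gt.substitution_columns[sp].append(col)
        col += 1

    records = [(name, b"".join(cols[name]).decode("ascii")) for name in names]
    aln = MultipleAlignment(records, reference_id="ref")
    return aln, gt


def simulate_conservation_tracks(
    n_genes: int,
    window: tuple[int, int] = TSS_SPAN,
    base_mean: float = 1.0,
    promoter_drop: float = 0.0,
    drop_interval: tuple[int, int] = PROMOTER_WINDOW,
    noise_sd: float = 0.1,
    seed: int | None = None,
    group: str = "",
    gene_prefix: str = "gene",
) -> list[TSSVector]:
    """TSS-anchored conservation vectors with a depressible promoter window.

    Scores are ``base_mean`` plus Gaussian noise, minus ``promoter_drop``
    on ``drop_interval`` (offsets relative to the TSS).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if window[1] - window[0] != TSS_LENGTH or window != TSS_SPAN:
        raise ValueError(f"window must equal {TSS_SPAN} ({TSS_LENGTH} positions)")
    rng = np.random.default_rng(seed)
    offsets = np.arange(*TSS_SPAN)
    drop = np.where((offsets >= drop_interval[0]) & (offsets < drop_interval[1]), promoter_drop, 0.0)
    out = []
    for i in range(n_genes):
        values = base_mean - drop + rng.normal(0.0, noise_sd, size=TSS_LENGTH)
        out.append(TSSVector(gene_id=f"{gene_prefix}{i}", group=group, values=values))
    return out


def vectors_to_genome(
    vectors: list[TSSVector],
    contig: str = "chrSim",
    first_tss: int = 2000,
    spacing: int = 3000,
    alternate_strands: bool = True,
) -> tuple[ConservationTrack, list[GeneAnnotation]]:
    """Lay TSS vectors onto a synthetic contig as a per-base track + annotations.

    Round-tripping through :func:`promdiv.conservation.anchor_scores_to_tss`
    recovers the vectors exactly; strands alternate to exercise the
    strand-resolution logic.
    """
    scores: dict[int, float] = {}
    annotations = []
    for i, vec in enumerate(vectors):
        tss = first_tss + i * spacing
        strand = "-" if (alternate_strands and i % 2) else "+"
        sign = 1 if strand == "+" else -1
        for o, v in zip(range(*TSS_SPAN), vec.values):
            scores[tss + sign * o] = float(v)
        annotations.append(
            GeneAnnotation(gene_id=vec.gene_id, contig=contig, tss=tss, strand=strand, group=vec.group)
        )
    return ConservationTrack(scores={contig: scores}), annotations


def simulate_mkt_counts(
    n_genes: int,
    true_alpha: float,
    mean_Ps: float = 20.0,
    mean_Ds: float = 20.0,
    pn_ps_ratio: float = 0.3,
    seed: int | None = None,
    gene_prefix: str = "gene",
) -> list[MKTable]:
    """Per-gene Poisson count tables whose pooled alpha converges to ``true_alpha``.

    Ps ~ Poisson(mean_Ps), Pn ~ Poisson(pn_ps_ratio * mean_Ps),
    Ds ~ Poisson(mean_Ds), Dn ~ Poisson(mean_Ds * pn_ps_ratio / (1 - true_alpha)):
    the non-synonymous divergence rate is inflated by 1/(1 - alpha) relative
    to the neutral expectation, which is exactly what pooled alpha recovers.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 <= true_alpha < 1.0):
        raise ValueError(f"true_alpha must be in [0, 1), got {true_alpha}")
    if mean_Ps <= 0 or mean_Ds <= 0 or pn_ps_ratio <= 0:
        raise ValueError("means and pn_ps_ratio must be > 0")
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n_genes):
        tables.append(
            MKTable(
                gene_id=f"{gene_prefix}{i}",
                Pn=int(rng.poisson(pn_ps_ratio * mean_Ps)),
                Ps=int(rng.poisson(mean_Ps)),
                Dn=int(rng.poisson(mean_Ds * pn_ps_ratio / (1.0 - true_alpha))),
                Ds=int(rng.poisson(mean_Ds)),
            )
        )
    return tables
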