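"""End-to-end orchestration: simulate or load inputs, run every analysis stage,
write machine-readable outputs plus a run manifest.

The pipeline is driven by a YAML/dict config with three data blocks
(``alignments``, ``conservation``, ``mkt``), each either a ``simulate``
block or a ``paths`` block, plus an ``params`` block of analysis settings.
A single global seed fans out into independent per-stage streams; re-running
with the same config and seed reproduces every output byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation import anchor_scores_to_tss, dp_contrast, profiles_to_frame as cons_profiles_to_frame
from .conservation import promoter_mean_ttest, read_scores
from .events import (
    GeneAnnotation,
    anchor_to_tss,
    build_event_vector,
    event_positions,
    events_to_frame,
    offset_channel,
    read_alignment,
)
from .gfunction import g_test
from .mkt import analyse_mkt, bootstrap_alpha_comparison, read_mkt_tsv
from .simulate import (
    SimAlignmentConfig,
    simulate_conservation_tracks,
    simulate_mkt_counts,
    simulate_promoter_alignment,
)
from .windows import (
    group_region_stats,
    heatmap_matrix,
    profiles_to_frame,
    region_stats_to_frame,
    sliding_event_score,
)

log = logging.getLogger(__name__)

CHANNELS = ("all", "indel", "base")

DEFAULT_PARAMS: dict[str, Any] = {
    "half_window": 5,
    "promoter_window": (-380, -30),
    "anchor_span": (-1000, 1000),
    "mc_reps": 100_000,
    "bootstrap_k": 30,
    "bootstrap_B": 100,
    "bonferroni_m": None,
    "control_group": "control",
    "conservation_control_group": "genome",
    "alpha_threshold": 0.05,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: str
    alignments: Mapping[str, Any] | None = None
    conservation: Mapping[str, Any] | None = None
    mkt: Mapping[str, Any] | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        for key in ("promoter_window", "anchor_span"):
            merged[key] = tuple(merged[key])
        self.params = merged
        for name in ("alignments", "conservation", "mkt"):
            block = getattr(self, name)
            if block is None:
                continue
            keys = set(block) & {"simulate", "paths"}
            if len(keys) != 1:
                raise ValueError(
                    f"{name} block must contain exactly one of 'simulate'/'paths', got {sorted(keys)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw["output_dir"]),
            alignments=raw.get("alignments"),
            conservation=raw.get("conservation"),
            mkt=raw.get("mkt"),
            params=dict(raw.get("params") or {}),
        )

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "alignments": _jsonable(self.alignments),
            "conservation": _jsonable(self.conservation),
            "mkt": _jsonable(self.mkt),
            "params": _jsonable(self.params),
        }


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage_seed(global_seed: int, stage_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(global_seed)
    return np.random.default_rng(ss.spawn(8)[stage_index])


def _tss_column_for_ref_position(ev, ref_position: int) -> int:
    cols = np.flatnonzero(ev.ref_coord == ref_position)
    if cols.size == 0:
        raise PipelineError(f"alignments: no column maps to reference position {ref_position}")
    return int(cols[0])


def _collect_alignments(cfg: PipelineConfig, rng: np.random.Generator):
    """Yield (gene_id, group, MultipleAlignment, GeneAnnotation, tss_column)."""
    block = cfg.alignments
    if "simulate" in block:
        sim = dict(block["simulate"])
        genes_per_group = int(sim.pop("genes_per_group", 10))
        groups = sim.pop("groups")
        base = {k: v for k, v in sim.items()}
        out = []
        for group, overrides in groups.items():
            for i in range(genes_per_group):
                params = dict(base)
                params.update(overrides or {})
                params["seed"] = int(rng.integers(0, 2**31 - 1))
                aln_cfg = SimAlignmentConfig(**params)
                aln, gt = simulate_promoter_alignment(aln_cfg)
                gene_id = f"{group}_g{i}"
                tss_pos = aln_cfg.seq_length // 2
                ann = GeneAnnotation(gene_id=gene_id, contig="sim", tss=tss_pos, strand="+", group=group)
                out.append((gene_id, group, aln, ann, tss_pos, gt))
        return out
    paths = block["paths"]
    ann_df = pd.read_csv(paths["annotations"], sep="\t")
    reference_id = paths.get("reference_id", "ref")
    out = []
    for r in ann_df.itertuples():
        aln = read_alignment(Path(paths["dir"]) / f"{r.gene_id}.fa", reference_id=reference_id)
        ann = GeneAnnotation(
            gene_id=str(r.gene_id), contig=str(r.contig), tss=int(r.tss),
            strand=str(r.strand), group=str(r.group),
        )
        out.append((str(r.gene_id), str(r.group), aln, ann, int(r.tss_column), None))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict[str, Any] = {
        "config": config.echo(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "valid": False,
    }

    try:
        if config.alignments is not None:
            _run_alignment_stages(config, outdir, manifest)
        if config.mkt is not None:
            _run_mkt_stage(config, outdir, manifest)
        if config.conservation is not None:
            _run_conservation_stage(config, outdir, manifest)
    except Exception:
        manifest["valid"] = False
        _write_manifest(manifest, outdir)
        raise
    manifest["valid"] = True
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _run_alignment_stages(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    p = config.params
    rng = _stage_seed(config.seed, 0)
    try:
        items = _collect_alignments(config, rng)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"alignments: {exc}") from exc

    event_frames = []
    profiles_by_channel = {c: {} for c in CHANNELS}
    all_profiles = []
    gtest_dir = outdir / "gtest"
    gtest_dir.mkdir(exist_ok=True)
    gtest_rng = _stage_seed(config.seed, 1)
    lo, hi = p["anchor_span"]
    for gene_id, group, aln, ann, tss_col_or_pos, gt in items:
        ev = build_event_vector(aln)
        tss_column = (
            _tss_column_for_ref_position(ev, tss_col_or_pos)
            if gt is not None
            else int(tss_col_or_pos)
        )
        ev = anchor_to_tss(ev, ann, tss_column)
        frame = events_to_frame(gene_id, ev)
        frame.insert(1, "group", group)
        event_frames.append(frame)
        for channel in CHANNELS:
            positions, values = offset_channel(ev, channel, span=(lo, hi))
            prof = sliding_event_score(
                values, half_window=p["half_window"], positions=positions,
                gene_id=gene_id, channel=channel,
            )
            profiles_by_channel[channel].setdefault(group, []).append(prof)
            all_profiles.append(prof)
        # G test on indel-start positions over the full alignment
        x = event_positions(ev, "indel")
        if x.size:
            traj = g_test(
                x, aln.L, B=p["mc_reps"],
                seed=int(gtest_rng.integers(0, 2**31 - 1)),
            )
            payload = traj.to_dict()
        else:
            payload = {"L": aln.L, "n": 0, "statistic": None, "p_global": None,
                       "null_q95": None, "stretches": []}
        payload["gene_id"] = gene_id
        with open(gtest_dir / f"{gene_id}.json", "w") as fh:
            json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
            fh.write("\n")

    events_df = pd.concat(event_frames, ignore_index=True)
    events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
    profiles_to_frame(all_profiles).to_csv(outdir / "se_profiles.tsv", sep="\t", index=False)

    heat_frames = []
    stat_frames = []
    for channel in CHANNELS:
        by_group = profiles_by_channel[channel]
        hm = heatmap_matrix(by_group, window=(lo, hi))
        hm.insert(0, "channel", channel)
        hm.index.name = "group"
        heat_frames.append(hm.reset_index())
        sec, stats_ = group_region_stats(
            by_group,
            control_group=p["control_group"],
            window=p["promoter_window"],
            m_comparisons=p["bonferroni_m"],
            channel=channel,
        )
        df = region_stats_to_frame(stats_)
        df.insert(0, "SeC", sec)
        stat_frames.append(df)
    pd.concat(heat_frames, ignore_index=True).to_csv(outdir / "heatmap.tsv", sep="\t", index=False)
    pd.concat(stat_frames, ignore_index=True).to_csv(
        outdir / "region_stats.tsv", sep="\t", index=False
    )
    manifest["stages"]["alignments"] = {
        "n_genes": len(items),
        "events_rows": int(len(events_df)),
        "se_profile_rows": int(sum(len(pr.positions) for pr in all_profiles)),
        "gtest_files": len(items),
    }


def _run_mkt_stage(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    p = config.params
    rng = _stage_seed(config.seed, 2)
    block = config.mkt
    if "simulate" in block:
        sim = dict(block["simulate"])
        groups_spec = sim.pop("groups")
        shared = {k: sim[k] for k in ("mean_Ps", "mean_Ds", "pn_ps_ratio") if k in sim}
        tables_by_group = {}
        for group, spec in groups_spec.items():
            tables_by_group[group] = simulate_mkt_counts(
                n_genes=int(spec["n_genes"]),
                true_alpha=float(spec["true_alpha"]),
                seed=int(rng.integers(0, 2**31 - 1)),
                gene_prefix=f"{group}_",
                **shared,
            )
    else:
        paths = block["paths"]
        df = pd.read_csv(paths["counts"], sep="\t")
        if "group" not in df.columns:
            raise PipelineError("mkt: counts TSV needs a 'group' column")
        tables_by_group = {}
        for group, sub in df.groupby("group", sort=False):
            tmp = outdir / f".mkt_{group}.tsv"
            sub.to_csv(tmp, sep="\t", index=False)
            tables_by_group[str(group)] = read_mkt_tsv(tmp)
            tmp.unlink()

    frames = []
    for group, tables in tables_by_group.items():
        df = analyse_mkt(tables)
        df.insert(1, "group", group)
        frames.append(df)
    mkt_df = pd.concat(frames, ignore_index=True)
    mkt_df.to_csv(outdir / "mkt.tsv", sep="\t", index=False)

    group_names = list(tables_by_group)
    if len(group_names) >= 2:
        a, b = group_names[0], group_names[1]
        boot = bootstrap_alpha_comparison(
            tables_by_group[a], tables_by_group[b],
            k=p["bootstrap_k"], B=p["bootstrap_B"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        payload = boot.to_dict()
        payload["group_a"], payload["group_b"] = a, b
        with open(outdir / "bootstrap.json", "w") as fh:
            json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
            fh.write("\n")
    manifest["stages"]["mkt"] = {
        "n_genes": int(len(mkt_df)),
        "groups": {g: len(t) for g, t in tables_by_group.items()},
    }


def _run_conservation_stage(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    p = config.params
    rng = _stage_seed(config.seed, 3)
    block = config.conservation
    if "simulate" in block:
        sim = dict(block["simulate"])
        groups_spec = sim.pop("groups")
        shared = {k: sim[k] for k in ("base_mean", "noise_sd") if k in sim}
        vectors_by_group = {}
        for group, spec in groups_spec.items():
            vectors_by_group[group] = simulate_conservation_tracks(
                n_genes=int(spec["n_genes"]),
                promoter_drop=float(spec.get("promoter_drop", 0.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
                group=group,
                gene_prefix=f"{group}_",
                **shared,
            )
    else:
        paths = block["paths"]
        track = read_scores(paths["scores"])
        ann_df = pd.read_csv(paths["annotations"], sep="\t")
        annotations = [
            GeneAnnotation(
                gene_id=str(r.gene_id), contig=str(r.contig), tss=int(r.tss),
                strand=str(r.strand), group=str(r.group),
            )
            for r in ann_df.itertuples()
        ]
        vectors = anchor_scores_to_tss(track, annotations)
        vectors_by_group = {}
        for v in vectors:
            vectors_by_group.setdefault(v.group, []).append(v)

    cons_profiles_to_frame(vectors_by_group).to_csv(
        outdir / "conservation_profiles.tsv", sep="\t", index=False
    )
    control = p["conservation_control_group"]
    if control not in vectors_by_group:
        raise PipelineError(
            f"conservation: control group {control!r} not among {list(vectors_by_group)}"
        )
    dp = dp_contrast(vectors_by_group, control_group=control, window=p["promoter_window"])
    ttests = {}
    for group in vectors_by_group:
        if group == control:
            continue
        t, pv = promoter_mean_ttest(
            vectors_by_group[group], vectors_by_group[control], window=p["promoter_window"]
        )
        ttests[group] = {"t": t, "p": pv}
    payload = {
        "control_group": control,
        "dP": {g: vars(s) for g, s in dp.items()},
        "promoter_ttest_vs_control": ttests,
    }
    with open(outdir / "dp_stats.json", "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["stages"]["conservation"] = {
        "groups": {g: len(v) for g, v in vectors_by_group.items()},
    }
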