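"""Sliding-window promoter divergence: Se scores, the d statistic and chi-squared.

Two simulated cohorts of 5-species promoter alignments — a control at
1 indel/kb and a fast-evolving group at 3 indels/kb — are translated into
binary indel events, smoothed into sliding event (Se) scores, and compared
over the TATA-distal window [-380, -30) with the d statistic (percentage
of positions whose Se exceeds the control average Se^C).
"""

import numpy as np

from promdiv import (
    GeneAnnotation,
    SimAlignmentConfig,
    anchor_to_tss,
    build_event_vector,
    chi_squared_vs_control,
    control_threshold,
    d_statistic,
    offset_channel,
    simulate_promoter_alignment,
    sliding_event_score,
)
from promdiv.windows import pooled_window_values

rng = np.random.default_rng(11)
ann = GeneAnnotation(gene_id="g", contig="sim", tss=1000, strand="+")

profiles = {}
for group, rate in (("control", 1.0), ("fast", 3.0)):
    profs = []
    for _ in range(20):
        cfg = SimAlignmentConfig(
            seq_length=2000, sub_prob=0.02, indel_rate=rate,
            seed=int(rng.integers(2**31)),
        )
        aln, _ = simulate_promoter_alignment(cfg)
        ev = build_event_vector(aln)
        tss_col = int(np.flatnonzero(ev.ref_coord == 1000)[0])
        ev = anchor_to_tss(ev, ann, tss_col)
        positions, values = offset_channel(ev, "indel", span=(-1000, 1000))
        profs.append(sliding_event_score(values, positions=positions, channel="indel"))
    profiles[group] = profs

sec = control_threshold(profiles["control"])
d_ctrl, *_ = d_statistic(pooled_window_values(profiles["control"]), sec)
d_fast, n_above, N = d_statistic(pooled_window_values(profiles["fast"]), sec)
rs = chi_squared_vs_control(n_above, N, d_ctrl, m_comparisons=1, group="fast")

print(f"Se^C (control average Se in [-380,-30)): {sec:.3f}")
print(f"d(control) = {d_ctrl:.1f}%   d(fast) = {d_fast:.1f}%  over N = {N} positions")
print(f"chi2(1) = {rs.chi2:.1f},  p = {rs.p:.3g}")
# d is the percentage of promoter-window positions diverging faster than the
# control average; the 3x indel cohort should show a clearly larger d.
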