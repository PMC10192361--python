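"""McDonald-Kreitman tests, alpha estimation and bootstrap group contrasts.

Each gene contributes a 2x2 table of non-synonymous/synonymous counts of
within-species polymorphism (Pn, Ps) and between-species divergence
(Dn, Ds). Departure from neutrality is tested with a two-sided Fisher
exact test; p-values are Benjamini-Hochberg corrected across genes. The
proportion of non-synonymous substitutions fixed by positive selection is

    alpha = 1 - (Ds * Pn) / (Dn * Ps)

undefined when Dn = 0 or Ps = 0. Gene sets are contrasted by concatenating
counts (pooled alpha) and by bootstrap: k genes drawn with replacement from
each set B times, pooled alpha per draw, and an unpaired t test between the
two alpha samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_BOOTSTRAP_K = 30
DEFAULT_BOOTSTRAP_B = 100


@dataclass
class MKTable:
    """Polymorphism/divergence counts for one gene, with test results."""

    gene_id: str
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    p_fisher: float | None = None
    q_fdr: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        for name in ("Pn", "Ps", "Dn", "Ds"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return self.Pn, self.Ps, self.Dn, self.Ds


@dataclass
class BootstrapResult:
    """Bootstrap contrast of pooled alpha between two gene sets."""

    k: int
    B: int
    alpha_samples_a: np.ndarray
    alpha_samples_b: np.ndarray
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "B": self.B,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "redraws": self.redraws,
            "alpha_samples_a": list(map(float, self.alpha_samples_a)),
            "alpha_samples_b": list(map(float, self.alpha_samples_b)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def mkt_fisher(t: MKTable) -> float:
    """Two-sided Fisher exact p for the table [[Pn, Ps], [Dn, Ds]]."""
    _, p = stats.fisher_exact([[t.Pn, t.Ps], [t.Dn, t.Ds]], alternative="two-sided")
    return float(p)


def odds_ratio(t: MKTable) -> float:
    """Sample odds ratio (Pn/Ps)/(Dn/Ds); inf/nan on zero margins."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return float((t.Pn * t.Ds) / (t.Ps * t.Dn)) if t.Ps * t.Dn else float("nan")


def alpha_estimate(t: MKTable) -> float:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); NaN (undefined flag) when Dn=0 or Ps=0."""
    if t.Dn == 0 or t.Ps == 0:
        return float("nan")
    return 1.0 - (t.Ds * t.Pn) / (t.Dn * t.Ps)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def concatenate_alpha(tables: Sequence[MKTable]) -> float:
    """Pooled alpha: counts summed across tables, then the alpha formula."""
    if not tables:
        raise ValueError("need at least one table")
    Pn = sum(t.Pn for t in tables)
    Ps = sum(t.Ps for t in tables)
    Dn = sum(t.Dn for t in tables)
    Ds = sum(t.Ds for t in tables)
    return alpha_estimate(MKTable("pooled", Pn, Ps, Dn, Ds))


def analyse_mkt(tables: Sequence[MKTable]) -> pd.DataFrame:
    """Per-gene Fisher p, BH q, alpha and odds ratio; fills the tables in place."""
    ps = [mkt_fisher(t) for t in tables]
    qs = fdr_adjust(ps)
    rows = []
    for t, p, q in zip(tables, ps, qs):
        t.p_fisher, t.q_fdr, t.alpha = p, float(q), alpha_estimate(t)
        rows.append(
            {
                "gene_id": t.gene_id,
                "Pn": t.Pn, "Ps": t.Ps, "Dn": t.Dn, "Ds": t.Ds,
                "p_fisher": p, "q_fdr": float(q),
                "alpha": t.alpha, "odds_ratio": odds_ratio(t),
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_alphas(
    tables: Sequence[MKTable], k: int, B: int, seed, max_retries: int = 100
) -> tuple[np.ndarray, int]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_retries):
            idx = rng.integers(0, len(tables), size=k)
            a = concatenate_alpha([tables[i] for i in idx])
            if np.isfinite(a):
                out[b] = a
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"bootstrap draw produced undefined alpha {max_retries} times in a row"
            )
    return out, redraws


def bootstrap_alpha_comparison(
    group_a: Sequence[MKTable],
    group_b: Sequence[MKTable],
    k: int = DEFAULT_BOOTSTRAP_K,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int | None = None,
    equal_var: bool = True,
) -> BootstrapResult:
    """Bootstrap contrast of pooled alpha between two gene sets.

    Per group, B draws of k genes with replacement; each draw's alpha comes
    from the concatenated counts. Draws with undefined alpha are redrawn
    (bounded retries, count reported). The two alpha samples are compared
    with an unpaired Student t test (``equal_var=False`` gives Welch).
    Both groups consume an identically-seeded stream, so comparing a group
    against itself yields t = 0, p = 1 exactly.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one gene")
    if k < 1 or B < 1:
        raise ValueError("k and B must be >= 1")
    alphas_a, r_a = _bootstrap_alphas(group_a, k, B, np.random.default_rng(seed))
    alphas_b, r_b = _bootstrap_alphas(group_b, k, B, np.random.default_rng(seed))
    if np.array_equal(alphas_a, alphas_b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(alphas_a, alphas_b, equal_var=equal_var)
    return BootstrapResult(
        k=k, B=B,
        alpha_samples_a=alphas_a, alpha_samples_b=alphas_b,
        mean_a=float(alphas_a.mean()), mean_b=float(alphas_b.mean()),
        sd_a=float(alphas_a.std(ddof=1)) if B > 1 else 0.0,
        sd_b=float(alphas_b.std(ddof=1)) if B > 1 else 0.0,
        t_statistic=float(t_stat), p_value=float(p),
        redraws=r_a + r_b,
    )


def read_mkt_tsv(path) -> list[MKTable]:
    """Read a count table TSV with columns gene_id, Pn, Ps, Dn, Ds [, group]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "Pn", "Ps", "Dn", "Ds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MKT table missing columns: {sorted(missing)}")
    return [
        MKTable(str(r.gene_id), int(r.Pn), int(r.Ps), int(r.Dn), int(r.Ds))
        for r in df.itertuples()
    ]


def write_mkt_tsv(tables: Sequence[MKTable], path, groups: dict[str, str] | None = None) -> None:
    rows = [
        {"gene_id": t.gene_id, "Pn": t.Pn, "Ps": t.Ps, "Dn": t.Dn, "Ds": t.Ds,
         **({"group": groups[t.gene_id]} if groups else {})}
        for t in tables
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
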