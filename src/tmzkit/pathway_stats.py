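"""Pathway-level dropout statistics.

Two complementary pathway statistics are provided:

* a combined Z-test contrasting TMZ with DMSO.  For gene g, ``X_g`` is the
  difference of sample means of guide-level log2 PD20/PD0 ratios
  (TMZ minus DMSO), ``S_g`` the standard error of that difference
  (``sqrt(s1^2/n1 + s2^2/n2)`` with unbiased variances), and
  ``Z_g = X_g / S_g``.  Genes in pathway P combine as
  ``Z_P = sum(X_g) / sqrt(sum(S_g^2))``, standard normal under the null of
  no average dropout difference; two-sided p-values use the complementary
  error function.
* a paired t statistic describing dropout per pathway and condition: pairs
  are (guide, replicate) log10(count + pseudocount) values at PD20 vs PD0
  pooled over the pathway's genes, reported with -log10(p) and the log2
  ratio of pooled PD20 to PD0 counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import CountMatrix
from .synthetic_data import LibraryDesign

__all__ = [
    "GeneContrast",
    "PathwayZResult",
    "PathwayDropout",
    "gene_zstat",
    "gene_contrasts",
    "pathway_zstat",
    "pathway_zresults",
    "pathway_paired_t",
    "radar_summary",
]


@dataclass
class GeneContrast:
    """Per-gene TMZ-vs-DMSO contrast of guide-level log2 ratios."""

    gene_id: str
    x: float  # difference of sample means, TMZ - DMSO
    s: float  # standard error of the difference
    z: float  # x / s; NaN when s == 0 (degenerate, excluded from pathways)
    n_tmz: int
    n_dmso: int


@dataclass
class PathwayZResult:
    pathway: str
    z: float
    p_two_sided: float
    n_genes: int
    n_excluded: int = 0  # genes dropped for s == 0


@dataclass
class PathwayDropout:
    pathway: str
    genotype: str
    treatment: str
    t_stat: float
    neg_log10_p: float
    log2_fc_pooled: float
    n_pairs: int
    degenerate: bool = False


def _normal_p_two_sided(z: float) -> float:
    return float(special.erfc(abs(z) / math.sqrt(2.0)))


def gene_zstat(
    tmz_ratios: Sequence[float],
    dmso_ratios: Sequence[float],
    gene_id: str = "",
) -> GeneContrast:
    """Two-sample Z contrast of log2 ratios (TMZ minus DMSO) for one gene."""
    a = np.asarray(tmz_ratios, dtype=float)
    b = np.asarray(dmso_ratios, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 ratios per arm")
    x = float(a.mean() - b.mean())
    s = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    z = x / s if s > 0 else float("nan")
    return GeneContrast(gene_id=gene_id, x=x, s=s, z=z,
                        n_tmz=len(a), n_dmso=len(b))


def gene_contrasts(
    lfcs: pd.DataFrame,
    unit: str = "guide_replicate",
    tmz_label: str = "TMZ",
    dmso_label: str = "DMSO",
) -> list[GeneContrast]:
    """Per-gene contrasts from a long guide-lfc table.

    ``unit`` chooses the replication unit feeding X_g:
    "guide_replicate" (default) uses every guide x replicate ratio,
    "guide" averages each guide over replicates first, and "replicate"
    averages guides within each replicate.
    """
    if unit not in ("guide_replicate", "guide", "replicate"):
        raise ValueError(f"unknown replication unit {unit!r}")
    df = lfcs[~lfcs["is_ntc"]]
    if unit == "guide":
        df = (df.groupby(["gene_id", "treatment", "guide_id"], observed=True)
              ["lfc"].mean().reset_index())
    elif unit == "replicate":
        df = (df.groupby(["gene_id", "treatment", "replicate"], observed=True)
              ["lfc"].mean().reset_index())
    grp = df.groupby(["gene_id", "treatment"], observed=True)["lfc"]
    stats_df = grp.agg(["mean", "var", "count"]).unstack("treatment")
    for label in (tmz_label, dmso_label):
        if ("mean", label) not in stats_df.columns:
            raise ValueError(f"no lfcs for treatment {label!r}")
    m_t = stats_df[("mean", tmz_label)].to_numpy()
    m_d = stats_df[("mean", dmso_label)].to_numpy()
    v_t = stats_df[("var", tmz_label)].to_numpy()
    v_d = stats_df[("var", dmso_label)].to_numpy()
    n_t = stats_df[("count", tmz_label)].fillna(0).to_numpy()
    n_d = stats_df[("count", dmso_label)].fillna(0).to_numpy()
    out = []
    for gene, mt, md, vt, vd, nt, nd in zip(stats_df.index, m_t, m_d,
                                            v_t, v_d, n_t, n_d):
        if nt < 2 or nd < 2 or np.isnan(mt) or np.isnan(md):
            continue
        x = float(mt - md)
        s = math.sqrt(vt / nt + vd / nd)
        out.append(GeneContrast(gene_id=gene, x=x, s=s,
                                z=x / s if s > 0 else float("nan"),
                                n_tmz=int(nt), n_dmso=int(nd)))
    return out


def pathway_zstat(contrasts: Sequence[GeneContrast], pathway: str = "") -> PathwayZResult:
    """Combine gene contrasts: Z_P = sum(X_g) / sqrt(sum(S_g^2))."""
    usable = [c for c in contrasts if c.s > 0 and np.isfinite(c.s)]
    excluded = len(contrasts) - len(usable)
    if not usable:
        raise ValueError(f"pathway {pathway!r} has no gene with S_g > 0")
    num = sum(c.x for c in usable)
    den = math.sqrt(sum(c.s ** 2 for c in usable))
    z = num / den
    return PathwayZResult(pathway=pathway, z=z,
                          p_two_sided=_normal_p_two_sided(z),
                          n_genes=len(usable), n_excluded=excluded)


def pathway_zresults(
    contrasts: Sequence[GeneContrast],
    pathway_map: Mapping[str, set[str]],
) -> list[PathwayZResult]:
    """One PathwayZResult per pathway named in ``pathway_map``."""
    by_pathway: dict[str, list[GeneContrast]] = {}
    lookup = {c.gene_id: c for c in contrasts}
    for gene, pathways in pathway_map.items():
        c = lookup.get(gene)
        if c is None:
            continue
        for p in pathways:
            by_pathway.setdefault(p, []).append(c)
    return [pathway_zstat(cs, pathway=p) for p, cs in sorted(by_pathway.items())]


def paired_t_dropout(pd20: np.ndarray, pd0: np.ndarray) -> tuple[float, float, bool]:
    """Paired t statistic and two-sided p for PD20 vs PD0 paired values."""
    d = np.asarray(pd20, float) - np.asarray(pd0, float)
    if len(d) < 2:
        raise ValueError("need >= 2 pairs for a paired t-test")
    if np.allclose(d.var(ddof=1), 0.0):
        t = 0.0 if np.allclose(d.mean(), 0.0) else math.inf * np.sign(d.mean())
        return float(t), 1.0, True  # zero-variance differences: degenerate
    res = stats.ttest_rel(pd20, pd0)
    return float(res.statistic), float(res.pvalue), False


def pathway_paired_t(
    norm: CountMatrix,
    design: LibraryDesign,
    pathway_map: Mapping[str, set[str]],
    pseudocount: float = 0.5,
) -> list[PathwayDropout]:
    """Pooled paired t dropout per pathway and (genotype, treatment) condition.

    Pairs are (guide, replicate) log10(normalised count + pseudocount)
    values at PD20 vs PD0, pooled over all guides of the pathway's genes;
    pairing is by guide_id and replicate, not column position.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    s = norm.samples
    guides = design.guides.set_index("guide_id")
    gene_to_guides: dict[str, list[str]] = {}
    for gid, row in guides.iterrows():
        if not row["is_ntc"]:
            gene_to_guides.setdefault(row["gene_id"], []).append(gid)
    conditions = sorted({(r["genotype"], r["treatment"]) for _, r in s.iterrows()})
    pathways = sorted({p for ps in pathway_map.values() for p in ps})
    out = []
    for genotype, treatment in conditions:
        sel = (s["genotype"] == genotype) & (s["treatment"] == treatment)
        sub = s[sel]
        reps = sorted(sub["replicate"].unique())
        col_of = {(row["timepoint"], row["replicate"]): name
                  for name, row in sub.iterrows()}
        for pw in pathways:
            guide_ids = [g for gene, ps in pathway_map.items() if pw in ps
                         for g in gene_to_guides.get(gene, [])]
            if not guide_ids:
                continue
            block = norm.counts.loc[guide_ids]
            pd0, pd20 = [], []
            for rep in reps:
                if ("PD0", rep) not in col_of or ("PD20", rep) not in col_of:
                    raise ValueError(
                        f"unmatched PD0/PD20 pair for {genotype}/{treatment} "
                        f"replicate {rep}"
                    )
                pd0.append(block[col_of[("PD0", rep)]].to_numpy())
                pd20.append(block[col_of[("PD20", rep)]].to_numpy())
            pd0 = np.concatenate(pd0)
            pd20 = np.concatenate(pd20)
            t, p, degen = paired_t_dropout(np.log10(pd20 + pseudocount),
                                           np.log10(pd0 + pseudocount))
            fc = float(np.log2(pd20.sum() / pd0.sum())) if pd0.sum() > 0 else float("nan")
            out.append(PathwayDropout(
                pathway=pw, genotype=genotype, treatment=treatment,
                t_stat=t, neg_log10_p=float(-np.log10(p)),
                log2_fc_pooled=fc, n_pairs=len(pd0), degenerate=degen,
            ))
    return out


def radar_summary(
    zresults: Mapping[str, Sequence[PathwayZResult]],
    pooled_lfc: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Long-format radar-plot table: one row per (cell line, pathway).

    ``zresults`` maps cell line -> pathway Z results; ``pooled_lfc``
    optionally maps (cell_line, pathway) -> pooled log2 fold change.
    Pathways missing in a cell line appear as explicit NA rows.
    """
    pathways = sorted({r.pathway for rs in zresults.values() for r in rs})
    rows = []
    for cell_line, results in sorted(zresults.items()):
        lookup = {r.pathway: r for r in results}
        for pw in pathways:
            r = lookup.get(pw)
            rows.append({
                "cell_line": cell_line,
                "pathway": pw,
                "neg_log10_p": -math.log10(r.p_two_sided) if r else float("nan"),
                "log2_fc_pooled": (pooled_lfc or {}).get((cell_line, pw),
                                                         float("nan")),
            })
    return pd.DataFrame(rows)
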