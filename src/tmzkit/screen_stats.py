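"""Guide- and gene-level dropout statistics for pooled CRISPR screens.

The gene score is SigmaFC (also called SUMLFC): the sum over a gene's guides
of the log2 PD20/PD0 abundance ratio, computed on counts-per-million
normalised counts with a pseudocount, averaging each guide over screen
replicates before summation.  Significance comes from an empirical null
built by resampling non-targeting-control (NTC) guide ratios: for a gene
with n guides, B null SigmaFC draws are sums of n NTC guide ratios sampled
with replacement, and the two-sided add-one p-value is
``(1 + #{|null| >= |score|}) / (B + 1)``, Benjamini-Hochberg adjusted across
genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix
from .synthetic_data import LibraryDesign

__all__ = [
    "normalize_counts",
    "guide_log2_ratios",
    "gene_sigma_fc",
    "permutation_pvalues",
    "score_screen",
]


def normalize_counts(raw: CountMatrix, scale: float = 1e6) -> CountMatrix:
    """Counts-per-million normalisation: each sample column sums to ``scale``."""
    totals = raw.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cannot normalise all-zero sample(s): {list(zero.index)}")
    norm = raw.counts.astype(float) * (scale / totals)
    return CountMatrix(norm, raw.samples.copy())


def guide_log2_ratios(
    norm: CountMatrix,
    design: LibraryDesign | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide log2((PD20 + c) / (PD0 + c)) for each (treatment, replicate).

    Requires matched PD0/PD20 columns per (genotype, treatment, replicate).
    Returns a long table with columns guide_id, gene_id, is_ntc, genotype,
    treatment, replicate, lfc.  gene_id/is_ntc need ``design``; without it
    they are filled with ''/False.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    s = norm.samples
    pairs = {}
    for name, row in s.iterrows():
        key = (row["genotype"], row["treatment"], row["replicate"])
        pairs.setdefault(key, {})[row["timepoint"]] = name
    frames = []
    for (genotype, treatment, rep), cols in sorted(pairs.items()):
        if set(cols) != {"PD0", "PD20"}:
            raise ValueError(
                f"unmatched PD0/PD20 pair for genotype={genotype!r} "
                f"treatment={treatment!r} replicate={rep!r}: have {sorted(cols)}"
            )
        lfc = np.log2((norm.counts[cols["PD20"]].to_numpy() + pseudocount)
                      / (norm.counts[cols["PD0"]].to_numpy() + pseudocount))
        frames.append(pd.DataFrame({
            "guide_id": norm.counts.index,
            "genotype": genotype,
            "treatment": treatment,
            "replicate": rep,
            "lfc": lfc,
        }))
    out = pd.concat(frames, ignore_index=True)
    if design is not None:
        ann = design.guides.set_index("guide_id")[["gene_id", "is_ntc"]]
        out = out.join(ann, on="guide_id")
        if out["gene_id"].isna().any():
            bad = out.loc[out["gene_id"].isna(), "guide_id"].iloc[0]
            raise ValueError(f"guide {bad!r} not present in library design")
    else:
        out["gene_id"] = ""
        out["is_ntc"] = False
    return out


def _replicate_mean(lfcs: pd.DataFrame) -> pd.DataFrame:
    """Mean lfc per guide across replicates, within guide/gene/treatment."""
    return (lfcs.groupby(["guide_id", "gene_id", "is_ntc", "treatment"],
                         sort=False, observed=True)["lfc"]
            .mean().reset_index())


def gene_sigma_fc(
    lfcs: pd.DataFrame,
    design: LibraryDesign,
    aggregate_replicates: str = "mean",
) -> pd.DataFrame:
    """SigmaFC per gene and treatment: sum over guides of the replicate-mean lfc.

    NTC guides are excluded.  Genes of the design absent from ``lfcs`` are
    omitted from the result.  ``aggregate_replicates`` currently supports
    "mean" (average each guide over replicates) and "sum" (sum all
    guide x replicate ratios, rescaled by 1/n_replicates is NOT applied).
    """
    if aggregate_replicates not in ("mean", "sum"):
        raise ValueError("aggregate_replicates must be 'mean' or 'sum'")
    targeting = lfcs[~lfcs["is_ntc"]]
    if aggregate_replicates == "mean":
        per_guide = _replicate_mean(targeting)
    else:
        per_guide = targeting
    grp = per_guide.groupby(["gene_id", "treatment"], sort=True, observed=True)
    scores = grp["lfc"].sum().rename("sigma_fc").reset_index()
    scores["n_guides"] = grp["guide_id"].nunique().to_numpy()
    return scores[["gene_id", "treatment", "sigma_fc", "n_guides"]]


def permutation_pvalues(
    scores: pd.DataFrame,
    ntc_lfcs: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach permutation p-values (vs the NTC null) and BH-adjusted p-values.

    ``ntc_lfcs`` is a lfc table restricted to NTC guides (any treatments);
    the null pool per treatment is the replicate-mean lfc per NTC guide.
    The add-one estimator never returns 0; p is in [1/(B+1), 1].
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    out = scores.copy()
    out["p_perm"] = np.nan
    rng = np.random.default_rng(seed)
    for treatment, sub in scores.groupby("treatment", sort=True, observed=True):
        pool_df = ntc_lfcs[(ntc_lfcs["is_ntc"]) &
                           (ntc_lfcs["treatment"] == treatment)]
        pool = (pool_df.groupby("guide_id", observed=True)["lfc"].mean()
                .to_numpy())
        if len(pool) == 0:
            raise ValueError(f"no NTC guides for treatment {treatment!r}")
        if len(pool) < 30:
            raise ValueError(
                f"need >= 30 NTC guides for a stable null, have {len(pool)}"
            )
        for n in sorted(sub["n_guides"].unique()):
            draws = pool[rng.integers(0, len(pool), size=(B, int(n)))].sum(axis=1)
            null_abs = np.sort(np.abs(draws))
            idx = sub.index[sub["n_guides"] == n]
            obs = np.abs(out.loc[idx, "sigma_fc"].to_numpy())
            # count of |null| >= |obs| via searchsorted on the sorted null
            ge = B - np.searchsorted(null_abs, obs, side="left")
            out.loc[idx, "p_perm"] = (1.0 + ge) / (B + 1.0)
    out["p_adj"] = np.nan
    for treatment, sub in out.groupby("treatment", sort=True, observed=True):
        out.loc[sub.index, "p_adj"] = multipletests(
            sub["p_perm"].to_numpy(), method="fdr_bh")[1]
    # BH never lowers a p-value below the raw estimate
    out["p_adj"] = np.maximum(out["p_adj"], out["p_perm"])
    return out


def score_screen(
    raw: CountMatrix,
    design: LibraryDesign,
    pseudocount: float = 0.5,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full gene-scoring pass: CPM -> guide ratios -> SigmaFC -> permutation p."""
    norm = normalize_counts(raw)
    lfcs = guide_log2_ratios(norm, design, pseudocount)
    scores = gene_sigma_fc(lfcs, design)
    return permutation_pvalues(scores, lfcs[lfcs["is_ntc"]], B=B, seed=seed)
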