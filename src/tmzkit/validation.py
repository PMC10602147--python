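"""Simulation studies that check the pipeline's null calibration.

These run the real pipeline on synthetic null data and summarise its
behaviour: the standard-normal null of the pathway Z statistic, uniformity
of the gene-level permutation p-values, and frequentist calibration of the
logistic cohort model.  They back both the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import cohort_model, pathway_stats, screen_stats, synthetic_data

__all__ = [
    "NullStudyResult",
    "zp_null_study",
    "permutation_null_pvalues",
    "logistic_type1_study",
    "logistic_recovery_study",
]


@dataclass
class NullStudyResult:
    """Summary of a null simulation: rejection rate, KS test, sample size."""

    n: int
    rejection_rate: float
    alpha: float
    ks_statistic: float
    ks_pvalue: float

    @property
    def rejection_se(self) -> float:
        return float(np.sqrt(self.alpha * (1 - self.alpha) / self.n))


def zp_null_study(
    n_screens: int = 200,
    n_genes: int = 504,
    guides_per_gene: int = 10,
    n_ntc: int = 1000,
    n_pathways: int = 10,
    n_replicates: int = 3,
    baseline_mean: float = 500.0,
    dispersion: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[NullStudyResult, np.ndarray]:
    """Distribution of the pathway Z statistic under an all-null screen.

    Simulates ``n_screens`` independent screens with zero fitness effects,
    runs the normalisation -> guide-ratio -> gene-contrast -> pathway-Z
    pipeline on each, and pools the pathway Z values (``n_screens *
    n_pathways`` of them).  Returns the two-sided rejection rate at
    ``alpha`` plus a KS comparison of the pooled Z values against N(0, 1).
    """
    design = synthetic_data.make_library_design(
        n_genes, guides_per_gene, n_ntc, seed=seed, n_pathways=n_pathways
    )
    rng = np.random.default_rng(seed)
    zs = []
    for _ in range(n_screens):
        params = synthetic_data.ScreenSimParams(
            baseline_mean=baseline_mean, dispersion=dispersion,
            n_replicates=n_replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        counts = synthetic_data.simulate_screen(design, params)
        norm = screen_stats.normalize_counts(counts)
        lfcs = screen_stats.guide_log2_ratios(norm, design)
        contrasts = pathway_stats.gene_contrasts(lfcs)
        for res in pathway_stats.pathway_zresults(contrasts, design.pathway_map):
            zs.append(res.z)
    zs = np.asarray(zs)
    crit = stats.norm.isf(alpha / 2)
    ks = stats.kstest(zs, "norm")
    return NullStudyResult(
        n=len(zs),
        rejection_rate=float(np.mean(np.abs(zs) > crit)),
        alpha=alpha,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    ), zs


def permutation_null_pvalues(
    n_genes: int = 504,
    guides_per_gene: int = 10,
    n_ntc: int = 1000,
    B: int = 1000,
    baseline_mean: float = 500.0,
    dispersion: float = 0.2,
    treatment: str = "TMZ",
    seed: int = 0,
) -> np.ndarray:
    """Gene-level permutation p-values from one all-null screen."""
    design = synthetic_data.make_library_design(
        n_genes, guides_per_gene, n_ntc, seed=seed
    )
    params = synthetic_data.ScreenSimParams(
        baseline_mean=baseline_mean, dispersion=dispersion, seed=seed
    )
    counts = synthetic_data.simulate_screen(design, params)
    scored = screen_stats.score_screen(counts, design, B=B, seed=seed + 1)
    return scored.loc[scored["treatment"] == treatment, "p_perm"].to_numpy()


def _fit_simulated_cohort(params: synthetic_data.CohortSimParams):
    cohort = synthetic_data.simulate_cohort(params)
    adjusted = cohort_model.adjust_expression(
        cohort, hypermutation_threshold=params.hypermutation_threshold
    )
    return cohort_model.fit_hypermutation_model(adjusted)


def logistic_type1_study(
    n_reps: int = 500,
    n_patients: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullStudyResult:
    """Wald-p calibration for the expression coefficient when its truth is 0."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_reps):
        params = synthetic_data.CohortSimParams(
            n_patients=n_patients, beta_rad18=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            fit = _fit_simulated_cohort(params)
        except ValueError:
            continue  # rare single-class or separated draw at small n
        pvals.append(float(fit.p["rad18_adj"]))
    pvals = np.asarray(pvals)
    ks = stats.kstest(pvals, "uniform")
    return NullStudyResult(
        n=len(pvals),
        rejection_rate=float(np.mean(pvals < alpha)),
        alpha=alpha,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def logistic_recovery_study(
    n_patients: int = 5000, seed: int = 0
) -> tuple[dict[str, float], "cohort_model.LogisticFit"]:
    """Fit one large simulated cohort; return the generator truth and fit."""
    params = synthetic_data.CohortSimParams(n_patients=n_patients, seed=seed)
    truth = {
        "intercept": params.beta0,
        "rad18_adj": params.beta_rad18,
        "mgmt": params.beta_mgmt,
    }
    return truth, _fit_simulated_cohort(params)
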