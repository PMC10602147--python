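"""Somatic-variant filter cascade and per-clone mutation catalogs.

The filter reproduces the post-calling cleanup applied to whole-exome calls
from clonally expanded cell lines, in a fixed order:

1. indels longer than ``max_indel_len`` bp are removed;
2. mutant allele frequency, coverage (tumour AND normal) and supporting-read
   thresholds are applied, all inclusive (``>=``);
3. known polymorphisms are subtracted;
4. calls outside the exome capture intervals are dropped.

Each removed record is attributed to the FIRST rule it fails, so the audit
counts are reproducible and sum to the input size.  Surviving SNVs are binned
into the six pyrimidine-strand substitution classes and 96 trinucleotide
contexts per clone, and arm-level induction (TMZ minus DMSO clone means) is
assessed with Welch t-tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import VariantRecord
from .sbs import CLASS_INDEX, CONTEXT_INDEX, SUB_CLASSES, classify_snv

__all__ = [
    "FilterConfig",
    "FilterAudit",
    "CloneCatalog",
    "InductionResult",
    "filter_variants",
    "build_catalogs",
    "compare_arms",
    "classify_snv",
]

FILTER_RULES = ("indel_length", "maf", "depth", "alt_reads",
                "known_polymorphism", "exome_interval")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the variant filter cascade (all boundaries inclusive)."""

    max_indel_len: int = 10
    min_maf: float = 0.10
    min_depth: int = 10
    min_alt_reads: int = 3
    drop_known_polymorphisms: bool = True
    require_exome_interval: bool = True

    def __post_init__(self) -> None:
        if self.max_indel_len < 0 or self.min_depth < 0 or self.min_alt_reads < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not 0.0 <= self.min_maf <= 1.0:
            raise ValueError(f"min_maf {self.min_maf} outside [0,1]")


@dataclass
class FilterAudit:
    """Per-rule removal counts; ``kept + sum(removed) == n_input``."""

    n_input: int
    n_kept: int
    removed: Counter

    def total_removed(self) -> int:
        return sum(self.removed.values())


def _first_failing_rule(r: VariantRecord, cfg: FilterConfig) -> str | None:
    if r.variant_type != "SNV" and r.indel_length > cfg.max_indel_len:
        return "indel_length"
    if r.maf < cfg.min_maf:
        return "maf"
    if r.depth_tumor < cfg.min_depth or r.depth_normal < cfg.min_depth:
        return "depth"
    if r.alt_reads < cfg.min_alt_reads:
        return "alt_reads"
    if cfg.drop_known_polymorphisms and r.known_polymorphism:
        return "known_polymorphism"
    if cfg.require_exome_interval and not r.in_exome_interval:
        return "exome_interval"
    return None


def filter_variants(
    records: Iterable[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], FilterAudit]:
    """Apply the filter cascade; return kept records and a removal audit."""
    cfg = cfg or FilterConfig()
    kept: list[VariantRecord] = []
    removed: Counter = Counter({rule: 0 for rule in FILTER_RULES})
    n = 0
    for r in records:
        n += 1
        rule = _first_failing_rule(r, cfg)
        if rule is None:
            kept.append(r)
        else:
            removed[rule] += 1
    return kept, FilterAudit(n_input=n, n_kept=len(kept), removed=removed)


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

@dataclass
class CloneCatalog:
    """Per-clone SNV counts as a 6-class vector and a 96-context vector."""

    clone_id: str
    genotype: str
    treatment: str
    context_counts: np.ndarray  # 96 ints, canonical CONTEXTS_96 order
    n_skipped: int = 0  # records with ambiguous bases, excluded with warning
    class_counts: dict = field(init=False)
    total_snv: int = field(init=False)

    def __post_init__(self) -> None:
        ctx = np.asarray(self.context_counts, dtype=int)
        if ctx.shape != (96,) or (ctx < 0).any():
            raise ValueError("context_counts must be 96 non-negative integers")
        self.context_counts = ctx
        per_class = ctx.reshape(6, 16).sum(axis=1)
        self.class_counts = dict(zip(SUB_CLASSES, per_class.tolist()))
        self.total_snv = int(ctx.sum())

    @property
    def arm(self) -> tuple[str, str]:
        return (self.genotype, self.treatment)


def build_catalogs(
    records_by_clone: Mapping[str, Sequence[VariantRecord]],
    arms: Mapping[str, tuple[str, str]],
) -> list[CloneCatalog]:
    """Bin each clone's kept SNVs into a CloneCatalog.

    Non-SNV records are excluded from the counts; SNVs with ambiguous bases
    are skipped and tallied in ``n_skipped``.  A clone with no SNVs yields a
    valid all-zero catalog.
    """
    catalogs = []
    for clone_id, records in records_by_clone.items():
        if clone_id not in arms:
            raise KeyError(f"no (genotype, treatment) arm for clone {clone_id!r}")
        counts = np.zeros(96, dtype=int)
        skipped = 0
        for r in records:
            if r.variant_type != "SNV":
                continue
            try:
                _, label = classify_snv(r.ref, r.alt, r.context)
            except ValueError:
                skipped += 1
                continue
            counts[CONTEXT_INDEX[label]] += 1
        genotype, treatment = arms[clone_id]
        catalogs.append(CloneCatalog(clone_id, genotype, treatment, counts,
                                     n_skipped=skipped))
    return catalogs


# ---------------------------------------------------------------------------
# arm comparisons
# ---------------------------------------------------------------------------

@dataclass
class InductionResult:
    """TMZ-minus-DMSO mean SNV counts for one genotype and class (or total).

    ``pattern`` tags the substitution classes: C>T (attributed to O6-methyl-
    guanine mispairing) is Pattern I; the five remaining classes are
    Pattern II.
    """

    genotype: str
    which: str  # "total" or one of the six classes
    mean_tmz: float
    mean_dmso: float
    induced: float
    p_value: float
    pattern: str
    degenerate: bool = False


def _welch(tmz: np.ndarray, dmso: np.ndarray) -> tuple[float, bool]:
    if len(tmz) < 2 or len(dmso) < 2:
        return float("nan"), True
    if np.var(tmz) == 0 and np.var(dmso) == 0:
        return 1.0, True  # identical/constant arms carry no evidence
    return float(stats.ttest_ind(tmz, dmso, equal_var=False).pvalue), False


def compare_arms(
    catalogs: Sequence[CloneCatalog],
    per_class: bool = True,
    tmz_label: str = "TMZ",
    dmso_label: str = "DMSO",
) -> list[InductionResult]:
    """Induction of total and per-class SNV counts per genotype."""
    genotypes = sorted({c.genotype for c in catalogs})
    out: list[InductionResult] = []
    for gt in genotypes:
        tmz = [c for c in catalogs if c.genotype == gt and c.treatment == tmz_label]
        dmso = [c for c in catalogs if c.genotype == gt and c.treatment == dmso_label]
        if not tmz or not dmso:
            continue
        specs = [("total", None)]
        if per_class:
            specs += [(cls, CLASS_INDEX[cls]) for cls in SUB_CLASSES]
        for which, idx in specs:
            if idx is None:
                a = np.array([c.total_snv for c in tmz], dtype=float)
                b = np.array([c.total_snv for c in dmso], dtype=float)
                pattern = ""
            else:
                a = np.array([c.class_counts[which] for c in tmz], dtype=float)
                b = np.array([c.class_counts[which] for c in dmso], dtype=float)
                pattern = "I" if which == "C>T" else "II"
            p, degen = _welch(a, b)
            out.append(InductionResult(
                genotype=gt, which=which,
                mean_tmz=float(a.mean()), mean_dmso=float(b.mean()),
                induced=float(a.mean() - b.mean()),
                p_value=p, pattern=pattern, degenerate=degen,
            ))
    return out
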