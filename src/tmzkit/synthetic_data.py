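"""Synthetic generators with known ground truth for every pipeline stage.

Three generators emulate the data layers of a pooled-screen / mutagenesis /
patient-cohort study of temozolomide (TMZ) genotoxicity:

* ``simulate_screen`` — negative-binomial sgRNA counts for a DDR-focused
  CRISPR dropout screen (by default 504 genes x 10 guides + 1000
  non-targeting controls, sampled at population doubling 0 and 20 under
  DMSO and TMZ), with per-gene per-doubling fitness effects as ground truth.
* ``simulate_catalogs`` — per-clone somatic SNV catalogs drawn from mixtures
  of 96-context mutational signatures with arm-dependent activities, emitted
  both as ground-truth context vectors and as raw variant records so the
  filter stage is exercised.
* ``simulate_cohort`` — patient tables generated under a known logistic
  model linking proliferation-adjusted expression and MGMT status to
  hypermutation.

All generators take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CohortTable, CountMatrix, SignatureMatrix, VariantRecord
from .mutation_catalog import CloneCatalog
from .sbs import CONTEXTS_96, revcomp

__all__ = [
    "LibraryDesign",
    "ScreenSimParams",
    "CatalogSimParams",
    "CohortSimParams",
    "DEFAULT_PATHWAYS",
    "make_library_design",
    "simulate_screen",
    "make_signature_matrix",
    "simulate_catalogs",
    "simulate_cohort",
]

#: Default DNA-damage-response pathway names used by the library generator.
DEFAULT_PATHWAYS = ("MMR", "BER", "NER", "HR", "NHEJ", "FA", "TLS",
                    "Checkpoint", "PARP", "NucleotideMetabolism")


@dataclass
class LibraryDesign:
    """sgRNA library: guide->gene map, NTC flags and gene->pathway map."""

    guides: pd.DataFrame  # columns guide_id, gene_id ('' for NTC), is_ntc
    pathway_map: dict[str, set[str]]

    def __post_init__(self) -> None:
        if self.guides["guide_id"].duplicated().any():
            raise ValueError("guide_ids must be unique")
        targeting = self.guides[~self.guides["is_ntc"]]
        if (targeting["gene_id"] == "").any():
            raise ValueError("every targeting guide must map to a gene")
        self.guides = self.guides.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.guides.loc[~self.guides["is_ntc"], "gene_id"].unique())

    @property
    def n_targeting(self) -> int:
        return int((~self.guides["is_ntc"]).sum())

    @property
    def n_ntc(self) -> int:
        return int(self.guides["is_ntc"].sum())

    def guides_of(self, gene: str) -> list[str]:
        sel = self.guides["gene_id"] == gene
        return self.guides.loc[sel & ~self.guides["is_ntc"], "guide_id"].tolist()


def make_library_design(
    n_genes: int = 504,
    guides_per_gene: int = 10,
    n_ntc: int = 1000,
    pathway_spec: Mapping[str, set[str]] | None = None,
    seed: int = 0,
    n_pathways: int = len(DEFAULT_PATHWAYS),
) -> LibraryDesign:
    """Build a library design (default: 5040 targeting + 1000 NTC guides).

    ``pathway_spec`` maps gene_id -> set of pathway names; if omitted, genes
    are assigned round-robin to ``n_pathways`` default DDR pathway names
    (one pathway per gene).  Deterministic for a given seed.
    """
    if min(n_genes, guides_per_gene, n_ntc) < 0:
        raise ValueError("library sizes must be non-negative")
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    rows = [
        (f"{g}_g{j + 1:02d}", g, False)
        for g in genes
        for j in range(guides_per_gene)
    ]
    rows += [(f"NTC{i + 1:04d}", "", True) for i in range(n_ntc)]
    guides = pd.DataFrame(rows, columns=["guide_id", "gene_id", "is_ntc"])
    if pathway_spec is None:
        names = DEFAULT_PATHWAYS[:n_pathways] if n_pathways <= len(DEFAULT_PATHWAYS) \
            else tuple(f"PW{i + 1}" for i in range(n_pathways))
        pathway_map = {g: {names[i % len(names)]} for i, g in enumerate(genes)}
    else:
        pathway_map = {g: set(p) for g, p in pathway_spec.items()}
    return LibraryDesign(guides=guides, pathway_map=pathway_map)


# ---------------------------------------------------------------------------
# screen counts
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Generative parameters of the screen count simulator.

    ``gene_effects`` maps gene_id -> {treatment: per-doubling log2 fitness
    effect}; unlisted genes (and always the NTCs) have effect 0.  ``dispersion``
    is the negative-binomial overdispersion (variance = mu + dispersion*mu^2);
    0 gives Poisson counts.
    """

    baseline_mean: float = 500.0
    dispersion: float = 0.2
    gene_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    treatments: Sequence[str] = ("DMSO", "TMZ")
    genotype: str = "WT"
    n_replicates: int = 3
    doublings: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if disp == 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / disp, mean * disp)
    return rng.poisson(lam)


def simulate_screen(design: LibraryDesign, params: ScreenSimParams) -> CountMatrix:
    """Simulate raw sgRNA counts for PD0/PD20 x treatment x replicate.

    A guide with per-doubling effect e has expected PD20 abundance
    ``baseline * 2**(e * doublings)`` before the PD20 column is renormalised
    to the PD0 sequencing depth (dropout is relative, as under fixed read
    depth).  NTC guides always have effect 0.
    """
    rng = np.random.default_rng(params.seed)
    guides = design.guides
    n = len(guides)
    mu0 = np.full(n, params.baseline_mean)
    effect = {t: np.zeros(n) for t in params.treatments}
    gene_pos = {g: np.flatnonzero((guides["gene_id"] == g).to_numpy())
                for g in params.gene_effects}
    for gene, per_t in params.gene_effects.items():
        if gene not in gene_pos or len(gene_pos[gene]) == 0:
            raise ValueError(f"gene_effects names unknown gene {gene!r}")
        for t, e in per_t.items():
            effect[t][gene_pos[gene]] = e
    cols, meta = {}, []
    for t in params.treatments:
        mu20 = mu0 * np.exp2(effect[t] * params.doublings)
        mu20 = mu20 * mu0.sum() / mu20.sum()  # fixed sequencing depth
        for r in range(1, params.n_replicates + 1):
            for tp, mu in (("PD0", mu0), ("PD20", mu20)):
                name = f"{tp}_{t}_R{r}"
                cols[name] = _nb_draw(rng, mu, params.dispersion)
                meta.append((name, tp, t, params.genotype, r))
    counts = pd.DataFrame(cols, index=pd.Index(guides["guide_id"], name="guide_id"))
    samples = pd.DataFrame(
        meta, columns=["sample", "timepoint", "treatment", "genotype", "replicate"]
    ).set_index("sample")
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# signature matrices and clone catalogs
# ---------------------------------------------------------------------------

def make_signature_matrix(
    n_signatures: int = 5,
    seed: int = 0,
    concentration: float = 0.3,
    include_sig11: bool = True,
) -> SignatureMatrix:
    """Generate a synthetic 96-context signature matrix.

    This is a stand-in constructed for testing, NOT the published COSMIC
    tables.  Columns are Dirichlet draws over the 96 contexts; when
    ``include_sig11`` is set the first column is named "Signature 11" and
    given an alkylation-like profile: ~90% of its mass on C>T contexts,
    down-weighted at CpG (``?[C>T]G``) sites.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    names = []
    for k in range(n_signatures):
        if k == 0 and include_sig11:
            w = np.full(96, 0.1 / 80)
            for i, label in enumerate(CONTEXTS_96):
                if label[2:5] == "C>T":
                    w[i] = 0.9 / 16 * (0.2 if label[-1] == "G" else 1.3)
            w = w * rng.dirichlet(np.full(96, 50.0)) * 96  # mild jitter
            names.append("Signature 11")
        else:
            w = rng.dirichlet(np.full(96, concentration))
            names.append(f"Signature S{k + 1}")
        cols[names[-1]] = w / w.sum()
    df = pd.DataFrame(cols, index=pd.Index(CONTEXTS_96, name="context"))
    return SignatureMatrix(df)


@dataclass
class CatalogSimParams:
    """Arms, signature activities and seed for the clone-catalog simulator.

    ``arms`` lists (genotype, treatment, n_clones); ``activities`` maps
    (genotype, treatment) -> expected mutation count per signature (length-K
    non-negative vector in the signature matrix's column order).
    """

    signature_matrix: SignatureMatrix
    arms: Sequence[tuple[str, str, int]] = (
        ("WT", "DMSO", 6), ("WT", "TMZ", 6),
        ("RAD18KO", "DMSO", 6), ("RAD18KO", "TMZ", 6),
    )
    activities: Mapping[tuple[str, str], Sequence[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.signature_matrix)
        for arm, act in self.activities.items():
            a = np.asarray(act, dtype=float)
            if a.shape != (k,):
                raise ValueError(f"activity vector for {arm} must have length {k}")
            if (a < 0).any():
                raise ValueError(f"negative activity for arm {arm}")


def _context_to_variant_fields(label: str) -> tuple[str, str, str]:
    """(ref, alt, context string) on the pyrimidine strand for a 96 label."""
    five, sub, three = label[0], label[2:5], label[6]
    ref, alt = sub[0], sub[2]
    return ref, alt, f"{five}{ref}{three}"


def simulate_catalogs(
    params: CatalogSimParams,
) -> tuple[list[CloneCatalog], dict[str, list[VariantRecord]]]:
    """Draw per-clone mutation catalogs and matching raw variant records.

    Per clone, the count attributed to signature k is Poisson(activity_k)
    and its contexts are multinomial over the signature's 96-context column;
    the clone total is therefore Poisson(sum of activities).  Each mutation
    is also emitted as a VariantRecord (with MAF, depths, supporting reads
    and context; half are represented on the purine strand) that passes the
    default filter cascade, so rebuilding catalogs from the records must
    reproduce the ground-truth context vectors exactly.
    """
    rng = np.random.default_rng(params.seed)
    S = params.signature_matrix
    catalogs: list[CloneCatalog] = []
    variants: dict[str, list[VariantRecord]] = {}
    for genotype, treatment, n_clones in params.arms:
        arm = (genotype, treatment)
        act = np.asarray(params.activities.get(arm, np.zeros(len(S))), dtype=float)
        for i in range(n_clones):
            clone_id = f"{genotype}_{treatment}_c{i + 1}"
            ctx = np.zeros(96, dtype=int)
            for k in range(len(S)):
                m = rng.poisson(act[k])
                if m:
                    ctx += rng.multinomial(m, S.matrix[:, k])
            catalogs.append(CloneCatalog(clone_id, genotype, treatment, ctx))
            recs: list[VariantRecord] = []
            pos = 1
            for j, label in enumerate(CONTEXTS_96):
                ref, alt, context = _context_to_variant_fields(label)
                for _ in range(int(ctx[j])):
                    pos += int(rng.integers(50, 5000))
                    r, a, c = ref, alt, context
                    if rng.random() < 0.5:  # purine-strand representation
                        r, a, c = revcomp(r), revcomp(a), revcomp(c)
                    depth_t = int(rng.integers(30, 120))
                    maf = float(rng.uniform(0.2, 0.6))
                    recs.append(VariantRecord(
                        chrom="chr1", pos=pos, ref=r, alt=a, maf=maf,
                        depth_tumor=depth_t,
                        depth_normal=int(rng.integers(30, 120)),
                        alt_reads=max(3, int(round(maf * depth_t))),
                        context=c, known_polymorphism=False,
                        in_exome_interval=True, clone_id=clone_id,
                    ))
            variants[clone_id] = recs
    return catalogs, variants


# ---------------------------------------------------------------------------
# patient cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Known-truth generative model for patient cohort tables.

    Expression follows ``intercept + slope * proliferation + N(0, noise_sd)``;
    the hypermutation label is Bernoulli with logit
    ``beta0 + beta_rad18 * residual + beta_mgmt * 1[MGMT low]``.
    Signature-11 counts are then drawn consistently with the label relative
    to the >500 hypermutation threshold.
    """

    n_patients: int = 400
    beta0: float = -1.0
    beta_rad18: float = -0.8
    beta_mgmt: float = -0.5
    slope: float = 2.0
    intercept: float = 5.0
    noise_sd: float = 1.0
    p_mgmt_low: float = 0.5
    hypermutation_threshold: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def simulate_cohort(params: CohortSimParams) -> CohortTable:
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    prolif = rng.normal(0.0, 1.0, size=n)
    eps = rng.normal(0.0, params.noise_sd, size=n)
    expr = params.intercept + params.slope * prolif + eps
    mgmt_low = rng.random(n) < params.p_mgmt_low
    logit = params.beta0 + params.beta_rad18 * eps + params.beta_mgmt * mgmt_low
    p = 1.0 / (1.0 + np.exp(-logit))
    hyper = rng.random(n) < p
    thr = params.hypermutation_threshold
    sig11 = np.where(
        hyper,
        thr + 1.0 + rng.exponential(0.8 * thr, size=n),
        rng.uniform(0.0, 0.9 * thr, size=n),
    )
    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "rad18_expression": expr,
        "proliferation_score": prolif,
        "mgmt_status": np.where(mgmt_low, "low", "high"),
        "signature11_count": sig11,
        "hypermutation": hyper,
    })
    return CohortTable(df, mgmt_kind="status")
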