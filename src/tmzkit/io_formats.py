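"""Readers and writers for every external table the pipeline touches.

All tabular formats are plain TSV: tab-separated, UTF-8, ``#`` comment lines,
no quoting.  Variant records are additionally accepted as a minimal
uncompressed VCF v4.2 subset (read through pysam) whose INFO tags carry the
post-calling annotations the filter stage needs:

======  =====================================================
tag     meaning
======  =====================================================
AF      mutant allele frequency in the tumour sample
DPT     read depth at the site in the tumour sample
DPN     read depth at the site in the matched normal
ALTC    number of reads supporting the alternate allele
CTX     trinucleotide reference context centred on POS
KNOWN   flag: site matches a known polymorphism catalogue
EXON    flag: site falls inside the exome capture intervals
======  =====================================================

Coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sbs import BASES, CONTEXTS_96

__all__ = [
    "FormatError",
    "CountMatrix",
    "VariantRecord",
    "SignatureMatrix",
    "CohortTable",
    "read_count_table",
    "write_count_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_library",
    "write_library",
    "read_pathway_map",
    "write_pathway_map",
    "read_variants",
    "write_variants_tsv",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_cohort",
    "write_cohort",
]

SAMPLE_FIELDS = ("timepoint", "treatment", "genotype", "replicate")

_TSV = dict(sep="\t", comment="#", dtype_backend="numpy_nullable")


class FormatError(ValueError):
    """An external table violates the documented layout or an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Guide x sample sgRNA abundances plus per-sample metadata.

    ``counts`` is indexed by guide_id with one column per sample;
    ``samples`` is indexed by sample name with columns
    (timepoint, treatment, genotype, replicate).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate guide_id {dup!r} in count matrix")
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise FormatError(f"samples missing from sample sheet: {missing}")
        for f in SAMPLE_FIELDS:
            if f not in self.samples.columns:
                raise FormatError(f"sample sheet lacks required column {f!r}")
        vals = self.counts.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise FormatError("count matrix contains missing values")
        if (vals < 0).any():
            guide = self.counts.index[np.where(vals < 0)[0][0]]
            raise FormatError(f"negative count for guide {guide!r}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.samples.index[mask]
        return CountMatrix(self.counts[list(keep)], self.samples.loc[keep])


@dataclass
class VariantRecord:
    """One post-calling somatic variant with its filter annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    depth_tumor: int
    depth_normal: int
    alt_reads: int
    context: str
    known_polymorphism: bool = False
    in_exome_interval: bool = True
    clone_id: str | None = None
    variant_type: str = field(init=False)

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        self.context = self.context.upper()
        if self.pos < 1:
            raise FormatError(f"pos must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise FormatError(f"invalid alleles {self.ref!r}>{self.alt!r}")
        if len(self.ref) == 1 and len(self.alt) == 1:
            self.variant_type = "SNV"
        elif len(self.alt) > len(self.ref):
            self.variant_type = "insertion"
        else:
            self.variant_type = "deletion"
        if not 0.0 <= self.maf <= 1.0:
            raise FormatError(f"maf {self.maf} outside [0,1]")
        for name in ("depth_tumor", "depth_normal", "alt_reads"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} negative")
        if self.variant_type == "SNV":
            if len(self.context) != 3 or any(b not in BASES for b in self.context):
                raise FormatError(f"invalid SNV context {self.context!r}")
            if self.context[1] != self.ref:
                raise FormatError(
                    f"context middle base {self.context[1]!r} != ref {self.ref!r}"
                    f" at {self.chrom}:{self.pos}"
                )

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


class SignatureMatrix:
    """96-context x K signature probability matrix (COSMIC v2 layout).

    Rows are the canonical 96 context labels; each column is a signature
    whose entries are non-negative and sum to 1.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.copy()
        if set(df.index) != set(CONTEXTS_96):
            n = len(df.index)
            if n != 96:
                raise FormatError(f"expected 96 context rows, got {n}")
            bad = sorted(set(df.index) - set(CONTEXTS_96))[:3]
            raise FormatError(f"unrecognised context labels, e.g. {bad}")
        df = df.loc[list(CONTEXTS_96)].astype(float)
        if df.columns.duplicated().any():
            raise FormatError("duplicate signature names")
        if (df.to_numpy() < 0).any():
            raise FormatError("signature matrix has negative entries")
        sums = df.sum(axis=0)
        off = sums[(sums - 1.0).abs() > 1e-3]
        if len(off):
            raise FormatError(
                f"signature columns do not sum to 1: {dict(off.round(4))}"
            )
        self.values = df / sums  # renormalise the <=1e-3 drift away

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.values.columns:
            raise KeyError(
                f"unknown signature {name!r}; available: {self.names}"
            )
        return self.values[name].to_numpy()

    def __len__(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortTable:
    """Patient rows: expression, proliferation, MGMT, Signature-11 count.

    ``mgmt_kind`` records whether the MGMT column was a binary
    promoter/expression status ("status", values low/high) or a continuous
    expression value ("expression").
    """

    table: pd.DataFrame
    mgmt_kind: str = "status"

    def __post_init__(self) -> None:
        req = {"patient_id", "rad18_expression", "proliferation_score",
               "mgmt_status", "signature11_count"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"cohort table lacks columns {sorted(missing)}")
        if self.table["patient_id"].duplicated().any():
            dup = self.table.loc[self.table["patient_id"].duplicated(),
                                 "patient_id"].iloc[0]
            raise FormatError(f"duplicate patient_id {dup!r}")
        if (self.table["signature11_count"].astype(float) < 0).any():
            raise FormatError("signature11_count must be >= 0")
        if self.mgmt_kind == "status":
            bad = set(self.table["mgmt_status"]) - {"low", "high"}
            if bad:
                raise FormatError(f"mgmt_status values must be low/high, got {bad}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# count matrix / sample sheet / library / pathway map
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "sample" not in df.columns:
        raise FormatError(f"{path}: sample sheet needs a 'sample' column")
    for f in SAMPLE_FIELDS:
        if f not in df.columns:
            raise FormatError(f"{path}: sample sheet lacks column {f!r}")
    return df.set_index("sample")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_count_table(path, sample_sheet, design=None) -> CountMatrix:
    """Read a guide x sample count TSV, validating against the sample sheet.

    ``sample_sheet`` may be a path or an already-loaded DataFrame.  If a
    LibraryDesign is supplied, guides not in the design are rejected.
    """
    df = _read_tsv(path)
    if "guide_id" not in df.columns:
        raise FormatError(f"{path}: missing guide_id column")
    if df["guide_id"].duplicated().any():
        row = int(np.where(df["guide_id"].duplicated())[0][0]) + 2
        raise FormatError(f"{path}: duplicate guide_id at line {row}")
    counts = df.set_index("guide_id")
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = int(np.where(vals.isna())[0][0]) + 2
            raise FormatError(f"{path}: non-numeric count in {col!r} line {row}")
        if (vals < 0).any():
            row = int(np.where(vals < 0)[0][0]) + 2
            raise FormatError(f"{path}: negative count in column {col!r} line {row}")
        counts[col] = vals
    samples = sample_sheet if isinstance(sample_sheet, pd.DataFrame) \
        else read_sample_sheet(sample_sheet)
    if design is not None:
        known = set(design.guides["guide_id"])
        unknown = [g for g in counts.index if g not in known]
        if unknown:
            raise FormatError(
                f"{path}: {len(unknown)} guide(s) not in library design, "
                f"e.g. {unknown[:3]}"
            )
    return CountMatrix(counts, samples)


def write_count_table(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("guide_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_library(path):
    """Read a library TSV (guide_id, gene_id, is_ntc) into a LibraryDesign."""
    from .synthetic_data import LibraryDesign

    df = _read_tsv(path)
    for col in ("guide_id", "gene_id", "is_ntc"):
        if col not in df.columns:
            raise FormatError(f"{path}: library TSV lacks column {col!r}")
    df = df.copy()
    df["is_ntc"] = df["is_ntc"].astype(bool)
    df["gene_id"] = df["gene_id"].where(~df["is_ntc"], "")
    return LibraryDesign(guides=df[["guide_id", "gene_id", "is_ntc"]],
                         pathway_map={})


def write_library(design, path) -> None:
    design.guides.to_csv(path, sep="\t", index=False)


def read_pathway_map(path) -> dict[str, set[str]]:
    """gene_id -> set of pathway names; a gene may appear on several rows."""
    df = _read_tsv(path)
    for col in ("gene_id", "pathway"):
        if col not in df.columns:
            raise FormatError(f"{path}: pathway TSV lacks column {col!r}")
    out: dict[str, set[str]] = {}
    for gene, pw in zip(df["gene_id"], df["pathway"]):
        out.setdefault(str(gene), set()).add(str(pw))
    return out


def write_pathway_map(pathway_map: Mapping[str, Iterable[str]], path) -> None:
    rows = [(g, p) for g, pws in sorted(pathway_map.items()) for p in sorted(pws)]
    pd.DataFrame(rows, columns=["gene_id", "pathway"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VARIANT_COLS = ["clone_id", "chrom", "pos", "ref", "alt", "maf", "depth_tumor",
                 "depth_normal", "alt_reads", "context", "known_polymorphism",
                 "in_exome_interval"]

_VCF_REQUIRED_INFO = ("AF", "DPT", "DPN", "ALTC", "CTX")


def read_variants(path, clone_id: str | None = None) -> list[VariantRecord]:
    """Read variant records from the TSV dialect or a minimal VCF.

    Dispatch is by extension: ``.vcf`` goes through pysam, anything else is
    read as the TSV dialect with explicit columns.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_variants_vcf(path, clone_id)
    return _read_variants_tsv(path)


def _read_variants_tsv(path) -> list[VariantRecord]:
    df = _read_tsv(path)
    if df.empty and not set(_VARIANT_COLS) <= set(df.columns):
        raise FormatError(f"{path}: empty variant TSV without a valid header")
    missing = [c for c in _VARIANT_COLS if c not in df.columns and c != "clone_id"]
    if missing:
        raise FormatError(f"{path}: variant TSV lacks columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(VariantRecord(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            maf=float(row["maf"]), depth_tumor=int(row["depth_tumor"]),
            depth_normal=int(row["depth_normal"]),
            alt_reads=int(row["alt_reads"]), context=str(row["context"]),
            known_polymorphism=bool(row["known_polymorphism"]),
            in_exome_interval=bool(row["in_exome_interval"]),
            clone_id=str(row["clone_id"]) if "clone_id" in df.columns else None,
        ))
    return records


def _read_variants_vcf(path, clone_id: str | None) -> list[VariantRecord]:
    import pysam

    vcf = pysam.VariantFile(str(path))
    missing = [t for t in _VCF_REQUIRED_INFO if t not in vcf.header.info]
    if missing:
        raise FormatError(
            f"{path}: VCF header lacks required INFO tags {missing}"
        )
    records = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"{path}: record at {rec.chrom}:{rec.pos} must have exactly "
                "one ALT allele"
            )
        info = rec.info
        af = info["AF"]
        af = float(af[0] if isinstance(af, tuple) else af)
        records.append(VariantRecord(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
            maf=af, depth_tumor=int(info["DPT"]), depth_normal=int(info["DPN"]),
            alt_reads=int(info["ALTC"]), context=str(info["CTX"]),
            known_polymorphism=bool(info.get("KNOWN", False)),
            in_exome_interval=bool(info.get("EXON", False)),
            clone_id=clone_id,
        ))
    return records


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d.pop("variant_type")
        d["clone_id"] = d["clone_id"] or ""
        rows.append(d)
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clone catalogs
# ---------------------------------------------------------------------------

def write_catalogs(catalogs, path) -> None:
    """One row per clone: metadata, total, 6 class and 96 context columns."""
    from .sbs import SUB_CLASSES

    rows = []
    for c in catalogs:
        row = {"clone_id": c.clone_id, "genotype": c.genotype,
               "treatment": c.treatment, "total_snv": c.total_snv}
        row.update({f"class:{k}": v for k, v in c.class_counts.items()})
        row.update({f"ctx:{label}": int(n)
                    for label, n in zip(CONTEXTS_96, c.context_counts)})
        rows.append(row)
    cols = (["clone_id", "genotype", "treatment", "total_snv"]
            + [f"class:{k}" for k in SUB_CLASSES]
            + [f"ctx:{label}" for label in CONTEXTS_96])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_catalogs(path) -> list:
    from .mutation_catalog import CloneCatalog

    df = _read_tsv(path)
    ctx_cols = [f"ctx:{label}" for label in CONTEXTS_96]
    missing = [c for c in ("clone_id", "genotype", "treatment", *ctx_cols)
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: catalog TSV lacks columns {missing[:5]}")
    return [
        CloneCatalog(str(r["clone_id"]), str(r["genotype"]),
                     str(r["treatment"]),
                     np.array([r[c] for c in ctx_cols], dtype=int))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# signature matrix / cohort
# ---------------------------------------------------------------------------

def read_signature_matrix(path) -> SignatureMatrix:
    df = _read_tsv(path)
    if "context" not in df.columns:
        raise FormatError(f"{path}: signature TSV needs a 'context' column")
    return SignatureMatrix(df.set_index("context"))


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    sig.values.rename_axis("context").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_cohort(path) -> CohortTable:
    df = _read_tsv(path)
    if "mgmt_status" not in df.columns:
        raise FormatError(f"{path}: cohort TSV lacks column 'mgmt_status'")
    kind = "expression" if pd.api.types.is_numeric_dtype(df["mgmt_status"]) \
        else "status"
    if "hypermutation" in df.columns:
        df["hypermutation"] = df["hypermutation"].astype(bool)
    if "pole_mutated" in df.columns:
        df["pole_mutated"] = df["pole_mutated"].astype(bool)
    return CohortTable(df, mgmt_kind=kind)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)
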