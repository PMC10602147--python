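"""Non-negative least-squares refitting of 96-context mutation catalogs.

A catalog ``m`` (96 counts) is decomposed against a fixed signature matrix
``S`` (96 x K, columns summing to 1) by solving

    min_a || S a - m ||_2   subject to  a >= 0.

The exposures ``a`` are reported in mutation counts attributed per
signature.  The problem is convex; the Lawson-Hanson active-set solver
returns the global optimum, which is verified here against the KKT
conditions (zero gradient on active coordinates, non-negative gradient on
zero coordinates).  The Signature-11 exposure feeds the hypermutation call:
a sample is hypermutated iff its Signature-11 count strictly exceeds the
threshold (default 500).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import SignatureMatrix
from .mutation_catalog import CloneCatalog

__all__ = [
    "SignatureExposure",
    "HypermutationCall",
    "nnls_fit",
    "fit_catalogs",
    "signature11_count",
    "call_hypermutation",
]

#: relative KKT tolerance, scaled by max(1, ||m||)
_KKT_RTOL = 1e-8


@dataclass
class SignatureExposure:
    """Per-sample non-negative exposures (mutation counts per signature)."""

    sample_id: str
    exposures: pd.Series  # indexed by signature name, >= 0
    residual_norm: float
    reconstruction: np.ndarray  # S @ exposures, length 96

    def __getitem__(self, name: str) -> float:
        if name not in self.exposures.index:
            raise KeyError(
                f"unknown signature {name!r}; available: "
                f"{list(self.exposures.index)}"
            )
        return float(self.exposures[name])


@dataclass
class HypermutationCall:
    sample_id: str
    signature11_count: float
    threshold: float = 500.0
    is_hypermutated: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.signature11_count < 0:
            raise ValueError("signature11_count must be >= 0")
        self.is_hypermutated = self.signature11_count > self.threshold


def nnls_fit(
    catalog96: np.ndarray | Sequence[float],
    S: SignatureMatrix,
    sample_id: str = "",
) -> SignatureExposure:
    """Fit one 96-context catalog; KKT-verified global optimum."""
    m = np.asarray(catalog96, dtype=float)
    if m.shape != (96,):
        raise ValueError(f"catalog must have 96 entries, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("catalog counts must be non-negative")
    A = S.matrix
    if not m.any():
        a = np.zeros(A.shape[1])
        return SignatureExposure(sample_id, pd.Series(a, index=S.names),
                                 0.0, np.zeros(96))
    a, rnorm = nnls(A, m)
    grad = A.T @ (A @ a - m)
    tol = _KKT_RTOL * max(1.0, float(np.linalg.norm(m)))
    active = a > tol
    if np.abs(grad[active]).max(initial=0.0) > tol or grad.min() < -tol:
        raise RuntimeError(
            "NNLS solution failed the KKT optimality check "
            f"(max |grad_active| = {np.abs(grad[active]).max(initial=0.0):.3g},"
            f" min grad = {grad.min():.3g}, tol = {tol:.3g})"
        )
    return SignatureExposure(sample_id, pd.Series(a, index=S.names),
                             float(rnorm), A @ a)


def fit_catalogs(
    catalogs: Sequence[CloneCatalog],
    S: SignatureMatrix,
    mode: str = "per_sample",
) -> list[SignatureExposure]:
    """Fit every clone catalog, or pooled per (genotype, treatment) arm.

    ``mode`` is "per_sample" (default, one exposure per clone) or
    "per_arm" (catalogs summed within each arm before fitting).
    """
    if mode == "per_sample":
        return [nnls_fit(c.context_counts, S, sample_id=c.clone_id)
                for c in catalogs]
    if mode == "per_arm":
        pooled: dict[tuple[str, str], np.ndarray] = {}
        for c in catalogs:
            pooled.setdefault(c.arm, np.zeros(96, dtype=int))
            pooled[c.arm] = pooled[c.arm] + c.context_counts
        return [nnls_fit(ctx, S, sample_id=f"{gt}_{tr}")
                for (gt, tr), ctx in sorted(pooled.items())]
    raise ValueError(f"unknown mode {mode!r}")


def signature11_count(
    exposure: SignatureExposure, name: str = "Signature 11"
) -> float:
    """Mutation count attributed to the named (alkylation) signature."""
    return exposure[name]


def call_hypermutation(
    count: float, threshold: float = 500.0, sample_id: str = ""
) -> HypermutationCall:
    """Strict >threshold rule: 500 is not hypermutated, 501 is."""
    if count < 0:
        raise ValueError("signature count must be >= 0")
    return HypermutationCall(sample_id=sample_id, signature11_count=float(count),
                             threshold=float(threshold))
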