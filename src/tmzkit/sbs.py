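"""Single-base-substitution conventions: classes, 96 trinucleotide contexts.

Somatic SNVs are reported on the pyrimidine strand: a substitution whose
reference base is a purine (A or G) is reverse-complemented together with its
flanking context before classification.  This yields six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) and, with one 5' and one 3' flanking base,
96 context bins labelled ``X[R>A]Y``.
"""

from __future__ import annotations

SUB_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical row order: class-major, then 5' base, then 3' base (A,C,G,T).
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}
CLASS_INDEX = {c: i for i, c in enumerate(SUB_CLASSES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"ambiguous base {exc.args[0]!r} in {seq!r}") from None


def classify_snv(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Classify an SNV into (substitution class, 96-context label).

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases, ``ref != alt``.
    context : str
        Trinucleotide centred on the variant position; its middle base must
        equal ``ref``.

    Returns
    -------
    (class, label)
        e.g. ``("C>T", "T[C>T]A")``.  Purine-strand input is normalised to
        the pyrimidine strand, so a variant and its reverse-complement
        representation classify identically.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("classify_snv requires single-base ref and alt")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r})")
    if len(context) != 3:
        raise ValueError(f"context must be a trinucleotide, got {context!r}")
    for b in (ref, alt, *context):
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if context[1] != ref:
        raise ValueError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if ref in "AG":  # normalise to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = revcomp(context)
    sub = f"{ref}>{alt}"
    label = f"{context[0]}[{sub}]{context[2]}"
    return sub, label


def class_of_context(label: str) -> str:
    """Substitution class of a 96-context label, e.g. ``T[C>T]A`` -> ``C>T``."""
    return label[2:5]
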