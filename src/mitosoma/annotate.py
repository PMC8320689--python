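"""Consequence annotation of mitochondrial variants.

Variants are written in the left-anchored ``m.<pos><REF>><ALT>`` style
used throughout the mitochondrial literature: ``m.5338T>C`` is a
substitution, ``m.10191TC>T`` deletes the base at 10,192 (REF covers
10,191-10,192), and ``m.10946A>AC`` inserts a C after 10,946. Coding
substitutions are classified by re-translating the affected codon under
the vertebrate mitochondrial code (light-strand genes via the reverse
complement): same residue -> synonymous, different residue -> missense,
new stop (including AGA/AGG) -> stop_gain. Coding indels whose length is
not a multiple of three are frameshifts; in-frame indels are not
loss-of-function. Loss-of-function (LoF) = stop_gain or frameshift.

For positions covered by overlapping genes every consequence is
computed; the most severe is primary and the rest are recorded as
secondary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from mitosoma.reference import (
    GENE_ALIASES,
    MITO_CODE,
    CoordinateError,
    MitoGenomeModel,
    revcomp,
)

_M_RE = re.compile(r"^m\.(\d+)([ACGTN]+)>([ACGTN]+)$")

#: most severe first; used to pick the primary consequence at overlaps
SEVERITY = [
    "frameshift", "stop_gain", "missense", "in_frame", "synonymous",
    "tRNA", "rRNA", "dloop", "intergenic",
]

LOF_CLASSES = {"stop_gain", "frameshift"}

#: Table-1 layout order of the 13 protein genes grouped by OXPHOS complex
COMPLEX_ORDER = ["Complex I", "Complex III", "Complex IV", "ATP synthase"]


class NotationError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class MitoVariant:
    position: int  # 1-based start of REF
    ref_allele: str
    alt_allele: str

    @property
    def kind(self) -> str:
        nr, na = len(self.ref_allele), len(self.alt_allele)
        if nr == na == 1:
            return "SNV"
        if nr > na and self.ref_allele.startswith(self.alt_allele):
            return "deletion"
        if na > nr and self.alt_allele.startswith(self.ref_allele):
            return "insertion"
        return "MNV"

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def m_notation(self) -> str:
        return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"

    def to_hgvs(self) -> str:
        """Canonical HGVS form (used for VCF-style REF/ALT emission)."""
        if self.kind == "SNV":
            return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"
        if self.kind == "deletion":
            lo = self.position + len(self.alt_allele)
            hi = self.position + len(self.ref_allele) - 1
            return f"m.{lo}del" if lo == hi else f"m.{lo}_{hi}del"
        if self.kind == "insertion":
            ins = self.alt_allele[len(self.ref_allele):]
            return f"m.{self.position}_{self.position + 1}ins{ins}"
        return f"m.{self.position}_{self.position + len(self.ref_allele) - 1}delins{self.alt_allele}"


def parse_m_notation(text: str, model: MitoGenomeModel) -> MitoVariant:
    """Parse an ``m.``-notation string, validating REF against rCRS."""
    m = _M_RE.match(text.strip())
    if not m:
        raise NotationError(f"malformed m-notation: {text!r}")
    pos = int(m.group(1))
    ref, alt = m.group(2), m.group(3)
    if ref == alt:
        raise NotationError(f"{text!r}: REF and ALT are identical")
    end = pos + len(ref) - 1
    if pos < 1 or end > model.length:
        raise CoordinateError(f"{text!r}: span {pos}-{end} outside 1..{model.length}")
    observed = model.slice(pos, end)
    if observed != ref:
        raise ReferenceMismatchError(
            f"{text!r}: rCRS has {observed!r} at {pos}-{end}, not {ref!r}"
        )
    return MitoVariant(position=pos, ref_allele=ref, alt_allele=alt)


@dataclass
class Consequence:
    primary_gene: str
    klass: str
    complex_label: str = "none"
    protein_change: tuple[str, int, str] | None = None  # (ref_res, codon_index, alt_res)
    secondary: list[tuple[str, str]] = field(default_factory=list)  # (gene, klass)
    terminal_codon: bool = False  # classified via the polyA-completed stop

    @property
    def is_lof(self) -> bool:
        return self.klass in LOF_CLASSES


def _affected_span(variant: MitoVariant) -> tuple[int, int]:
    """Genomic span whose features the variant can hit."""
    if variant.kind == "insertion":
        return variant.position, min(variant.position + 1, 16569)
    if variant.kind == "deletion":
        return variant.position + len(variant.alt_allele), variant.position + len(
            variant.ref_allele
        ) - 1
    return variant.position, variant.position + len(variant.ref_allele) - 1


def _coding_snv_class(
    model: MitoGenomeModel, gene: str, pos: int, alt_base: str
) -> tuple[str, tuple[str, int, str], bool]:
    codon_index, offset, codon = model.codon_context(gene, pos)
    strand = model.feature(gene).strand
    alt = alt_base if strand == "heavy" else revcomp(alt_base)
    alt_codon = codon[: offset - 1] + alt + codon[offset:]
    ref_res = MITO_CODE.get(codon, "X")
    alt_res = MITO_CODE.get(alt_codon, "X")
    terminal = model.is_incomplete_terminal_codon(gene, codon_index)
    if ref_res == alt_res:
        klass = "synonymous"
    elif alt_res == "*":
        klass = "stop_gain"
    else:
        klass = "missense"
    return klass, (ref_res, codon_index, alt_res), terminal


def annotate(variant: MitoVariant, model: MitoGenomeModel) -> Consequence:
    """Classify one validated variant against the rCRS gene model."""
    lo, hi = _affected_span(variant)
    feats: list = []
    for p in range(lo, hi + 1):
        for f in model.features_at(p):
            if f.gene_name not in [g.gene_name for g in feats]:
                feats.append(f)
    results: list[tuple[str, str, tuple | None, bool]] = []
    if not feats:
        results.append(("intergenic", "intergenic", None, False))
    for f in feats:
        if f.kind != "protein":
            results.append((f.gene_name, f.kind, None, False))
            continue
        if variant.kind == "SNV":
            klass, change, terminal = _coding_snv_class(
                model, f.gene_name, variant.position, variant.alt_allele
            )
            results.append((f.gene_name, klass, change, terminal))
        elif variant.kind in ("insertion", "deletion"):
            klass = "frameshift" if variant.length_change % 3 else "in_frame"
            results.append((f.gene_name, klass, None, False))
        else:  # MNV: per-codon substitution, most severe wins
            best = None
            for i, (rb, ab) in enumerate(zip(variant.ref_allele, variant.alt_allele)):
                if rb == ab:
                    continue
                p = variant.position + i
                if p not in f:
                    continue
                kl, ch, term = _coding_snv_class(model, f.gene_name, p, ab)
                cand = (SEVERITY.index(kl), kl, ch, term)
                if best is None or cand[0] < best[0]:
                    best = cand
            if best is not None:
                results.append((f.gene_name, best[1], best[2], best[3]))
    results.sort(key=lambda r: SEVERITY.index(r[1]))
    gene, klass, change, terminal = results[0]
    complex_label = "none"
    if gene not in ("intergenic",):
        feat = model.feature(gene)
        complex_label = feat.complex_label
    return Consequence(
        primary_gene=gene,
        klass=klass,
        complex_label=complex_label,
        protein_change=change,
        secondary=[(g, k) for g, k, _, _ in results[1:]],
        terminal_codon=terminal,
    )


def annotate_m(text: str, model: MitoGenomeModel) -> Consequence:
    return annotate(parse_m_notation(text, model), model)


def somatic_variant_from_call(position: int, ref: str, alt: str, model) -> MitoVariant:
    """Convert a caller allele (base, ``+SEQ``, ``-SEQ``) to a MitoVariant."""
    if alt.startswith("+"):
        return MitoVariant(position=position, ref_allele=ref, alt_allele=ref + alt[1:])
    if alt.startswith("-"):
        deleted = alt[1:]
        return MitoVariant(
            position=position, ref_allele=ref + deleted, alt_allele=ref
        )
    return MitoVariant(position=position, ref_allele=ref, alt_allele=alt)


def annotate_somatic_table(
    mutations: pd.DataFrame, model: MitoGenomeModel
) -> pd.DataFrame:
    """Attach consequence columns to a somatic-mutation table."""
    rows = []
    for r in mutations.itertuples():
        var = somatic_variant_from_call(int(r.position), str(r.ref), str(r.alt), model)
        cons = annotate(var, model)
        pc = (
            f"{cons.protein_change[0]}{cons.protein_change[1]}{cons.protein_change[2]}"
            if cons.protein_change
            else ""
        )
        rows.append(
            {
                "m_notation": var.m_notation(),
                "gene": cons.primary_gene,
                "class": cons.klass,
                "is_lof": cons.is_lof,
                "complex": cons.complex_label,
                "protein_change": pc,
            }
        )
    ann = pd.DataFrame(rows, index=mutations.index)
    return pd.concat([mutations, ann], axis=1)


def lof_summary(annotated: pd.DataFrame, model: MitoGenomeModel) -> pd.DataFrame:
    """Complex-level clustering table of LoF mutations.

    One row per protein gene in complex order (zero-count genes
    included), with the contributing tumor-subtype labels.
    """
    lof = annotated[annotated["is_lof"]] if not annotated.empty else annotated
    rows = []
    for cplx in COMPLEX_ORDER:
        genes = [f for f in model.protein_genes() if f.complex_label == cplx]
        for f in sorted(genes, key=lambda f: f.gene_name, reverse=True):
            sub = lof[lof["gene"] == f.gene_name] if not lof.empty else lof
            subtypes = (
                sorted(sub["subtype"].astype(str).unique())
                if "subtype" in sub.columns and not sub.empty
                else []
            )
            rows.append(
                {
                    "region": cplx,
                    "gene": f.gene_name,
                    "n_lof": int(len(sub)),
                    "subtypes": ",".join(s for s in subtypes if s) or "-",
                }
            )
    return pd.DataFrame(rows)
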