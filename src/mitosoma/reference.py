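"""Circular rCRS genome model: sequence, features, and the vertebrate mitochondrial code.

The human mitochondrial genome is a 16,569-bp circular molecule. All
coordinates in this package are 1-based inclusive on the revised Cambridge
Reference Sequence (rCRS, NC_012920.1), matching the standard ``m.``
variant notation. Circularity only matters for the control region
(D-loop), which wraps the origin and is stored as two intervals
(16,024-16,569 and 1-576) sharing one gene label.

Translation uses the vertebrate mitochondrial genetic code, which differs
from the standard code at four codons: TGA encodes Trp, AGA and AGG are
stop codons, and ATA encodes Met. Seven of the thirteen protein genes end
in an incomplete codon (a trailing T or TA) that is completed to a TAA
stop by post-transcriptional polyadenylation; ``codon_context`` flags
those codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

MT_LENGTH = 16569

#: canonical gene-symbol aliases (the literature writes both forms)
GENE_ALIASES = {
    "MT-COX1": "MT-CO1",
    "MT-COX2": "MT-CO2",
    "MT-COX3": "MT-CO3",
    "MT-CYTB": "MT-CYB",
    "MT-ND4L": "MT-ND4L",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _build_code_table() -> dict[str, str]:
    """The 64-codon vertebrate mitochondrial code (NCBI table 2)."""
    tab = unambiguous_dna_by_id[2]
    code = dict(tab.forward_table)
    for stop in tab.stop_codons:
        code[stop] = "*"
    # fill any codon biopython leaves implicit (none expected, but be total)
    for codon in ("".join(c) for c in product("ACGT", repeat=3)):
        code.setdefault(codon, "X")
    return code


#: codon -> one-letter amino acid, '*' for stop
MITO_CODE: dict[str, str] = _build_code_table()


def translate_mito(cds: str) -> str:
    """Translate a coding sequence codon-by-codon under the mito code.

    Codons containing N translate to 'X'. Trailing incomplete codons are
    ignored (they are handled explicitly by callers via polyA completion).
    """
    return "".join(
        MITO_CODE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
    )


class CoordinateError(ValueError):
    """Position outside 1..16,569."""


class NonCodingError(ValueError):
    """Codon arithmetic requested for a position outside a protein feature."""


@dataclass(frozen=True)
class MitoFeature:
    gene_name: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "heavy" | "light"
    kind: str  # protein | tRNA | rRNA | dloop | intergenic
    complex_label: str  # "Complex I" | "Complex III" | "Complex IV" | "ATP synthase" | "none"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise CoordinateError(f"bad feature span {self.start}-{self.end}")
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitoGenomeModel:
    """The rCRS sequence plus its circular feature map."""

    sequence: str
    features: list[MitoFeature]
    code_table: dict[str, str] = field(default_factory=lambda: dict(MITO_CODE))

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ValueError(
                f"expected the {MT_LENGTH}-bp rCRS; got {len(self.sequence)} bases "
                "(Yoruba/hg19 chrM and other references are not supported)"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence contains non-ACGTN characters")

    @property
    def length(self) -> int:
        return MT_LENGTH

    def base(self, position: int) -> str:
        self._check(position)
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice (no wrap-around)."""
        self._check(start)
        self._check(end)
        return self.sequence[start - 1 : end]

    @staticmethod
    def _check(position: int) -> None:
        if not 1 <= position <= MT_LENGTH:
            raise CoordinateError(f"position {position} outside 1..{MT_LENGTH}")

    # -- feature lookup ----------------------------------------------------

    def features_at(self, position: int) -> list[MitoFeature]:
        self._check(position)
        return [f for f in self.features if position in f]

    def region_of(self, position: int) -> list[tuple[str, str]]:
        """All (gene_name, kind) overlapping ``position``.

        Overlapping genes (e.g. MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4) are all
        returned. Positions covered by no annotated feature are reported
        as the explicit ("intergenic", "intergenic") class, so the lookup
        is total over the genome.
        """
        hits = [(f.gene_name, f.kind) for f in self.features_at(position)]
        if not hits:
            return [("intergenic", "intergenic")]
        # D-loop is two records with one label; collapse duplicates
        seen: list[tuple[str, str]] = []
        for h in hits:
            if h not in seen:
                seen.append(h)
        return seen

    def feature(self, gene: str) -> MitoFeature:
        gene = GENE_ALIASES.get(gene, gene)
        for f in self.features:
            if f.gene_name == gene:
                return f
        raise KeyError(gene)

    def protein_genes(self) -> list[MitoFeature]:
        return [f for f in self.features if f.kind == "protein"]

    # -- coding arithmetic -------------------------------------------------

    def coding_sequence(self, gene: str) -> str:
        """Gene sequence in reading orientation (light-strand genes reverse
        complemented), including any trailing incomplete codon."""
        f = self.feature(gene)
        if f.kind != "protein":
            raise NonCodingError(f"{gene} is not a protein gene")
        s = self.slice(f.start, f.end)
        return revcomp(s) if f.strand == "light" else s

    def codon_context(self, gene: str, position: int) -> tuple[int, int, str]:
        """(codon_index, offset_in_codon, reference_codon) for a genomic position.

        Both codon_index and offset_in_codon are 1-based. For a position in
        a terminal incomplete codon, the codon is completed with 'A'
        (polyadenylation) and returned padded to three bases.
        """
        f = self.feature(gene)
        if f.kind != "protein":
            raise NonCodingError(f"{gene} is not a protein gene")
        if position not in f:
            raise NonCodingError(f"position {position} not inside {gene}")
        cds = self.coding_sequence(gene)
        offset = position - f.start if f.strand == "heavy" else f.end - position
        codon_index, within = divmod(offset, 3)
        codon = cds[codon_index * 3 : codon_index * 3 + 3]
        if len(codon) < 3:  # terminal incomplete codon, polyA-completed stop
            codon = codon + "A" * (3 - len(codon))
        return codon_index + 1, within + 1, codon

    def is_incomplete_terminal_codon(self, gene: str, codon_index: int) -> bool:
        cds = self.coding_sequence(gene)
        n_full, rem = divmod(len(cds), 3)
        return rem != 0 and codon_index == n_full + 1

    def protein(self, gene: str) -> str:
        """Translated protein, including any polyA-completed terminal stop."""
        cds = self.coding_sequence(gene)
        rem = len(cds) % 3
        if rem:
            cds = cds + "A" * (3 - rem)
        return translate_mito(cds)


def _data_path(name: str):
    return resources.files("mitosoma.data").joinpath(name)


def load_reference(
    fasta_path=None, features_path=None
) -> MitoGenomeModel:
    """Load the vendored rCRS model (or user-supplied equivalents).

    The feature table is a TSV with header
    ``gene  start  end  strand  kind  complex``.
    """
    fasta_path = fasta_path or _data_path("rCRS.fasta")
    features_path = features_path or _data_path("rcrs_features.tsv")
    with open(fasta_path) as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    seq = str(record.seq).upper()
    features = []
    with open(features_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "start", "end", "strand", "kind", "complex"]
        if header != expected:
            raise ValueError(f"feature table header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            gene, start, end, strand, kind, cplx = line.rstrip("\n").split("\t")
            features.append(
                MitoFeature(gene, int(start), int(end), strand, kind, cplx)
            )
    return MitoGenomeModel(sequence=seq, features=features)
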