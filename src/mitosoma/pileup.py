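"""Per-position, per-strand, quality-annotated allele counts for one sample.

Two on-disk representations are supported:

* the MACT TSV dialect (the pipeline's native format), header::

    pos  ref  A_f  C_f  G_f  T_f  A_r  C_r  G_r  T_r  indels  mq_A  mq_C  mq_G  mq_T

  where ``indels`` is ``.`` or a comma-separated list of ``+SEQ:fwd:rev``
  (insertion of SEQ after ``pos``) and ``-SEQ:fwd:rev`` (deletion of SEQ
  starting at ``pos``+1) items, and ``mq_X`` is the mean Phred base
  quality of reads supporting allele X (0 when absent);

* plain 6-column ``samtools mpileup`` text as an alternate reader.

In memory a pileup is a pandas DataFrame with exactly the MACT columns;
``PileupColumn`` is a light per-position view used by the single-site
caller operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
MACT_COLUMNS = [
    "pos", "ref",
    "A_f", "C_f", "G_f", "T_f",
    "A_r", "C_r", "G_r", "T_r",
    "indels",
    "mq_A", "mq_C", "mq_G", "mq_T",
]


class PileupParseError(ValueError):
    pass


@dataclass
class PileupColumn:
    """One reference position: per-allele per-strand counts and mean qualities.

    ``counts`` maps an allele ("A".."T", "+SEQ", "-SEQ") to (fwd, rev)
    read counts; ``mean_quality`` maps the same keys to mean Phred scores.
    """

    position: int
    ref: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    mean_quality: dict[str, float] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return int(sum(f + r for f, r in self.counts.values()))

    def count(self, allele: str) -> int:
        f, r = self.counts.get(allele, (0, 0))
        return f + r

    def quality(self, allele: str) -> float:
        return float(self.mean_quality.get(allele, 0.0))


@dataclass
class PileupTable:
    """A whole-sample pileup: one MACT row per covered reference position."""

    df: pd.DataFrame
    sample_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in MACT_COLUMNS if c not in self.df.columns]
        if missing:
            raise PileupParseError(f"pileup missing columns {missing}")
        self.df = self.df[MACT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def depths(self) -> np.ndarray:
        """Total read depth per row (bases plus indel-supporting reads)."""
        base = self.df[[f"{b}_{s}" for b in BASES for s in "fr"]].to_numpy().sum(axis=1)
        ind = np.array([_indel_reads(s) for s in self.df["indels"]])
        return base + ind

    def column(self, position: int) -> PileupColumn:
        sub = self.df[self.df["pos"] == position]
        if sub.empty:
            raise KeyError(position)
        row = sub.iloc[0]
        return row_to_column(row)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.2f")

    @classmethod
    def from_tsv(cls, path, sample_id: str = "") -> "PileupTable":
        try:
            df = pd.read_csv(
                path, sep="\t", dtype={"ref": str, "indels": str}, na_filter=False
            )
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise PileupParseError(f"cannot read pileup {path}: {exc}") from exc
        _validate_rows(df, path)
        return cls(df=df, sample_id=sample_id or str(path))


def row_to_column(row: pd.Series) -> PileupColumn:
    counts: dict[str, tuple[int, int]] = {}
    quals: dict[str, float] = {}
    for b in BASES:
        f, r = int(row[f"{b}_f"]), int(row[f"{b}_r"])
        if f + r:
            counts[b] = (f, r)
            quals[b] = float(row[f"mq_{b}"])
    site_q = _site_mean_quality(row)
    for allele, f, r in parse_indel_field(str(row["indels"])):
        counts[allele] = (f, r)
        quals[allele] = site_q
    return PileupColumn(
        position=int(row["pos"]), ref=str(row["ref"]), counts=counts, mean_quality=quals
    )


def _site_mean_quality(row: pd.Series) -> float:
    num = den = 0.0
    for b in BASES:
        n = int(row[f"{b}_f"]) + int(row[f"{b}_r"])
        num += n * float(row[f"mq_{b}"])
        den += n
    return num / den if den else 0.0


def parse_indel_field(field_text: str) -> list[tuple[str, int, int]]:
    """Parse ``+SEQ:fwd:rev,-SEQ:fwd:rev`` into (allele, fwd, rev) tuples."""
    field_text = field_text.strip()
    if field_text in (".", "", "nan"):
        return []
    out = []
    for item in field_text.split(","):
        parts = item.split(":")
        if (
            len(parts) != 3
            or parts[0][:1] not in "+-"
            or len(parts[0]) < 2
            or not (parts[1].isdigit() and parts[2].isdigit())
        ):
            raise PileupParseError(f"bad indel item {item!r}")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def format_indel_field(items: list[tuple[str, int, int]]) -> str:
    if not items:
        return "."
    return ",".join(f"{a}:{f}:{r}" for a, f, r in items)


def _indel_reads(field_text: str) -> int:
    return sum(f + r for _, f, r in parse_indel_field(str(field_text)))


def _validate_rows(df: pd.DataFrame, path) -> None:
    missing = [c for c in MACT_COLUMNS if c not in df.columns]
    if missing:
        raise PileupParseError(f"{path}: missing columns {missing}")
    for i, s in enumerate(df["indels"]):
        try:
            parse_indel_field(str(s))
        except PileupParseError as exc:
            raise PileupParseError(f"{path} line {i + 2}: {exc}") from exc


# ---------------------------------------------------------------------------
# samtools mpileup text (alternate reader)
# ---------------------------------------------------------------------------

def from_mpileup(path, sample_id: str = "") -> PileupTable:
    """Read 6-column ``samtools mpileup`` text (chrom pos ref depth bases quals).

    Read-start (``^X``) and read-end (``$``) markers are stripped;
    ``.``/``,`` count toward the reference allele on the forward/reverse
    strand; ``+N<seq>``/``-N<seq>`` attach an indel allele to the read
    they follow; ``*`` placeholders (within-deletion positions) are
    counted into depth but carry no allele.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise PileupParseError(f"{path} line {lineno}: expected 6 columns")
            _, pos, ref, _, bases, quals = parts[:6]
            rows.append(_parse_mpileup_row(int(pos), ref.upper(), bases, quals, lineno))
    df = pd.DataFrame(rows, columns=MACT_COLUMNS)
    return PileupTable(df=df, sample_id=sample_id or str(path))


def _parse_mpileup_row(pos: int, ref: str, bases: str, quals: str, lineno: int):
    counts = {b: [0, 0] for b in BASES}
    qsums = {b: [0.0, 0] for b in BASES}
    indels: dict[str, list[int]] = {}
    qi = 0  # index into the quality string (one char per read base, not per indel)
    i = 0
    last_strand = 0  # 0 fwd, 1 rev; strand of the read the next indel belongs to
    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            n = int(bases[i + 1 : j])
            seq = bases[j : j + n].upper()
            key = ch + seq
            indels.setdefault(key, [0, 0])[last_strand] += 1
            i = j + n
            continue
        if qi >= len(quals):
            raise PileupParseError(f"line {lineno}: quality string shorter than bases")
        q = ord(quals[qi]) - 33
        qi += 1
        if ch in ".,":
            strand = 0 if ch == "." else 1
            base = ref
        elif ch.upper() in BASES:
            strand = 0 if ch.isupper() else 1
            base = ch.upper()
        elif ch in "*<>Nn":
            i += 1
            last_strand = 0
            continue
        else:
            raise PileupParseError(f"line {lineno}: unexpected pileup char {ch!r}")
        counts[base][strand] += 1
        qsums[base][0] += q
        qsums[base][1] += 1
        last_strand = strand
        i += 1
    row = {"pos": pos, "ref": ref}
    for b in BASES:
        row[f"{b}_f"], row[f"{b}_r"] = counts[b]
        row[f"mq_{b}"] = qsums[b][0] / qsums[b][1] if qsums[b][1] else 0.0
    row["indels"] = format_indel_field(
        [(a, f, r) for a, (f, r) in sorted(indels.items())]
    )
    return row
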