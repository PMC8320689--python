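"""K-mer maternal-haplogroup classification.

A haplogroup library maps each haplogroup label to the set of all
length-k substrings of that haplogroup's consensus mitochondrial genome,
circularized (wrap-around k-mers included). A sample is classified by
containment: ``score(label) = |sample_kmers & library_kmers(label)| /
|library_kmers(label)|``; the best-scoring label wins, ties broken
lexicographically. The sample's k-mers are taken from its germline
consensus — rCRS with the subject's germline substitutions applied — so
no read-level data is needed.

The bundled library is a SYNTHETIC fixture: a dozen divergent consensus
sequences derived from rCRS by fixed substitution sets, with real
haplogroup label names and a declared macrogroup map, but NOT real
Phylotree data. A real library in the same serialized format can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from scipy import stats

from mitosoma.reference import MitoGenomeModel

DEFAULT_K = 12


class HaplogroupError(ValueError):
    pass


@dataclass
class HaplogroupLibrary:
    entries: dict[str, frozenset[str]]
    k: int = DEFAULT_K
    macro_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, kmers in self.entries.items():
            if any(len(m) != self.k for m in kmers):
                raise HaplogroupError(f"{label}: k-mer length != {self.k}")
            if label not in self.macro_map:
                raise HaplogroupError(f"{label}: missing macro_map entry")

    def labels(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class HaplogroupCall:
    subject_id: str
    best_label: str
    best_score: float
    alternates: list[tuple[str, float]]  # descending score, best first
    macro: str


def circular_kmers(sequence: str, k: int) -> frozenset[str]:
    """All k-mers of a circular sequence; k-mers containing non-ACGT dropped."""
    ext = sequence + sequence[: k - 1]
    ok = set("ACGT")
    return frozenset(
        ext[i : i + k]
        for i in range(len(sequence))
        if set(ext[i : i + k]) <= ok
    )


def build_library(
    consensus_seqs: dict[str, str], macro_map: dict[str, str], k: int = DEFAULT_K
) -> HaplogroupLibrary:
    """Build a k-mer library from per-haplogroup consensus sequences.

    Sequences with more than 1% non-ACGT characters are rejected.
    """
    if len(consensus_seqs) < 2:
        raise HaplogroupError("need at least 2 haplogroup consensus sequences")
    entries = {}
    for label, seq in consensus_seqs.items():
        seq = seq.upper()
        bad = sum(c not in "ACGT" for c in seq)
        if bad > 0.01 * len(seq):
            raise HaplogroupError(f"{label}: >1% non-ACGT characters")
        entries[label] = circular_kmers(seq, k)
    return HaplogroupLibrary(entries=entries, k=k, macro_map=dict(macro_map))


def classify(
    sample: str | frozenset[str], library: HaplogroupLibrary, subject_id: str = ""
) -> HaplogroupCall:
    """Containment-score classification of a sample consensus (or k-mer set)."""
    if not library.entries:
        raise HaplogroupError("empty haplogroup library")
    kmers = (
        circular_kmers(sample, library.k) if isinstance(sample, str) else frozenset(sample)
    )
    scored = sorted(
        (
            (label, len(kmers & lib_kmers) / len(lib_kmers))
            for label, lib_kmers in library.entries.items()
        ),
        key=lambda t: (-t[1], t[0]),
    )
    best_label, best_score = scored[0]
    return HaplogroupCall(
        subject_id=subject_id,
        best_label=best_label,
        best_score=best_score,
        alternates=scored,
        macro=library.macro_map[best_label],
    )


def serialize_library(library: HaplogroupLibrary, path) -> None:
    """Sorted text serialization (diff-able): header then `label<TAB>kmer` rows."""
    with open(path, "w") as fh:
        fh.write(f"#k={library.k}\n")
        for label in library.labels():
            fh.write(f"#macro\t{label}\t{library.macro_map[label]}\n")
        for label in library.labels():
            for kmer in sorted(library.entries[label]):
                fh.write(f"{label}\t{kmer}\n")


def deserialize_library(path) -> HaplogroupLibrary:
    k = None
    macro: dict[str, str] = {}
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#k="):
                k = int(line[3:])
            elif line.startswith("#macro\t"):
                _, label, m = line.split("\t")
                macro[label] = m
            elif line:
                label, kmer = line.split("\t")
                entries.setdefault(label, set()).add(kmer)
    if k is None:
        raise HaplogroupError(f"{path}: missing #k= header")
    return HaplogroupLibrary(
        entries={l: frozenset(s) for l, s in entries.items()}, k=k, macro_map=macro
    )


# ---------------------------------------------------------------------------
# bundled synthetic definitions
# ---------------------------------------------------------------------------

def load_haplogroup_defs(path=None) -> tuple[dict[str, list[tuple[int, str, str]]], dict[str, str]]:
    """Load haplogroup-defining substitutions: label -> [(pos, ref, alt)], macro map."""
    path = path or resources.files("mitosoma.data").joinpath(
        "haplogroup_defs_synthetic.tsv"
    )
    defs: dict[str, list[tuple[int, str, str]]] = {}
    macro: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in df.iterrows():
        variants = []
        for item in row["variants"].split(","):
            pos_part, alleles = item.split(":")
            ref, alt = alleles.split(">")
            variants.append((int(pos_part), ref, alt))
        defs[row["label"]] = variants
        macro[row["label"]] = row["macro"]
    return defs, macro


def consensus_from_variants(
    model: MitoGenomeModel, variants: list[tuple[int, str, str]]
) -> str:
    """Apply substitution variants (pos, ref, alt) to rCRS."""
    seq = list(model.sequence)
    for pos, ref, alt in variants:
        if seq[pos - 1] != ref:
            raise HaplogroupError(f"ref mismatch at {pos}: {seq[pos - 1]} != {ref}")
        seq[pos - 1] = alt
    return "".join(seq)


def default_library(model: MitoGenomeModel, k: int = DEFAULT_K) -> HaplogroupLibrary:
    defs, macro = load_haplogroup_defs()
    seqs = {label: consensus_from_variants(model, v) for label, v in defs.items()}
    return build_library(seqs, macro, k=k)


# ---------------------------------------------------------------------------
# composition reporting
# ---------------------------------------------------------------------------

def haplogroup_composition(
    calls: list[HaplogroupCall], sample_sheet: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Macro/major composition and a subtype x haplogroup homogeneity test.

    Returns (composition table, subtype x major contingency table,
    homogeneity p-value). The test is chi-square when all expected cell
    counts allow it; with sparse tables the chi-square p is still
    reported (the exact alternative is impractical beyond 2x2).
    """
    subjects = sample_sheet.drop_duplicates("subject_id").set_index("subject_id")
    rows = []
    for c in calls:
        if c.subject_id not in subjects.index:
            raise KeyError(f"subject {c.subject_id} missing from sample sheet")
        rows.append(
            {
                "subject_id": c.subject_id,
                "major": c.best_label,
                "macro": c.macro,
                "subtype": subjects.loc[c.subject_id, "subtype"],
            }
        )
    df = pd.DataFrame(rows)
    comp_rows = []
    for level in ("macro", "major"):
        counts = df[level].value_counts()
        for label, n in counts.items():
            comp_rows.append(
                {
                    "level": level,
                    "label": label,
                    "n": int(n),
                    "percent": round(100.0 * n / len(df), 1),
                }
            )
    composition = pd.DataFrame(comp_rows)
    ctab = pd.crosstab(df["subtype"], df["major"])
    if ctab.shape[0] > 1 and ctab.shape[1] > 1:
        p = float(stats.chi2_contingency(ctab.to_numpy())[1])
    else:
        p = 1.0
    return composition, ctab, p
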