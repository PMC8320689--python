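"""Tumor-only (somatic) mutation derivation.

A tumor PASS call graduates to a somatic mutation only if it survives,
in order:

1. germline subtraction — the same allele must not be a PASS call in
   the matched normal, and the raw (unweighted) alternate read fraction
   in the normal pileup must stay below a germline-presence threshold
   (default 1%), conservative against low-level germline leakage;
2. the cohort-recurrence filter — alleles present in strictly more than
   ``max_fraction`` (default 10%) of distinct subjects' tumor candidate
   sets are removed everywhere, catching systematic artifacts and
   residual common polymorphisms;
3. a common-variant blacklist of known germline polymorphisms
   (MitoMap-style, exact allele match).

Every removal is recorded, so for each sample
``|tumor PASS| = |somatic| + |germline| + |recurrent| + |blacklisted|``
holds exactly (the audit-conservation invariant).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from mitosoma.pileup import BASES, PileupTable, parse_indel_field

SOMATIC_COLUMNS = [
    "sample_id", "subject_id", "subtype", "position", "ref", "alt",
    "vaf", "normal_vaf", "depth", "p_value", "q_value", "filter_trail",
]


class PairingError(ValueError):
    pass


class BlacklistParseError(ValueError):
    pass


@dataclass(frozen=True)
class BlacklistEntry:
    position: int
    ref: str
    alt: str
    source: str = "common-germline"


def load_blacklist(path=None) -> pd.DataFrame:
    """Read a blacklist TSV (``pos  ref  alt  source``); bundled file by default."""
    path = path or resources.files("mitosoma.data").joinpath("blacklist_common.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    expected = ["pos", "ref", "alt", "source"]
    if list(df.columns) != expected:
        raise BlacklistParseError(f"{path}: columns {list(df.columns)} != {expected}")
    if df[["pos", "ref", "alt"]].duplicated().any():
        raise BlacklistParseError(f"{path}: duplicate (pos, ref, alt) entries")
    return df


def normal_raw_fraction(normal_pileup: PileupTable, position: int, alt: str) -> float:
    """Unweighted alternate-read fraction in the normal at one allele."""
    sub = normal_pileup.df[normal_pileup.df["pos"] == position]
    if sub.empty:
        return 0.0
    row = sub.iloc[0]
    base_depth = int(sum(row[f"{b}_{s}"] for b in BASES for s in "fr"))
    indels = parse_indel_field(str(row["indels"]))
    depth = base_depth + sum(f + r for _, f, r in indels)
    if depth == 0:
        return 0.0
    if alt[0] in "+-":
        k = sum(f + r for a, f, r in indels if a == alt)
    else:
        k = int(row[f"{alt}_f"] + row[f"{alt}_r"])
    return k / depth


def subtract_germline(
    tumor_calls: pd.DataFrame,
    normal_calls: pd.DataFrame,
    normal_pileup: PileupTable,
    threshold: float = 0.01,
    tumor_subject: str | None = None,
    normal_subject: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tumor PASS calls into (somatic candidates, germline-subtracted).

    A candidate is retained iff its (position, ref, alt) is not a PASS
    call in the normal AND its raw alternate fraction in the normal
    pileup is below ``threshold``. Retained candidates carry
    ``normal_vaf`` for audit.
    """
    if tumor_subject is not None and normal_subject is not None:
        if tumor_subject != normal_subject:
            raise PairingError(
                f"tumor subject {tumor_subject!r} != normal subject {normal_subject!r}"
            )
    tumor_pass = tumor_calls[tumor_calls["filters"] == "PASS"].copy()
    normal_pass = normal_calls[normal_calls["filters"] == "PASS"]
    normal_keys = set(
        zip(normal_pass["position"], normal_pass["ref"], normal_pass["alt"])
    )
    nvafs = [
        normal_raw_fraction(normal_pileup, int(r.position), str(r.alt))
        for r in tumor_pass.itertuples()
    ]
    tumor_pass["normal_vaf"] = nvafs
    in_normal = [
        (int(r.position), str(r.ref), str(r.alt)) in normal_keys
        for r in tumor_pass.itertuples()
    ]
    germline_mask = np.asarray(in_normal) | (
        tumor_pass["normal_vaf"].to_numpy() >= threshold
    ) if len(tumor_pass) else np.zeros(0, dtype=bool)
    somatic = tumor_pass[~germline_mask].reset_index(drop=True)
    germline = tumor_pass[germline_mask].reset_index(drop=True)
    return somatic, germline


def cohort_recurrence_filter(
    candidates: pd.DataFrame,
    max_fraction: float = 0.10,
    by: str = "subject_id",
    n_units: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove alleles recurring in strictly more than ``max_fraction`` of subjects.

    ``candidates`` spans the whole cohort (one row per candidate per
    sample) and must carry a ``by`` column (subjects by default; set
    ``by="sample_id"`` to count samples instead). ``n_units`` is the
    denominator — all subjects (or samples) in the run, including those
    without candidates; when omitted it falls back to the units present
    in ``candidates``. Returns (kept, removed).
    """
    if candidates.empty:
        return candidates, candidates
    if n_units is None:
        n_units = candidates[by].nunique()
    carriers = (
        candidates.drop_duplicates([by, "position", "ref", "alt"])
        .groupby(["position", "ref", "alt"])
        .size()
    )
    recurrent = {
        key for key, n in carriers.items() if n / n_units > max_fraction
    }
    keys = list(zip(candidates["position"], candidates["ref"], candidates["alt"]))
    mask = np.array([k in recurrent for k in keys])
    return (
        candidates[~mask].reset_index(drop=True),
        candidates[mask].reset_index(drop=True),
    )


def blacklist_filter(
    candidates: pd.DataFrame, blacklist: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove exact (position, ref, alt) blacklist matches. Returns (kept, removed)."""
    if candidates.empty or blacklist.empty:
        return candidates, candidates.iloc[0:0]
    bad = set(zip(blacklist["pos"], blacklist["ref"], blacklist["alt"]))
    keys = list(zip(candidates["position"], candidates["ref"], candidates["alt"]))
    mask = np.array([k in bad for k in keys])
    return (
        candidates[~mask].reset_index(drop=True),
        candidates[mask].reset_index(drop=True),
    )


@dataclass
class SomaticAudit:
    """Per-sample conservation ledger over the somatic filtering stages."""

    tumor_pass: dict[str, int]
    germline_subtracted: dict[str, int]
    recurrence_removed: dict[str, int]
    blacklist_removed: dict[str, int]
    somatic: dict[str, int]

    def conserved(self) -> bool:
        return all(
            self.tumor_pass[s]
            == self.somatic.get(s, 0)
            + self.germline_subtracted.get(s, 0)
            + self.recurrence_removed.get(s, 0)
            + self.blacklist_removed.get(s, 0)
            for s in self.tumor_pass
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s,
                "tumor_pass": self.tumor_pass[s],
                "germline_subtracted": self.germline_subtracted.get(s, 0),
                "recurrence_removed": self.recurrence_removed.get(s, 0),
                "blacklist_removed": self.blacklist_removed.get(s, 0),
                "somatic": self.somatic.get(s, 0),
            }
            for s in sorted(self.tumor_pass)
        ]
        return pd.DataFrame(rows)


def derive_somatic_cohort(
    per_pair: list[dict],
    blacklist: pd.DataFrame | None = None,
    germline_threshold: float = 0.01,
    recurrence_max_fraction: float = 0.10,
    recurrence_by: str = "subject_id",
) -> tuple[pd.DataFrame, SomaticAudit]:
    """Run the full somatic filter over a cohort.

    ``per_pair`` items are dicts with keys ``sample_id``, ``subject_id``,
    ``subtype``, ``tumor_calls``, ``normal_calls``, ``normal_pileup``.
    Returns the somatic mutation table (``SOMATIC_COLUMNS``) and the
    conservation audit.
    """
    blacklist = load_blacklist() if blacklist is None else blacklist
    candidates = []
    tumor_pass_n: dict[str, int] = {}
    germ_n: dict[str, int] = {}
    for item in per_pair:
        sid = item["sample_id"]
        somatic, germline = subtract_germline(
            item["tumor_calls"],
            item["normal_calls"],
            item["normal_pileup"],
            threshold=germline_threshold,
        )
        tumor_pass_n[sid] = len(somatic) + len(germline)
        germ_n[sid] = len(germline)
        somatic = somatic.assign(
            sample_id=sid,
            subject_id=item["subject_id"],
            subtype=item.get("subtype", ""),
            filter_trail="pass_caller;not_in_normal",
        )
        candidates.append(somatic)
    cand = (
        pd.concat(candidates, ignore_index=True)
        if candidates
        else pd.DataFrame(columns=SOMATIC_COLUMNS)
    )
    n_units = len({item["subject_id"] for item in per_pair}) if (
        recurrence_by == "subject_id"
    ) else len({item["sample_id"] for item in per_pair})
    kept, recurrent = cohort_recurrence_filter(
        cand, max_fraction=recurrence_max_fraction, by=recurrence_by, n_units=n_units
    )
    kept, blacklisted = blacklist_filter(kept, blacklist)
    if not kept.empty:
        kept = kept.assign(
            filter_trail=kept["filter_trail"] + ";not_recurrent;not_blacklisted"
        )
        kept = kept[SOMATIC_COLUMNS].sort_values(["sample_id", "position"]).reset_index(
            drop=True
        )
    else:
        kept = pd.DataFrame(columns=SOMATIC_COLUMNS)
    audit = SomaticAudit(
        tumor_pass=tumor_pass_n,
        germline_subtracted=germ_n,
        recurrence_removed=dict(recurrent.groupby("sample_id").size())
        if not recurrent.empty
        else {},
        blacklist_removed=dict(blacklisted.groupby("sample_id").size())
        if not blacklisted.empty
        else {},
        somatic=dict(kept.groupby("sample_id").size()) if not kept.empty else {},
    )
    return kept, audit
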