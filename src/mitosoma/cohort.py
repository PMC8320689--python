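"""Cohort-level burden and heteroplasmy statistics.

Summaries follow the analysis conventions of tumor/normal mtDNA cohort
studies: per-subtype mutation burden (mutations per sample) with
t-distribution 95% confidence intervals on per-sample counts, mean
heteroplasmy (VAF) per subtype, consequence-class composition,
two-group contrasts via a two-sided Fisher's exact test on the
samples-with/without-mutation 2x2 table (an exact Poisson rate test on
mutation counts is available as an alternative), recurrent-mutation
(hotspot) detection, and shared/gained/lost set algebra for subjects
with multiple specimens over time.

Categorical summaries use initial specimens only; subtypes below the
minimum sample count are reported in a separate small-n table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONSEQUENCE_CLASSES = [
    "missense", "synonymous", "stop_gain", "frameshift", "in_frame",
    "tRNA", "rRNA", "dloop", "intergenic",
]


class IntegrityError(ValueError):
    pass


@dataclass
class SubtypeSummary:
    subtype: str
    n_samples: int
    n_mutations: int
    mutations_per_sample: float
    mean_vaf: float | None
    vaf_ci: tuple[float, float] | None
    burden_ci: tuple[float, float] | None
    class_counts: dict[str, int]
    n_lof: int

    def to_row(self) -> dict:
        row = {
            "subtype": self.subtype,
            "n_samples": self.n_samples,
            "n_mutations": self.n_mutations,
            "mutations_per_sample": round(self.mutations_per_sample, 2),
            "mean_vaf": round(self.mean_vaf, 4) if self.mean_vaf is not None else "",
            "vaf_ci_low": round(self.vaf_ci[0], 4) if self.vaf_ci else "",
            "vaf_ci_high": round(self.vaf_ci[1], 4) if self.vaf_ci else "",
            "burden_ci_low": round(self.burden_ci[0], 4) if self.burden_ci else "",
            "burden_ci_high": round(self.burden_ci[1], 4) if self.burden_ci else "",
            "n_lof": self.n_lof,
        }
        for k in CONSEQUENCE_CLASSES:
            row[f"n_{k}"] = self.class_counts.get(k, 0)
        return row


def t_confidence_interval(values: np.ndarray, level: float = 0.95):
    """Mean and t-based CI of a sample (the one-sample t machinery)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = float(x.mean()) if n else float("nan")
    if n < 2 or np.allclose(x.std(ddof=1), 0):
        return mean, None
    half = stats.t.ppf(0.5 + level / 2, n - 1) * x.std(ddof=1) / np.sqrt(n)
    return mean, (mean - float(half), mean + float(half))


def _initial_tumors(sample_sheet: pd.DataFrame) -> pd.DataFrame:
    tumors = sample_sheet[sample_sheet["role"] == "tumor"].copy()
    tumors = tumors.sort_values(["subject_id", "timepoint", "sample_id"])
    initial = tumors.drop_duplicates("subject_id", keep="first")
    multi_dx = (
        tumors.groupby("subject_id")["subtype"].nunique().pipe(lambda s: s[s > 1]).index
    )
    return initial[~initial["subject_id"].isin(multi_dx)]


def summarize_subtypes(
    mutations: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_n: int = 15,
    vaf_over: str = "mutations",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subtype burden/heteroplasmy summary over initial tumor specimens.

    Subjects with multiple distinct diagnoses are excluded; for subjects
    with several specimens only the earliest timepoint counts. Subtypes
    with at least ``min_n`` samples appear in the main table, the rest
    in the small-n table. ``vaf_over`` averages VAF over "mutations"
    (default) or over "samples" (per-sample mean VAF first).
    """
    initial = _initial_tumors(sample_sheet)
    keep_samples = set(initial["sample_id"])
    if not mutations.empty:
        unjoined = set(mutations["sample_id"]) - set(sample_sheet["sample_id"])
        if unjoined:
            raise IntegrityError(f"mutations with unknown sample ids: {sorted(unjoined)}")
    muts = (
        mutations[mutations["sample_id"].isin(keep_samples)]
        if not mutations.empty
        else mutations
    )
    summaries = []
    for subtype, samples in initial.groupby("subtype"):
        ids = samples["sample_id"]
        sub = muts[muts["sample_id"].isin(set(ids))] if not muts.empty else muts
        per_sample = (
            sub.groupby("sample_id").size().reindex(ids, fill_value=0).to_numpy()
            if not sub.empty
            else np.zeros(len(ids), dtype=int)
        )
        burden_mean, burden_ci = t_confidence_interval(per_sample)
        if sub.empty:
            mean_vaf, vaf_ci = None, None
        elif vaf_over == "samples":
            mean_vaf, vaf_ci = t_confidence_interval(
                sub.groupby("sample_id")["vaf"].mean().to_numpy()
            )
        else:
            mean_vaf, vaf_ci = t_confidence_interval(sub["vaf"].to_numpy())
        class_counts = (
            sub["class"].value_counts().to_dict() if "class" in sub.columns else {}
        )
        n_lof = int(sub["is_lof"].sum()) if "is_lof" in sub.columns else 0
        summaries.append(
            SubtypeSummary(
                subtype=subtype,
                n_samples=len(ids),
                n_mutations=int(len(sub)),
                mutations_per_sample=burden_mean,
                mean_vaf=mean_vaf,
                vaf_ci=vaf_ci,
                burden_ci=burden_ci,
                class_counts=class_counts,
                n_lof=n_lof,
            )
        )
    rows = [s.to_row() for s in summaries]
    df = pd.DataFrame(rows).sort_values("subtype").reset_index(drop=True)
    main = df[df["n_samples"] >= min_n].reset_index(drop=True)
    small = df[df["n_samples"] < min_n].reset_index(drop=True)
    return main, small


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (with, without) x (a, b)
    fisher_p: float
    burden_a: float
    burden_b: float
    burden_ratio: float
    per_class: pd.DataFrame
    rate_test_p: float | None = None


def contrast_groups(
    mutations: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    method: str = "fisher",
) -> ContrastResult:
    """Two-subtype contrast on initial tumor specimens.

    ``method="fisher"`` (default) tests the samples-with-vs-without-
    mutation 2x2 table with a two-sided Fisher's exact test;
    ``method="poisson"`` additionally reports an exact Poisson
    two-sample rate test on total mutation counts.
    """
    initial = _initial_tumors(sample_sheet)
    out = {}
    for g in (group_a, group_b):
        ids = initial.loc[initial["subtype"] == g, "sample_id"]
        if ids.empty:
            raise ValueError(f"empty group {g!r}")
        sub = (
            mutations[mutations["sample_id"].isin(set(ids))]
            if not mutations.empty
            else mutations
        )
        n_with = int(sub["sample_id"].nunique()) if not sub.empty else 0
        out[g] = {
            "n": len(ids),
            "with": n_with,
            "muts": int(len(sub)),
            "sub": sub,
        }
    a, b = out[group_a], out[group_b]
    table = ((a["with"], b["with"]), (a["n"] - a["with"], b["n"] - b["with"]))
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    burden_a = a["muts"] / a["n"]
    burden_b = b["muts"] / b["n"]
    per_class_rows = []
    for k in CONSEQUENCE_CLASSES:
        if "class" not in mutations.columns:
            break
        ca = int((a["sub"]["class"] == k).sum()) if not a["sub"].empty else 0
        cb = int((b["sub"]["class"] == k).sum()) if not b["sub"].empty else 0
        per_class_rows.append(
            {
                "class": k,
                f"per_sample_{group_a}": round(ca / a["n"], 4),
                f"per_sample_{group_b}": round(cb / b["n"], 4),
            }
        )
    rate_p = None
    if method == "poisson":
        rate_p = float(
            stats.poisson_means_test(
                a["muts"], a["n"], b["muts"], b["n"], alternative="two-sided"
            ).pvalue
        )
    return ContrastResult(
        group_a=group_a,
        group_b=group_b,
        table=table,
        fisher_p=float(fisher_p),
        burden_a=burden_a,
        burden_b=burden_b,
        burden_ratio=burden_a / burden_b if burden_b else float("inf"),
        per_class=pd.DataFrame(per_class_rows),
        rate_test_p=rate_p,
    )


def find_hotspots(mutations: pd.DataFrame) -> pd.DataFrame:
    """Alleles carried by >= 2 distinct subjects, sorted by carriers then position."""
    if mutations.empty:
        return pd.DataFrame(
            columns=["position", "ref", "alt", "n_subjects", "subjects", "subtypes", "is_lof"]
        )
    grouped = mutations.drop_duplicates(["subject_id", "position", "ref", "alt"]).groupby(
        ["position", "ref", "alt"]
    )
    rows = []
    for (pos, ref, alt), g in grouped:
        if g["subject_id"].nunique() < 2:
            continue
        rows.append(
            {
                "position": int(pos),
                "ref": ref,
                "alt": alt,
                "n_subjects": int(g["subject_id"].nunique()),
                "subjects": ",".join(sorted(g["subject_id"].astype(str))),
                "subtypes": ",".join(sorted(set(g["subtype"].astype(str))))
                if "subtype" in g.columns
                else "",
                "is_lof": bool(g["is_lof"].any()) if "is_lof" in g.columns else False,
            }
        )
    df = pd.DataFrame(
        rows, columns=["position", "ref", "alt", "n_subjects", "subjects", "subtypes", "is_lof"]
    )
    if not df.empty:
        df = df.sort_values(
            ["n_subjects", "position"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def longitudinal_compare(
    mutations: pd.DataFrame, sample_sheet: pd.DataFrame, subject_id: str
) -> pd.DataFrame:
    """Shared/lost/gained allele sets between consecutive timepoints of one subject.

    Specimens from the same timepoint are compared symmetrically
    (intratumoral heterogeneity); consecutive distinct timepoints give
    one row each with shared, lost, and gained ``m.``-style keys. A
    single-specimen subject yields an empty frame (nothing to compare).
    """
    sheet = sample_sheet[
        (sample_sheet["subject_id"] == subject_id) & (sample_sheet["role"] == "tumor")
    ].sort_values(["timepoint", "sample_id"])
    if sheet.empty:
        raise KeyError(f"subject {subject_id} has no tumor specimens")
    def alleles(sample_ids) -> frozenset:
        if mutations.empty:
            return frozenset()
        sub = mutations[mutations["sample_id"].isin(set(sample_ids))]
        return frozenset(zip(sub["position"], sub["ref"], sub["alt"]))
    rows = []
    timepoints = sorted(sheet["timepoint"].unique())
    # same-day specimens: symmetric pairwise differences
    for tp in timepoints:
        ids = list(sheet.loc[sheet["timepoint"] == tp, "sample_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                s1, s2 = alleles([ids[i]]), alleles([ids[j]])
                rows.append(
                    _compare_row(subject_id, f"{ids[i]}|{ids[j]}", tp, tp,
                                 s1, s2, kind="same_day")
                )
    for t0, t1 in zip(timepoints, timepoints[1:]):
        s0 = alleles(sheet.loc[sheet["timepoint"] == t0, "sample_id"])
        s1 = alleles(sheet.loc[sheet["timepoint"] == t1, "sample_id"])
        rows.append(
            _compare_row(subject_id, f"t{t0}->t{t1}", t0, t1, s0, s1, kind="longitudinal")
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "comparison", "timepoint_a", "timepoint_b", "kind",
                 "shared", "lost", "gained"],
    )


def _fmt(keys: frozenset) -> str:
    return ";".join(f"{p}:{r}>{a}" for p, r, a in sorted(keys)) if keys else "."


def _compare_row(subject_id, label, ta, tb, set_a, set_b, kind):
    return {
        "subject_id": subject_id,
        "comparison": label,
        "timepoint_a": ta,
        "timepoint_b": tb,
        "kind": kind,
        "shared": _fmt(set_a & set_b),
        "lost": _fmt(set_a - set_b),
        "gained": _fmt(set_b - set_a),
    }
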