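"""Quality-aware pile-up variant caller with FDR control.

The caller scores every non-reference allele observed in a sample's
pileup against a per-site sequencing-error model, corrects the resulting
p-values for multiple testing with the Benjamini-Hochberg step-up
procedure across all alleles tested in the sample, and then applies the
stringent filter regime used for low-frequency mitochondrial
heteroplasmy: minimum coverage, minimum variant allele frequency (VAF),
and a strand-bias filter requiring both-strand support and a
non-significant Fisher's exact test on the ref/alt x strand table.

Base counts are quality-adjusted: reads below a Phred cutoff are dropped
and each surviving read contributes weight ``1 - 10**(-Q/10)`` (its
probability of being a correct base call). VAF is the ratio of
quality-weighted alternate to quality-weighted total counts, so it is an
(essentially unbiased) estimate of the heteroplasmy level.

The per-site test is a one-sided upper-tail binomial test of the raw
alternate read count against the site's mean per-read error rate
``10**(-Qbar/10)`` (floored at ``base_error_rate``). This is the closest
well-defined analogue of the published parameter regime; ``site_test``
is the single swap-in point should a different per-site test be wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mitosoma.pileup import (
    BASES,
    PileupColumn,
    PileupTable,
    parse_indel_field,
    row_to_column,
)

FILTER_NAMES = ("PASS", "low_cov", "low_vaf", "strand_bias", "fdr_fail")

CALL_COLUMNS = [
    "position", "ref", "alt", "vaf", "depth",
    "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
    "p_value", "q_value", "filters",
]


@dataclass(frozen=True)
class CallerConfig:
    min_vaf: float = 0.02
    min_depth: int = 100
    min_base_quality: int = 20
    base_error_rate: float = 1e-3
    fdr_alpha: float = 0.05
    strand_p_threshold: float = 1e-3
    min_alt_per_strand: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf <= 1:
            raise ValueError("min_vaf must be in (0,1]")
        if self.min_depth < 1 or self.min_alt_per_strand < 0:
            raise ValueError("bad depth/strand thresholds")
        if not 0 < self.base_error_rate < 1 or not 0 < self.fdr_alpha <= 1:
            raise ValueError("bad error rate / alpha")

    def with_(self, **kw) -> "CallerConfig":
        return replace(self, **kw)


@dataclass
class VariantCall:
    position: int
    ref: str
    alt: str  # base, "+SEQ" (insertion) or "-SEQ" (deletion)
    vaf: float
    depth: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    p_value: float
    q_value: float
    filters: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_pass(self) -> bool:
        return self.filters == frozenset({"PASS"})


def phred_weight(q: np.ndarray | float) -> np.ndarray | float:
    """Probability that a base call at Phred quality Q is correct."""
    return 1.0 - np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def adjusted_counts(column: PileupColumn, config: CallerConfig) -> dict[str, float]:
    """Quality-adjusted effective count per allele.

    Reads at alleles whose mean Phred quality is below
    ``config.min_base_quality`` are dropped; surviving reads each
    contribute ``1 - 10**(-Q/10)``.
    """
    out: dict[str, float] = {}
    for allele, (f, r) in column.counts.items():
        q = column.quality(allele)
        out[allele] = 0.0 if q < config.min_base_quality else (f + r) * float(phred_weight(q))
    return out


def site_error_rate(column: PileupColumn, config: CallerConfig) -> float:
    """Mean per-read error probability at the site, floored at base_error_rate."""
    num = den = 0.0
    for allele, (f, r) in column.counts.items():
        q = column.quality(allele)
        if q >= config.min_base_quality:
            num += (f + r) * q
            den += f + r
    if den == 0:
        return config.base_error_rate
    return max(float(10.0 ** (-(num / den) / 10.0)), config.base_error_rate)


def site_test(column: PileupColumn, allele: str, config: CallerConfig) -> float:
    """One-sided upper-tail binomial p-value for the allele's read count.

    Tests H0: the ``alt_count`` alternate reads among ``depth`` reads are
    sequencing errors arising at the site's quality-derived error rate.
    Absent alleles give p = 1.
    """
    if allele not in column.counts or column.quality(allele) < config.min_base_quality:
        return 1.0
    depth = _surviving_depth(column, config)
    k = column.count(allele)
    if depth < 1 or k == 0:
        return 1.0
    eps = site_error_rate(column, config)
    return float(stats.binom.sf(k - 1, depth, eps))


def _surviving_depth(column: PileupColumn, config: CallerConfig) -> int:
    return int(
        sum(
            f + r
            for allele, (f, r) in column.counts.items()
            if column.quality(allele) >= config.min_base_quality
        )
    )


def fisher_strand_p(
    ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int
) -> float:
    """Two-sided Fisher's exact p on the (ref, alt) x (fwd, rev) table."""
    _, p = stats.fisher_exact(
        [[ref_fwd, ref_rev], [alt_fwd, alt_rev]], alternative="two-sided"
    )
    return float(p)


def strand_bias_filter(call: VariantCall, config: CallerConfig) -> bool:
    """True when the call survives the strand-bias filter.

    Fails when either strand carries fewer than ``min_alt_per_strand``
    alternate reads, or when alternate reads are distributed across
    strands significantly differently from reference reads (two-sided
    Fisher's exact p below ``strand_p_threshold``).
    """
    if min(call.alt_fwd, call.alt_rev) < config.min_alt_per_strand:
        return False
    p = fisher_strand_p(call.ref_fwd, call.ref_rev, call.alt_fwd, call.alt_rev)
    return p >= config.strand_p_threshold


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# whole-sample calling (vectorized)
# ---------------------------------------------------------------------------

def call_sample(pileup: PileupTable, config: CallerConfig | None = None) -> pd.DataFrame:
    """Call every non-reference allele in one sample's pileup.

    Returns a DataFrame with one row per tested allele (columns
    ``CALL_COLUMNS``); ``filters`` is "PASS" or a comma-joined subset of
    {low_cov, low_vaf, strand_bias, fdr_fail}. Non-PASS calls are
    retained so that every filter decision is auditable.

    The expensive Fisher's exact component of the strand filter is only
    evaluated for calls that survive the coverage/VAF/FDR gates and the
    cheap both-strand-representation check; for calls already failed by
    another filter the strand flag reflects the representation check
    alone.
    """
    config = config or CallerConfig()
    df = pileup.df

    f_cols = [f"{b}_f" for b in BASES]
    r_cols = [f"{b}_r" for b in BASES]
    q_cols = [f"mq_{b}" for b in BASES]
    fwd = df[f_cols].to_numpy(dtype=np.int64)
    rev = df[r_cols].to_numpy(dtype=np.int64)
    mq = df[q_cols].to_numpy(dtype=float)
    raw = fwd + rev

    keep = mq >= config.min_base_quality          # quality cutoff per allele
    surv = np.where(keep, raw, 0)
    weight = np.where(keep, phred_weight(mq), 0.0)
    eff = surv * weight

    depth_raw = raw.sum(axis=1)                   # DP: all reads at the site
    depth_surv = surv.sum(axis=1)
    eff_depth = eff.sum(axis=1)

    qbar_num = (surv * np.where(keep, mq, 0.0)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        qbar = np.where(depth_surv > 0, qbar_num / np.maximum(depth_surv, 1), 0.0)
    eps = np.maximum(10.0 ** (-qbar / 10.0), config.base_error_rate)

    ref_idx = np.full(len(df), -1)
    base_to_i = {b: i for i, b in enumerate(BASES)}
    refs = df["ref"].to_numpy()
    for b, i in base_to_i.items():
        ref_idx[refs == b] = i

    positions = df["pos"].to_numpy()
    ref_f = np.where(
        ref_idx >= 0, np.take_along_axis(fwd, np.maximum(ref_idx, 0)[:, None], 1)[:, 0], 0
    )
    ref_r = np.where(
        ref_idx >= 0, np.take_along_axis(rev, np.maximum(ref_idx, 0)[:, None], 1)[:, 0], 0
    )

    # substitution candidates: every non-ref base allele with surviving reads
    cand_rows, cand_alleles = np.nonzero((surv > 0) & (np.arange(4) != ref_idx[:, None]))
    base_arr = np.array(BASES)
    with np.errstate(invalid="ignore", divide="ignore"):
        sub_vaf = np.where(
            eff_depth[cand_rows] > 0,
            eff[cand_rows, cand_alleles] / np.maximum(eff_depth[cand_rows], 1e-300),
            0.0,
        )
    frames = [
        pd.DataFrame(
            {
                "position": positions[cand_rows],
                "ref": refs[cand_rows],
                "alt": base_arr[cand_alleles],
                "vaf": sub_vaf,
                "depth": depth_raw[cand_rows],
                "alt_fwd": fwd[cand_rows, cand_alleles],
                "alt_rev": rev[cand_rows, cand_alleles],
                "ref_fwd": ref_f[cand_rows],
                "ref_rev": ref_r[cand_rows],
                "_surv_alt": surv[cand_rows, cand_alleles],
                "_surv_depth": depth_surv[cand_rows],
                "_eps": eps[cand_rows],
            }
        )
    ]
    # indel candidates (weighted at the site's mean quality)
    indel_col = df["indels"].to_numpy()
    rows: list[dict] = []
    for ri in np.nonzero(indel_col != ".")[0]:
        for allele, f, r in parse_indel_field(str(indel_col[ri])):
            if f + r == 0 or qbar[ri] < config.min_base_quality:
                continue
            w = float(phred_weight(qbar[ri]))
            eff_alt = (f + r) * w
            ed = float(eff_depth[ri]) + eff_alt
            rows.append(
                {
                    "position": int(positions[ri]),
                    "ref": str(refs[ri]),
                    "alt": allele,
                    "vaf": eff_alt / ed if ed > 0 else 0.0,
                    "depth": int(depth_raw[ri]) + f + r,
                    "alt_fwd": f, "alt_rev": r,
                    "ref_fwd": int(ref_f[ri]), "ref_rev": int(ref_r[ri]),
                    "_surv_alt": f + r,
                    "_surv_depth": int(depth_surv[ri]) + f + r,
                    "_eps": float(eps[ri]),
                }
            )
    if rows:
        frames.append(pd.DataFrame(rows))
    calls = pd.concat(frames, ignore_index=True)
    if calls.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)

    calls["p_value"] = stats.binom.sf(
        calls["_surv_alt"].to_numpy() - 1,
        np.maximum(calls["_surv_depth"].to_numpy(), 1),
        calls.pop("_eps").to_numpy(),
    )
    calls["q_value"] = benjamini_hochberg(calls["p_value"].to_numpy())

    low_cov = calls["depth"].to_numpy() < config.min_depth
    low_vaf = calls["vaf"].to_numpy() < config.min_vaf
    fdr_fail = calls["q_value"].to_numpy() > config.fdr_alpha
    one_strand = (
        np.minimum(calls["alt_fwd"].to_numpy(), calls["alt_rev"].to_numpy())
        < config.min_alt_per_strand
    )

    strand_fail = one_strand.copy()
    need_fisher = np.nonzero(~(low_cov | low_vaf | fdr_fail | one_strand))[0]
    for i in need_fisher:
        r = calls.iloc[i]
        p = fisher_strand_p(
            int(r["ref_fwd"]), int(r["ref_rev"]), int(r["alt_fwd"]), int(r["alt_rev"])
        )
        if p < config.strand_p_threshold:
            strand_fail[i] = True

    flag_sets = []
    for lc, lv, sf, ff in zip(low_cov, low_vaf, strand_fail, fdr_fail):
        flags = [
            name
            for name, hit in (
                ("low_cov", lc), ("low_vaf", lv), ("strand_bias", sf), ("fdr_fail", ff)
            )
            if hit
        ]
        flag_sets.append(",".join(flags) if flags else "PASS")
    calls["filters"] = flag_sets
    calls = calls.drop(columns=["_surv_alt", "_surv_depth"])
    return calls[CALL_COLUMNS].sort_values(["position", "alt"]).reset_index(drop=True)


def calls_to_variant_calls(calls: pd.DataFrame) -> list[VariantCall]:
    out = []
    for _, r in calls.iterrows():
        out.append(
            VariantCall(
                position=int(r["position"]), ref=str(r["ref"]), alt=str(r["alt"]),
                vaf=float(r["vaf"]), depth=int(r["depth"]),
                alt_fwd=int(r["alt_fwd"]), alt_rev=int(r["alt_rev"]),
                ref_fwd=int(r["ref_fwd"]), ref_rev=int(r["ref_rev"]),
                p_value=float(r["p_value"]), q_value=float(r["q_value"]),
                filters=frozenset(str(r["filters"]).split(",")),
            )
        )
    return out


def pass_calls(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[calls["filters"] == "PASS"].reset_index(drop=True)


def call_single_column(column: PileupColumn, allele: str, config: CallerConfig) -> VariantCall:
    """Score one allele at one site (no FDR context: q = p)."""
    eff = adjusted_counts(column, config)
    eff_depth = sum(eff.values())
    p = site_test(column, allele, config)
    f, r = column.counts.get(allele, (0, 0))
    rf, rr = column.counts.get(column.ref, (0, 0))
    vaf = eff.get(allele, 0.0) / eff_depth if eff_depth > 0 else 0.0
    call = VariantCall(
        position=column.position, ref=column.ref, alt=allele, vaf=vaf,
        depth=column.depth, alt_fwd=f, alt_rev=r, ref_fwd=rf, ref_rev=rr,
        p_value=p, q_value=p,
    )
    flags = []
    if call.depth < config.min_depth:
        flags.append("low_cov")
    if call.vaf < config.min_vaf:
        flags.append("low_vaf")
    if not strand_bias_filter(call, config):
        flags.append("strand_bias")
    if call.q_value > config.fdr_alpha:
        flags.append("fdr_fail")
    call.filters = frozenset(flags) if flags else frozenset({"PASS"})
    return call
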