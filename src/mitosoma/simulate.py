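"""Synthetic tumor/normal pileup generator with a recoverable ground truth.

Each simulated subject gets a germline consensus (rCRS plus a haplogroup
backbone of near-fixed substitutions), whole-genome coverage at high
mean depth (the >1000x regime typical of mtDNA in standard WGS), and
Phred-quality-dependent sequencing errors. Tumor samples additionally
carry injected somatic heteroplasmies at 2-30% VAF; both samples can
carry one-strand artifact sites and low-level NuMT-like contamination
(haplogroup-discordant alleles capped below the 2% calling floor).
Every non-reference injection is recorded in a truth table so that
recovery, precision, and calibration are measurable downstream.

Per position the model is: depth ~ Poisson(mean_depth); each read
carries a Phred quality Q ~ Normal(mean_phred, phred_sd) clipped to
[2, 45] and errs with probability 10**(-Q/10) (erroneous base uniform
over the three alternatives), so the per-site error rate is the
analytic mean of 10**(-Q/10) under that quality distribution;
heteroplasmic alternate reads ~ Binomial(depth, true_vaf), split evenly
across strands (artifact sites force all alternate reads onto one
strand). The emitted table records, per allele, the mean quality of its
supporting reads, which concentrates around mean_phred with standard
error phred_sd / sqrt(reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from mitosoma.haplogroups import load_haplogroup_defs
from mitosoma.pileup import BASES, MACT_COLUMNS, PileupTable, format_indel_field
from mitosoma.reference import MT_LENGTH, MitoGenomeModel, load_reference

TRUTH_COLUMNS = [
    "sample_id", "subject_id", "position", "ref", "alt", "true_vaf", "origin",
]

#: per-subtype mean somatic burden (mutations per tumor); the cohort-wide
#: default of 0.41 is used for labels without an override
DEFAULT_SUBTYPE_RATES: dict[str, float] = {
    "LGG": 0.27,
    "HGG": 0.60,
    "EPN": 0.46,
    "MB": 0.57,
}


class SimulationError(ValueError):
    pass


@lru_cache(maxsize=16)
def mean_error_rate(mean_phred: float, phred_sd: float) -> float:
    """E[10**(-Q/10)] for per-read quality Q ~ Normal clipped to [2, 45].

    The clipped tails contribute point masses at the boundary
    qualities; the interior is integrated numerically.
    """
    from scipy import stats as _stats

    lo, hi = 2.0, 45.0
    if phred_sd <= 0:
        q = min(max(mean_phred, lo), hi)
        return float(10.0 ** (-q / 10.0))
    dist = _stats.norm(mean_phred, phred_sd)
    grid = np.linspace(lo, hi, 4097)
    interior = np.trapezoid(10.0 ** (-grid / 10.0) * dist.pdf(grid), grid)
    tails = dist.cdf(lo) * 10.0 ** (-lo / 10.0) + dist.sf(hi) * 10.0 ** (-hi / 10.0)
    return float(interior + tails)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pairs: int = 10
    mean_depth_tumor: float = 2000.0
    mean_depth_normal: float = 1500.0
    mean_phred: float = 30.0
    phred_sd: float = 5.0
    somatic_rate: float = 0.41
    vaf_range: tuple[float, float] = (0.02, 0.30)
    indel_fraction: float = 0.10  # single-base ins/del share of somatic injections
    artifact_rate: float = 1.0  # expected one-strand artifact sites per sample
    artifact_vaf_range: tuple[float, float] = (0.02, 0.10)
    numt_rate: float = 3.0  # expected contaminated sites per subject
    numt_vaf_max: float = 0.015
    germline_vaf_min: float = 0.985
    subtype_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_RATES)
    )

    def __post_init__(self) -> None:
        lo, hi = self.vaf_range
        if not (0 < lo <= hi <= 1):
            raise SimulationError("vaf_range must be within (0,1]")
        if self.mean_depth_tumor <= 0 or self.mean_depth_normal <= 0:
            raise SimulationError("depths must be positive")
        if self.somatic_rate < 0:
            raise SimulationError("somatic_rate must be >= 0")

    def rate_for(self, subtype: str) -> float:
        return self.subtype_rates.get(subtype, self.somatic_rate)


@dataclass
class SimulatedPair:
    subject_id: str
    subtype: str
    haplogroup: str
    tumor: PileupTable
    normal: PileupTable
    truth: pd.DataFrame  # TRUTH_COLUMNS


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    # derived per-subject stream: reproducible under parallel generation
    return np.random.default_rng([int(config.seed), int(subject_index)])


@dataclass
class PairPlan:
    """The injections planned for one subject, before pileup synthesis."""

    subject_id: str
    subtype: str
    haplogroup: str
    germline: list[tuple[int, str, str]]  # (pos, ref, alt)
    germline_vafs: np.ndarray
    tumor_events: list[tuple[int, str, float, str]]  # (pos, alt, vaf, origin)
    normal_events: list[tuple[int, str, float, str]]


def plan_pair(
    config: SimulationConfig,
    subject_index: int,
    model: MitoGenomeModel | None = None,
    subtype: str | None = None,
) -> PairPlan:
    """Draw the injections for one subject (no pileup synthesis)."""
    model = model or load_reference()
    rng = _subject_rng(config, subject_index)
    return _plan(rng, config, subject_index, model, subtype)


def _plan(
    rng: np.random.Generator,
    config: SimulationConfig,
    subject_index: int,
    model: MitoGenomeModel,
    subtype: str | None,
) -> PairPlan:
    defs, _macro = load_haplogroup_defs()
    labels = sorted(defs)
    haplogroup = labels[subject_index % len(labels)]
    if haplogroup not in defs:
        raise SimulationError(f"unknown haplogroup key {haplogroup}")
    if subtype is None:
        subs = sorted(config.subtype_rates) or ["CNS"]
        subtype = subs[subject_index % len(subs)]

    germline = list(defs[haplogroup])
    occupied = {p for p, _, _ in germline} | {3107}

    def _free_position(lo: int = 1, hi: int = MT_LENGTH - 1) -> int:
        while True:
            p = int(rng.integers(lo, hi + 1))
            if p not in occupied and model.base(p) != "N" and model.base(p + 1) != "N":
                occupied.add(p)
                return p

    # somatic injections (tumor only)
    n_somatic = int(rng.poisson(config.rate_for(subtype)))
    somatic: list[tuple[int, str, float, str]] = []  # (pos, alt_allele, vaf, origin)
    lo, hi = config.vaf_range
    for _ in range(n_somatic):
        pos = _free_position()
        vaf = float(rng.uniform(lo, hi))
        if rng.random() < config.indel_fraction:
            if rng.random() < 0.5:
                alt = "+" + str(rng.choice(list(BASES)))
            else:
                alt = "-" + model.base(pos + 1)
        else:
            alt = str(rng.choice([b for b in BASES if b != model.base(pos)]))
        somatic.append((pos, alt, vaf, "somatic"))

    # one-strand artifact sites, independently per sample
    def _artifacts() -> list[tuple[int, str, float, str]]:
        out = []
        alo, ahi = config.artifact_vaf_range
        for _ in range(int(rng.poisson(config.artifact_rate))):
            pos = _free_position()
            alt = str(rng.choice([b for b in BASES if b != model.base(pos)]))
            out.append((pos, alt, float(rng.uniform(alo, ahi)), "artifact"))
        return out

    tumor_artifacts = _artifacts()
    normal_artifacts = _artifacts()

    # NuMT-like contamination: haplogroup-discordant alleles, shared sites
    discordant = sorted(
        {
            (p, a)
            for lab in labels
            if lab != haplogroup
            for p, _r, a in defs[lab]
            if p not in occupied
        }
    )
    n_numt = min(int(rng.poisson(config.numt_rate)), len(discordant))
    numt_sites = [
        discordant[i]
        for i in rng.choice(len(discordant), size=n_numt, replace=False)
    ] if n_numt else []
    for p, _a in numt_sites:
        occupied.add(p)

    def _numt_events() -> list[tuple[int, str, float, str]]:
        return [
            (p, a, float(rng.uniform(0.002, config.numt_vaf_max)), "numt")
            for p, a in numt_sites
        ]

    germ_vafs = rng.uniform(config.germline_vaf_min, 1.0, size=len(germline))

    return PairPlan(
        subject_id=f"P{subject_index:04d}",
        subtype=subtype,
        haplogroup=haplogroup,
        germline=germline,
        germline_vafs=germ_vafs,
        tumor_events=somatic + tumor_artifacts + _numt_events(),
        normal_events=normal_artifacts + _numt_events(),
    )


def simulate_pair(
    config: SimulationConfig,
    subject_index: int,
    model: MitoGenomeModel | None = None,
    subtype: str | None = None,
) -> SimulatedPair:
    """Simulate one tumor/normal pair with truth rows for every injection."""
    model = model or load_reference()
    rng = _subject_rng(config, subject_index)
    plan = _plan(rng, config, subject_index, model, subtype)
    subject_id = plan.subject_id
    tumor_id = f"{subject_id}_T"
    normal_id = f"{subject_id}_N"
    germline = plan.germline
    germ_vafs = plan.germline_vafs
    tumor_events = plan.tumor_events
    normal_events = plan.normal_events
    subtype = plan.subtype

    tumor_df = _synthesize_sample(
        rng, model, germline, tumor_events, config.mean_depth_tumor, config
    )
    normal_df = _synthesize_sample(
        rng, model, germline, normal_events, config.mean_depth_normal, config
    )

    truth_rows = []
    for sid, events in ((tumor_id, tumor_events), (normal_id, normal_events)):
        for (pos, ref, alt), gv in zip(germline, germ_vafs):
            truth_rows.append((sid, subject_id, pos, ref, alt, float(gv), "germline"))
        for pos, alt, vaf, origin in events:
            truth_rows.append((sid, subject_id, pos, model.base(pos), alt, vaf, origin))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    return SimulatedPair(
        subject_id=subject_id,
        subtype=subtype,
        haplogroup=plan.haplogroup,
        tumor=PileupTable(df=tumor_df, sample_id=tumor_id),
        normal=PileupTable(df=normal_df, sample_id=normal_id),
        truth=truth,
    )


def _synthesize_sample(
    rng: np.random.Generator,
    model: MitoGenomeModel,
    germline: list[tuple[int, str, str]],
    events: list[tuple[int, str, float, str]],
    mean_depth: float,
    config: SimulationConfig,
) -> pd.DataFrame:
    n = MT_LENGTH
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_arr = np.frombuffer(model.sequence.encode(), dtype="S1")

    cons = np.full(n, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        cons[ref_arr == b.encode()] = i
    for pos, _ref, alt in germline:
        cons[pos - 1] = base_idx[alt]

    depth = rng.poisson(mean_depth, size=n).astype(np.int64)
    depth[cons < 0] = 0  # the rCRS placeholder N position is left uncovered
    err_p = mean_error_rate(config.mean_phred, config.phred_sd)

    # heteroplasmic injections first (alt reads), then errors on the remainder
    alt_counts = np.zeros((n, 4), dtype=np.int64)
    alt_fwd = np.zeros((n, 4), dtype=np.int64)
    indel_items: dict[int, list[tuple[str, int, int]]] = {}
    taken = np.zeros(n, dtype=np.int64)
    for pos, alt, vaf, origin in events:
        i = pos - 1
        k = int(rng.binomial(depth[i], vaf))
        if k == 0:
            continue
        if alt[0] in "+-":
            if origin == "artifact":
                f = k if rng.random() < 0.5 else 0
            else:
                f = int(rng.binomial(k, 0.5))
            indel_items.setdefault(pos, []).append((alt, f, k - f))
            taken[i] += k
        else:
            j = base_idx[alt]
            alt_counts[i, j] += k
            if origin == "artifact":
                alt_fwd[i, j] += k if rng.random() < 0.5 else 0
            else:
                alt_fwd[i, j] += int(rng.binomial(k, 0.5))
            taken[i] += k

    remaining = np.maximum(depth - taken, 0)
    n_err = rng.binomial(remaining, err_p)
    # distribute errors uniformly over the three non-consensus bases
    err_split = rng.multinomial(n_err, [1 / 3] * 3)
    covered = cons >= 0
    other = np.zeros((n, 3), dtype=np.int8)
    for i in range(4):
        mask = cons == i
        alts = [j for j in range(4) if j != i]
        other[mask] = alts
    err_counts = np.zeros((n, 4), dtype=np.int64)
    rows = np.nonzero(covered)[0]
    np.add.at(err_counts, (rows, other[rows, 0]), err_split[rows, 0])
    np.add.at(err_counts, (rows, other[rows, 1]), err_split[rows, 1])
    np.add.at(err_counts, (rows, other[rows, 2]), err_split[rows, 2])
    err_fwd = rng.binomial(err_counts, 0.5)

    cons_reads = remaining - n_err
    cons_fwd = rng.binomial(cons_reads, 0.5)
    counts = alt_counts + err_counts
    fwd = alt_fwd + err_fwd
    cons_rows = np.nonzero(covered)[0]
    counts[cons_rows, cons[cons_rows]] += cons_reads[cons_rows]
    fwd[cons_rows, cons[cons_rows]] += cons_fwd[cons_rows]
    rev = counts - fwd

    data = {"pos": np.arange(1, n + 1), "ref": ref_arr.astype("U1")}
    for b, i in base_idx.items():
        data[f"{b}_f"] = fwd[:, i]
        data[f"{b}_r"] = rev[:, i]
    data["indels"] = [
        format_indel_field(indel_items.get(p, [])) for p in range(1, n + 1)
    ]
    # mean quality of an allele's reads: ~N(mean_phred, phred_sd / sqrt(reads))
    for b in BASES:
        nb = counts[:, base_idx[b]]
        se = config.phred_sd / np.sqrt(np.maximum(nb, 1))
        mq = np.clip(rng.normal(config.mean_phred, se), 2.0, 45.0)
        data[f"mq_{b}"] = np.where(nb > 0, np.round(mq, 1), 0.0)
    return pd.DataFrame(data, columns=MACT_COLUMNS)


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    sample_sheet: pd.DataFrame
    pairs: list[SimulatedPair]
    truth: pd.DataFrame


def simulate_cohort(
    config: SimulationConfig,
    model: MitoGenomeModel | None = None,
    outdir: str | Path | None = None,
) -> SimulatedCohort:
    """Simulate ``config.n_pairs`` tumor/normal pairs.

    Subjects take haplogroups round-robin from the bundled library and
    subtype labels round-robin from ``config.subtype_rates``. When
    ``outdir`` is given, one MACT pileup TSV per sample plus
    ``sample_sheet.tsv`` and ``truth.tsv`` are written there; an
    existing file at any target path is an error.
    """
    if config.n_pairs < 1:
        raise SimulationError("n_pairs must be >= 1")
    model = model or load_reference()
    pairs = [simulate_pair(config, i, model=model) for i in range(config.n_pairs)]
    sheet_rows = []
    for p in pairs:
        for role, table in (("tumor", p.tumor), ("normal", p.normal)):
            sheet_rows.append(
                {
                    "sample_id": table.sample_id,
                    "subject_id": p.subject_id,
                    "subtype": p.subtype,
                    "role": role,
                    "timepoint": 0,
                }
            )
    sheet = pd.DataFrame(sheet_rows)
    truth = pd.concat([p.truth for p in pairs], ignore_index=True)
    cohort = SimulatedCohort(sample_sheet=sheet, pairs=pairs, truth=truth)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in (
        ("sample_sheet.tsv", cohort.sample_sheet),
        ("truth.tsv", cohort.truth),
    ):
        target = outdir / name
        if target.exists():
            raise FileExistsError(f"refusing to overwrite {target}")
        frame.to_csv(target, sep="\t", index=False)
        paths.append(target)
    for p in cohort.pairs:
        for table in (p.tumor, p.normal):
            target = outdir / f"{table.sample_id}.pileup.tsv"
            if target.exists():
                raise FileExistsError(f"refusing to overwrite {target}")
            table.to_tsv(target)
            paths.append(target)
    return paths
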