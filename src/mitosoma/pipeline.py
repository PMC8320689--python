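"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in the order the analysis requires: (optional) simulate ->
call each sample -> germline-subtract each pair -> cohort recurrence +
blacklist filters -> consequence annotation -> haplogroup assignment ->
cohort summaries. Every artifact is hashed into a manifest
(``stage  artifact  sha256  seconds``) so a rerun with the same
configuration can be verified byte-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from mitosoma.annotate import annotate_somatic_table, lof_summary
from mitosoma.caller import CallerConfig, call_sample
from mitosoma.cohort import find_hotspots, longitudinal_compare, summarize_subtypes
from mitosoma.haplogroups import (
    classify,
    default_library,
    deserialize_library,
    haplogroup_composition,
)
from mitosoma.pileup import PileupTable
from mitosoma.reference import load_reference
from mitosoma.simulate import SimulationConfig, simulate_cohort
from mitosoma.somatic import derive_somatic_cohort, load_blacklist
from mitosoma.vcfio import write_vcf

log = logging.getLogger("mitosoma")


class ValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    output_dir: str = "mitosoma_run"
    sample_sheet: str = ""  # blank with simulate=True
    pileup_dir: str = ""
    blacklist: str = ""  # blank -> bundled fixture
    haplogroup_library: str = ""  # blank -> bundled synthetic library
    simulate: bool = False
    seed: int = 0
    n_pairs: int = 6
    min_vaf: float = 0.02
    min_depth: int = 100
    min_base_quality: int = 20
    fdr_alpha: float = 0.05
    strand_p_threshold: float = 1e-3
    germline_threshold: float = 0.01
    recurrence_max_fraction: float = 0.10
    recurrence_by: str = "subject_id"
    min_subtype_n: int = 15
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` config file; unknown keys are an error."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = _coerce(cls, key, val)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


def _coerce(cls, key, val):
    default = getattr(cls(), key)
    if isinstance(default, bool):
        return val.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(val)
    if isinstance(default, float):
        return float(val)
    return val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    rows: list[dict] = field(default_factory=list)

    def add(self, stage: str, artifact: Path, seconds: float) -> None:
        self.rows.append(
            {
                "stage": stage,
                "artifact": str(artifact),
                "sha256": _sha256(artifact),
                "seconds": round(seconds, 3),
            }
        )

    def verify_immutable(self) -> None:
        for row in self.rows:
            current = _sha256(Path(row["artifact"]))
            if current != row["sha256"]:
                raise StageError(
                    "manifest", f"artifact {row['artifact']} changed during the run"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "artifact", "sha256", "seconds"])


def validate_config(config: RunConfig) -> None:
    if not config.simulate:
        for key in ("sample_sheet", "pileup_dir"):
            p = getattr(config, key)
            if not p or not Path(p).exists():
                raise ValidationError(f"{key} path {p!r} does not exist")
    for key in ("blacklist", "haplogroup_library"):
        p = getattr(config, key)
        if p and not Path(p).exists():
            raise ValidationError(f"{key} path {p!r} does not exist")


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute all stages; returns the manifest DataFrame (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    validate_config(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "run_config.txt")
    manifest = Manifest()
    model = load_reference()
    caller_cfg = CallerConfig(
        min_vaf=config.min_vaf,
        min_depth=config.min_depth,
        min_base_quality=config.min_base_quality,
        fdr_alpha=config.fdr_alpha,
        strand_p_threshold=config.strand_p_threshold,
    )

    # -- inputs (simulated or on-disk) ------------------------------------
    t0 = time.time()
    if config.simulate:
        sim_dir = outdir / "simulated"
        cohort = simulate_cohort(
            SimulationConfig(seed=config.seed, n_pairs=config.n_pairs),
            model=model,
            outdir=None,
        )
        sheet = cohort.sample_sheet
        pileups = {
            t.sample_id: t for p in cohort.pairs for t in (p.tumor, p.normal)
        }
        sim_dir.mkdir(exist_ok=True)
        sheet.to_csv(sim_dir / "sample_sheet.tsv", sep="\t", index=False)
        cohort.truth.to_csv(sim_dir / "truth.tsv", sep="\t", index=False)
        manifest.add("simulate", sim_dir / "sample_sheet.tsv", time.time() - t0)
        manifest.add("simulate", sim_dir / "truth.tsv", 0.0)
        log.info("simulated %d pairs", config.n_pairs)
    else:
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        pileups = {}
        for sid in sheet["sample_id"]:
            path = Path(config.pileup_dir) / f"{sid}.pileup.tsv"
            if not path.exists():
                raise ValidationError(f"missing pileup for {sid}: {path}")
            pileups[sid] = PileupTable.from_tsv(path, sample_id=sid)

    # -- per-sample calling ------------------------------------------------
    t0 = time.time()
    call_dir = outdir / "calls"
    call_dir.mkdir(exist_ok=True)
    calls: dict[str, pd.DataFrame] = {}
    try:
        for sid, table in pileups.items():
            calls[sid] = call_sample(table, caller_cfg)
            vcf = call_dir / f"{sid}.vcf"
            write_vcf(calls[sid][calls[sid]["filters"] == "PASS"], vcf)
            manifest.add("call", vcf, 0.0)
    except Exception as exc:
        raise StageError("call", f"sample {sid}: {exc}") from exc
    manifest.rows[-1]["seconds"] = round(time.time() - t0, 3)

    # -- germline subtraction + cohort filters -----------------------------
    t0 = time.time()
    blacklist = (
        load_blacklist(config.blacklist) if config.blacklist else load_blacklist()
    )
    tumors = sheet[sheet["role"] == "tumor"]
    normals = sheet[sheet["role"] == "normal"].set_index("subject_id")
    per_pair = []
    try:
        for r in tumors.itertuples():
            if r.subject_id not in normals.index:
                raise StageError("somatic", f"no normal for subject {r.subject_id}")
            nid = normals.loc[r.subject_id, "sample_id"]
            if isinstance(nid, pd.Series):
                nid = nid.iloc[0]
            per_pair.append(
                {
                    "sample_id": r.sample_id,
                    "subject_id": r.subject_id,
                    "subtype": r.subtype,
                    "tumor_calls": calls[r.sample_id],
                    "normal_calls": calls[nid],
                    "normal_pileup": pileups[nid],
                }
            )
        somatic, audit = derive_somatic_cohort(
            per_pair,
            blacklist=blacklist,
            germline_threshold=config.germline_threshold,
            recurrence_max_fraction=config.recurrence_max_fraction,
            recurrence_by=config.recurrence_by,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("somatic", str(exc)) from exc
    somatic_path = outdir / "somatic.tsv"
    audit_path = outdir / "somatic_audit.tsv"
    somatic.to_csv(somatic_path, sep="\t", index=False)
    audit.to_frame().to_csv(audit_path, sep="\t", index=False)
    write_vcf(somatic, outdir / "somatic.vcf", somatic=True)
    manifest.add("somatic", somatic_path, time.time() - t0)
    manifest.add("somatic", audit_path, 0.0)
    manifest.add("somatic", outdir / "somatic.vcf", 0.0)
    if not audit.conserved():
        raise StageError("somatic", "filter audit does not conserve call counts")

    # -- annotation ---------------------------------------------------------
    t0 = time.time()
    try:
        annotated = annotate_somatic_table(somatic, model)
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc
    ann_path = outdir / "somatic_annotated.tsv"
    annotated.to_csv(ann_path, sep="\t", index=False)
    lof_path = outdir / "lof_summary.tsv"
    lof_summary(annotated, model).to_csv(lof_path, sep="\t", index=False)
    manifest.add("annotate", ann_path, time.time() - t0)
    manifest.add("annotate", lof_path, 0.0)

    # -- haplogroups --------------------------------------------------------
    t0 = time.time()
    try:
        library = (
            deserialize_library(config.haplogroup_library)
            if config.haplogroup_library
            else default_library(model)
        )
        hap_calls = []
        seq = list(model.sequence)
        for r in normals.reset_index().itertuples():
            nc = calls[r.sample_id]
            germ = nc[
                (nc["filters"] == "PASS")
                & (nc["alt"].str.len() == 1)
                & ~nc["alt"].str.startswith(("+", "-"))
            ]
            consensus = list(seq)
            for rec in germ.itertuples():
                consensus[int(rec.position) - 1] = str(rec.alt)
            hap_calls.append(classify("".join(consensus), library, subject_id=r.subject_id))
        composition, ctab, hom_p = haplogroup_composition(hap_calls, sheet)
    except Exception as exc:
        raise StageError("haplogroup", str(exc)) from exc
    hap_path = outdir / "haplogroups.tsv"
    pd.DataFrame(
        [
            {
                "subject_id": c.subject_id,
                "haplogroup": c.best_label,
                "macro": c.macro,
                "score": round(c.best_score, 6),
            }
            for c in hap_calls
        ]
    ).to_csv(hap_path, sep="\t", index=False)
    comp_path = outdir / "haplogroup_composition.tsv"
    composition.to_csv(comp_path, sep="\t", index=False)
    manifest.add("haplogroup", hap_path, time.time() - t0)
    manifest.add("haplogroup", comp_path, 0.0)
    log.info("haplogroup homogeneity p = %.4g", hom_p)

    # -- cohort statistics ---------------------------------------------------
    t0 = time.time()
    try:
        main, small = summarize_subtypes(annotated, sheet, min_n=config.min_subtype_n)
        hotspots = find_hotspots(annotated)
        longi = []
        for subject_id, grp in sheet[sheet["role"] == "tumor"].groupby("subject_id"):
            if grp["timepoint"].nunique() > 1 or len(grp) > 1:
                longi.append(longitudinal_compare(annotated, sheet, subject_id))
    except Exception as exc:
        raise StageError("cohort", str(exc)) from exc
    paths = {
        "subtype_summary.tsv": main,
        "subtype_summary_small_n.tsv": small,
        "hotspots.tsv": hotspots,
        "longitudinal.tsv": pd.concat(longi, ignore_index=True)
        if longi
        else pd.DataFrame(),
    }
    for name, frame in paths.items():
        p = outdir / name
        frame.to_csv(p, sep="\t", index=False)
        manifest.add("cohort", p, 0.0)
    manifest.rows[-1]["seconds"] = round(time.time() - t0, 3)

    manifest.verify_immutable()
    mf = manifest.to_frame()
    mf.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return mf
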