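"""Germline subtraction, recurrence and blacklist filters, audit conservation."""

import numpy as np
import pandas as pd
import pytest

from mitosoma.caller import CALL_COLUMNS, call_sample
from mitosoma.pileup import MACT_COLUMNS, PileupTable
from mitosoma.somatic import (
    BlacklistParseError,
    PairingError,
    blacklist_filter,
    cohort_recurrence_filter,
    derive_somatic_cohort,
    load_blacklist,
    normal_raw_fraction,
    subtract_germline,
)
from mitosoma.simulate import SimulationConfig, simulate_pair


def call_frame(rows):
    """rows: (position, ref, alt, vaf, filters)"""
    out = []
    for pos, ref, alt, vaf, filt in rows:
        rec = dict.fromkeys(CALL_COLUMNS, 0)
        rec.update(
            position=pos, ref=ref, alt=alt, vaf=vaf, depth=1000,
            p_value=1e-30, q_value=1e-28, filters=filt,
        )
        out.append(rec)
    return pd.DataFrame(out, columns=CALL_COLUMNS)


def normal_pileup(rows):
    """rows: (pos, ref, counts dict base->(f,r))"""
    recs = []
    for pos, ref, counts in rows:
        rec = {c: 0 for c in MACT_COLUMNS}
        rec.update(pos=pos, ref=ref, indels=".")
        for b, (f, r) in counts.items():
            rec[f"{b}_f"], rec[f"{b}_r"], rec[f"mq_{b}"] = f, r, 30.0
        recs.append(rec)
    return PileupTable(df=pd.DataFrame(recs, columns=MACT_COLUMNS), sample_id="n")


def test_germline_by_high_normal_fraction_removed():
    tumor = call_frame([(100, "A", "G", 0.10, "PASS")])
    normal = call_frame([])
    npu = normal_pileup([(100, "A", {"A": (275, 275), "G": (225, 225)})])  # 45%
    somatic, germ = subtract_germline(tumor, normal, npu)
    assert somatic.empty and len(germ) == 1
    assert germ.iloc[0]["normal_vaf"] == pytest.approx(0.45)


def test_clean_normal_retains_candidate():
    tumor = call_frame([(100, "A", "G", 0.10, "PASS")])
    normal = call_frame([])
    npu = normal_pileup([(100, "A", {"A": (500, 500)})])
    somatic, germ = subtract_germline(tumor, normal, npu)
    assert len(somatic) == 1 and germ.empty
    assert somatic.iloc[0]["normal_vaf"] == 0.0


def test_normal_pass_call_removes_even_with_low_fraction():
    tumor = call_frame([(100, "A", "G", 0.10, "PASS")])
    normal = call_frame([(100, "A", "G", 0.005, "PASS")])
    npu = normal_pileup([(100, "A", {"A": (996, 996), "G": (4, 4)})])
    somatic, germ = subtract_germline(tumor, normal, npu)
    assert somatic.empty and len(germ) == 1


def test_threshold_is_on_raw_fraction():
    tumor = call_frame([(100, "A", "G", 0.10, "PASS")])
    normal = call_frame([])
    npu = normal_pileup([(100, "A", {"A": (495, 495), "G": (5, 5)})])  # exactly 1%
    somatic, germ = subtract_germline(tumor, normal, npu, threshold=0.01)
    assert somatic.empty  # >= threshold counts as germline presence
    somatic2, _ = subtract_germline(tumor, normal, npu, threshold=0.02)
    assert len(somatic2) == 1


def test_non_pass_tumor_calls_ignored():
    tumor = call_frame([(100, "A", "G", 0.10, "low_vaf")])
    somatic, germ = subtract_germline(
        tumor, call_frame([]), normal_pileup([(100, "A", {"A": (500, 500)})])
    )
    assert somatic.empty and germ.empty


def test_mismatched_subjects_raise():
    with pytest.raises(PairingError):
        subtract_germline(
            call_frame([]), call_frame([]), normal_pileup([]),
            tumor_subject="P1", normal_subject="P2",
        )


def test_indel_normal_fraction():
    npu = normal_pileup([(100, "A", {"A": (490, 490)})])
    npu.df.loc[npu.df["pos"] == 100, "indels"] = "-C:10:10"
    assert normal_raw_fraction(npu, 100, "-C") == pytest.approx(20 / 1000)
    assert normal_raw_fraction(npu, 100, "+C") == 0.0


# -- recurrence -------------------------------------------------------------

def candidates(allele_per_subject):
    rows = []
    for subj, alleles in allele_per_subject.items():
        for pos, ref, alt in alleles:
            rows.append(
                {
                    "sample_id": f"{subj}_T", "subject_id": subj,
                    "position": pos, "ref": ref, "alt": alt,
                }
            )
    return pd.DataFrame(rows)


def test_recurrence_boundary_strictly_greater():
    shared = (100, "A", "G")
    cand = candidates({f"P{i}": [shared] for i in range(10)} | {f"Q{i}": [] for i in range(90)})
    # force 100 distinct subjects into the denominator
    filler = candidates({f"Q{i}": [(200 + i, "C", "T")] for i in range(90)})
    allc = pd.concat([cand, filler], ignore_index=True)
    kept, removed = cohort_recurrence_filter(allc, max_fraction=0.10)
    assert removed.empty  # 10 of 100 is not strictly greater than 10%

    extra = candidates({"P10": [shared], "P11": [shared]})
    allc2 = pd.concat([allc, extra], ignore_index=True)
    kept2, removed2 = cohort_recurrence_filter(allc2, max_fraction=0.10)
    assert len(removed2) == 12  # 12 of 102 subjects > 10% -> removed everywhere
    assert not (
        (kept2["position"] == 100) & (kept2["alt"] == "G")
    ).any()


def test_recurrence_counts_subjects_not_samples():
    shared = (100, "A", "G")
    rows = candidates({f"P{i}": [(200 + i, "C", "T")] for i in range(20)})
    dup = pd.DataFrame(
        [
            {"sample_id": f"P0_T{k}", "subject_id": "P0", "position": 100,
             "ref": "A", "alt": "G"}
            for k in range(5)  # five specimens of ONE subject
        ]
    )
    allc = pd.concat([rows, dup], ignore_index=True)
    kept, removed = cohort_recurrence_filter(allc, max_fraction=0.10)
    assert removed.empty  # 1 of 20 subjects despite 5 carrying samples


# -- blacklist ---------------------------------------------------------------

def test_blacklist_allele_level_match():
    bl = pd.DataFrame(
        [{"pos": 263, "ref": "A", "alt": "G", "source": "common-germline"}]
    )
    cand = candidates({"P0": [(263, "A", "G")], "P1": [(263, "A", "T")]})
    kept, removed = blacklist_filter(cand, bl)
    assert len(removed) == 1 and removed.iloc[0]["subject_id"] == "P0"
    assert len(kept) == 1 and kept.iloc[0]["alt"] == "T"


def test_empty_blacklist_is_identity():
    cand = candidates({"P0": [(100, "A", "G")]})
    kept, removed = blacklist_filter(cand, pd.DataFrame(columns=["pos", "ref", "alt"]))
    assert kept.equals(cand) and removed.empty


def test_bundled_blacklist_loads_and_matches_rcrs(model):
    bl = load_blacklist()
    assert not bl[["pos", "ref", "alt"]].duplicated().any()
    for r in bl.itertuples():
        assert model.base(int(r.pos)) == r.ref


def test_malformed_blacklist_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("position\tref\talt\n263\tA\tG\n")
    with pytest.raises(BlacklistParseError):
        load_blacklist(p)


# -- cohort-level conservation and truth recovery ----------------------------

@pytest.fixture(scope="module")
def mini_cohort():
    """12 pairs with plenty of injections, fully called."""
    cfg = SimulationConfig(seed=29, somatic_rate=2.0, subtype_rates={})
    pairs, per_pair = [], []
    for i in range(12):
        pair = simulate_pair(cfg, i)
        pairs.append(pair)
        per_pair.append(
            {
                "sample_id": pair.tumor.sample_id,
                "subject_id": pair.subject_id,
                "subtype": pair.subtype,
                "tumor_calls": call_sample(pair.tumor),
                "normal_calls": call_sample(pair.normal),
                "normal_pileup": pair.normal,
            }
        )
    somatic, audit = derive_somatic_cohort(per_pair)
    truth = pd.concat([p.truth for p in pairs], ignore_index=True)
    return somatic, audit, truth


def test_audit_conserves_counts_exactly(mini_cohort):
    _, audit, _ = mini_cohort
    assert audit.conserved()
    frame = audit.to_frame()
    assert (
        frame["tumor_pass"]
        == frame[["germline_subtracted", "recurrence_removed",
                  "blacklist_removed", "somatic"]].sum(axis=1)
    ).all()


def test_all_germline_truth_removed(mini_cohort):
    somatic, _, truth = mini_cohort
    germ_keys = set(
        zip(truth.loc[truth["origin"] == "germline", "position"],
            truth.loc[truth["origin"] == "germline", "alt"])
    )
    if not somatic.empty:
        out_keys = set(zip(somatic["position"], somatic["alt"]))
        assert not (out_keys & germ_keys)


def test_somatic_recovery_precision_recall(mini_cohort):
    somatic, _, truth = mini_cohort
    som_truth = truth[
        (truth["origin"] == "somatic") & (truth["true_vaf"] >= 0.05)
    ]
    truth_keys = set(
        zip(som_truth["sample_id"], som_truth["position"], som_truth["alt"])
    )
    out_keys = (
        set(zip(somatic["sample_id"], somatic["position"], somatic["alt"]))
        if not somatic.empty
        else set()
    )
    recall = len(out_keys & truth_keys) / len(truth_keys)
    assert recall >= 0.95
    # precision over confidently-true origins: nothing germline/numt slips through
    all_inject = truth[truth["origin"] == "somatic"]
    legit = set(zip(all_inject["sample_id"], all_inject["position"], all_inject["alt"]))
    false_pos = out_keys - legit
    precision = 1 - len(false_pos) / max(len(out_keys), 1)
    assert precision >= 0.95
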