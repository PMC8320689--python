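"""Burden summaries, group contrasts, hotspots, and longitudinal set algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from mitosoma.cohort import (
    IntegrityError,
    contrast_groups,
    find_hotspots,
    longitudinal_compare,
    summarize_subtypes,
    t_confidence_interval,
)


def make_sheet(subtype_sizes, timepoints=None):
    rows = []
    i = 0
    for subtype, n in subtype_sizes.items():
        for _ in range(n):
            subj = f"P{i:04d}"
            rows.append(
                {"sample_id": f"{subj}_T", "subject_id": subj, "subtype": subtype,
                 "role": "tumor", "timepoint": 0}
            )
            rows.append(
                {"sample_id": f"{subj}_N", "subject_id": subj, "subtype": subtype,
                 "role": "normal", "timepoint": 0}
            )
            i += 1
    return pd.DataFrame(rows)


def spread_mutations(sheet, subtype, n_mutations, rng, vaf=0.1, klass="missense"):
    """Distribute n mutations over the subtype's tumor samples (<=1 each extra)."""
    tumors = sheet[(sheet["subtype"] == subtype) & (sheet["role"] == "tumor")]
    ids = list(tumors["sample_id"])
    rows = []
    for j in range(n_mutations):
        sid = ids[j % len(ids)]
        subj = sid[:-2]
        rows.append(
            {"sample_id": sid, "subject_id": subj, "subtype": subtype,
             "position": 1000 + len(rows) * 7 + hash(subtype) % 100, "ref": "A",
             "alt": "G", "vaf": vaf, "class": klass, "is_lof": False}
        )
    return rows


# -- burden arithmetic -------------------------------------------------------

PRINTED_BURDENS = [  # (subtype, n_samples, n_mutations, printed per-sample, decimals)
    ("HGG", 50, 30, 0.6, 1),
    ("LGG", 166, 45, 0.27, 2),
    ("EPN", 59, 27, 0.46, 2),
    ("MB", 58, 33, 0.57, 2),
    ("Meningioma", 19, 14, 0.74, 2),
    ("Ganglioglioma", 36, 10, 0.28, 2),
    ("ATRT", 15, 5, 0.33, 2),
    ("DNET", 19, 4, 0.2, 1),
]


@pytest.mark.parametrize("subtype, n, muts, printed, decimals", PRINTED_BURDENS)
def test_mutations_per_sample_matches_printed_values(subtype, n, muts, printed, decimals):
    rng = np.random.default_rng(1)
    sheet = make_sheet({subtype: n})
    mut_rows = pd.DataFrame(spread_mutations(sheet, subtype, muts, rng))
    main, small = summarize_subtypes(mut_rows, sheet, min_n=15)
    table = pd.concat([main, small])
    got = float(table.loc[table["subtype"] == subtype, "mutations_per_sample"].iloc[0])
    assert round(got, decimals) == printed
    assert table.loc[table["subtype"] == subtype, "n_mutations"].iloc[0] == muts


def test_small_n_subtypes_split_out():
    sheet = make_sheet({"HGG": 20, "Chordoma": 3})
    main, small = summarize_subtypes(pd.DataFrame(), sheet, min_n=15)
    assert list(main["subtype"]) == ["HGG"]
    assert list(small["subtype"]) == ["Chordoma"]


def test_zero_mutation_subtype_has_flagged_ci():
    sheet = make_sheet({"DNET": 16})
    main, _ = summarize_subtypes(pd.DataFrame(), sheet, min_n=15)
    row = main.iloc[0]
    assert row["mutations_per_sample"] == 0.0
    assert row["mean_vaf"] == "" and row["vaf_ci_low"] == ""


def test_multi_diagnosis_subjects_excluded():
    sheet = make_sheet({"HGG": 16})
    # give one subject a second tumor with a different diagnosis
    extra = {"sample_id": "P0000_T2", "subject_id": "P0000", "subtype": "LGG",
             "role": "tumor", "timepoint": 1}
    sheet = pd.concat([sheet, pd.DataFrame([extra])], ignore_index=True)
    main, small = summarize_subtypes(pd.DataFrame(), sheet, min_n=15)
    total = pd.concat([main, small])
    assert total["n_samples"].sum() == 15  # P0000 dropped entirely


def test_recurrent_specimens_excluded_from_categorical():
    sheet = make_sheet({"HGG": 16})
    later = {"sample_id": "P0001_T2", "subject_id": "P0001", "subtype": "HGG",
             "role": "tumor", "timepoint": 2}
    sheet = pd.concat([sheet, pd.DataFrame([later])], ignore_index=True)
    muts = pd.DataFrame(
        [{"sample_id": "P0001_T2", "subject_id": "P0001", "subtype": "HGG",
          "position": 100, "ref": "A", "alt": "G", "vaf": 0.2,
          "class": "missense", "is_lof": False}]
    )
    main, _ = summarize_subtypes(muts, sheet, min_n=15)
    assert main.iloc[0]["n_mutations"] == 0  # the progression specimen is excluded
    assert main.iloc[0]["n_samples"] == 16


def test_unjoined_mutation_raises():
    sheet = make_sheet({"HGG": 16})
    muts = pd.DataFrame(
        [{"sample_id": "GHOST", "subject_id": "?", "subtype": "HGG",
          "position": 1, "ref": "A", "alt": "G", "vaf": 0.1}]
    )
    with pytest.raises(IntegrityError):
        summarize_subtypes(muts, sheet)


def test_t_confidence_interval_matches_closed_form():
    rng = np.random.default_rng(2)
    x = rng.normal(0.4, 0.2, size=25)
    mean, ci = t_confidence_interval(x)
    half = stats.t.ppf(0.975, 24) * x.std(ddof=1) / math.sqrt(25)
    assert mean == pytest.approx(x.mean())
    assert ci[0] == pytest.approx(x.mean() - half)
    assert ci[1] == pytest.approx(x.mean() + half)
    assert ci[0] < mean < ci[1]


# -- contrasts ---------------------------------------------------------------

def fisher_oracle(table):
    (a, b), (c, d) = table
    n, row1, col1 = a + b + c + d, a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(k)
        for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )


def test_contrast_table_and_fisher_p():
    rng = np.random.default_rng(3)
    sheet = make_sheet({"HGG": 50, "LGG": 150})
    rows = spread_mutations(sheet, "HGG", 10, rng) + spread_mutations(
        sheet, "LGG", 10, rng
    )
    res = contrast_groups(pd.DataFrame(rows), sheet, "HGG", "LGG")
    assert res.table == ((10, 10), (40, 140))
    assert res.fisher_p == pytest.approx(fisher_oracle(res.table), rel=1e-6)
    assert res.burden_a == pytest.approx(10 / 50)
    assert res.burden_b == pytest.approx(10 / 150)


def test_identical_groups_p_one():
    rng = np.random.default_rng(4)
    sheet = make_sheet({"A": 30, "B": 30})
    rows = spread_mutations(sheet, "A", 6, rng) + spread_mutations(sheet, "B", 6, rng)
    res = contrast_groups(pd.DataFrame(rows), sheet, "A", "B")
    assert res.fisher_p == pytest.approx(1.0)


def test_empty_group_raises():
    sheet = make_sheet({"A": 5})
    with pytest.raises(ValueError, match="empty group"):
        contrast_groups(pd.DataFrame(), sheet, "A", "Z")


def test_fisher_matches_enumeration_on_all_small_tables():
    """Exhaustive check for every 2x2 table with margins <= 12, plus a random
    sweep of larger tables with margins <= 40."""
    for a in range(0, 7):
        for b in range(0, 7):
            for c in range(0, 7):
                for d in range(0, 7):
                    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                        continue
                    table = ((a, b), (c, d))
                    _, p = stats.fisher_exact(table)
                    assert p == pytest.approx(fisher_oracle(table), rel=1e-8), table
    rng = np.random.default_rng(8)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 21, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        table = ((int(a), int(b)), (int(c), int(d)))
        _, p = stats.fisher_exact(table)
        assert p == pytest.approx(fisher_oracle(table), rel=1e-8), table


def test_poisson_rate_alternative_available():
    rng = np.random.default_rng(5)
    sheet = make_sheet({"HGG": 50, "LGG": 150})
    rows = spread_mutations(sheet, "HGG", 30, rng) + spread_mutations(
        sheet, "LGG", 40, rng
    )
    res = contrast_groups(pd.DataFrame(rows), sheet, "HGG", "LGG", method="poisson")
    assert res.rate_test_p is not None
    assert 0 < res.rate_test_p <= 1


def test_contrast_power_and_null_calibration():
    """At the published group rates the test usually rejects; under equal
    rates the p-value distribution is roughly uniform."""
    rng = np.random.default_rng(6)
    sheet = make_sheet({"HGG": 50, "LGG": 166})

    def simulate_p(rate_a, rate_b):
        rows = []
        for r in sheet[sheet["role"] == "tumor"].itertuples():
            lam = rate_a if r.subtype == "HGG" else rate_b
            for k in range(rng.poisson(lam)):
                rows.append(
                    {"sample_id": r.sample_id, "subject_id": r.subject_id,
                     "subtype": r.subtype, "position": 100 + k, "ref": "A",
                     "alt": "G", "vaf": 0.1}
                )
        if not rows:
            return 1.0
        return contrast_groups(pd.DataFrame(rows), sheet, "HGG", "LGG").fisher_p

    alt_ps = [simulate_p(0.6, 0.27) for _ in range(120)]
    assert np.median(alt_ps) < 0.05
    null_ps = [simulate_p(0.4, 0.4) for _ in range(120)]
    assert np.mean(np.asarray(null_ps) <= 0.05) < 0.12  # conservative/discrete


# -- hotspots ----------------------------------------------------------------

def test_engineered_hotspot_found():
    rows = []
    for i in range(4):
        rows.append(
            {"sample_id": f"P{i}_T", "subject_id": f"P{i}",
             "subtype": ["HGG", "MB", "CP", "LGG"][i],
             "position": 12417, "ref": "C", "alt": "-A", "vaf": 0.1,
             "is_lof": True}
        )
    rows.append(
        {"sample_id": "P9_T", "subject_id": "P9", "subtype": "LGG",
         "position": 100, "ref": "A", "alt": "G", "vaf": 0.1, "is_lof": False}
    )
    hs = find_hotspots(pd.DataFrame(rows))
    assert len(hs) == 1
    rec = hs.iloc[0]
    assert rec["n_subjects"] == 4
    assert rec["is_lof"]
    assert "HGG" in rec["subtypes"] and "MB" in rec["subtypes"]


def test_no_shared_alleles_empty():
    rows = [
        {"sample_id": "P0_T", "subject_id": "P0", "subtype": "HGG",
         "position": 1, "ref": "A", "alt": "G", "vaf": 0.1},
        {"sample_id": "P1_T", "subject_id": "P1", "subtype": "HGG",
         "position": 2, "ref": "C", "alt": "T", "vaf": 0.1},
    ]
    assert find_hotspots(pd.DataFrame(rows)).empty


def test_same_subject_twice_is_not_a_hotspot():
    rows = [
        {"sample_id": "P0_T", "subject_id": "P0", "subtype": "HGG",
         "position": 5, "ref": "A", "alt": "G", "vaf": 0.1},
        {"sample_id": "P0_T2", "subject_id": "P0", "subtype": "HGG",
         "position": 5, "ref": "A", "alt": "G", "vaf": 0.2},
    ]
    assert find_hotspots(pd.DataFrame(rows)).empty


# -- longitudinal ------------------------------------------------------------

def longi_sheet(specs):
    """specs: list of (sample_id, timepoint)."""
    return pd.DataFrame(
        [
            {"sample_id": s, "subject_id": "PX", "subtype": "LGG",
             "role": "tumor", "timepoint": t}
            for s, t in specs
        ]
    )


def longi_muts(allocation):
    rows = []
    for sid, keys in allocation.items():
        for pos, ref, alt in keys:
            rows.append(
                {"sample_id": sid, "subject_id": "PX", "subtype": "LGG",
                 "position": pos, "ref": ref, "alt": alt, "vaf": 0.1}
            )
    return pd.DataFrame(rows)


def test_basic_set_algebra():
    sheet = longi_sheet([("S0", 0), ("S1", 1)])
    muts = longi_muts({"S0": [(1, "A", "G"), (2, "C", "T")],
                       "S1": [(2, "C", "T"), (3, "G", "A")]})
    out = longitudinal_compare(muts, sheet, "PX")
    row = out[out["kind"] == "longitudinal"].iloc[0]
    assert row["shared"] == "2:C>T"
    assert row["lost"] == "1:A>G"
    assert row["gained"] == "3:G>A"


def test_identical_specimens_all_shared():
    sheet = longi_sheet([("S0", 0), ("S1", 1)])
    muts = longi_muts({"S0": [(1, "A", "G")], "S1": [(1, "A", "G")]})
    row = longitudinal_compare(muts, sheet, "PX").iloc[0]
    assert row["shared"] == "1:A>G" and row["lost"] == "." and row["gained"] == "."


def test_same_day_specimens_compared_symmetrically():
    sheet = longi_sheet([("S0a", 0), ("S0b", 0)])
    muts = longi_muts({"S0a": [(14553, "C", "T"), (4219, "G", "A")],
                       "S0b": [(14553, "C", "T")]})
    out = longitudinal_compare(muts, sheet, "PX")
    same_day = out[out["kind"] == "same_day"].iloc[0]
    assert same_day["shared"] == "14553:C>T"
    assert same_day["lost"] == "4219:G>A"


def test_single_specimen_yields_empty_comparison():
    sheet = longi_sheet([("S0", 0)])
    out = longitudinal_compare(longi_muts({}), sheet, "PX")
    assert out.empty


def test_unknown_subject_raises():
    sheet = longi_sheet([("S0", 0)])
    with pytest.raises(KeyError):
        longitudinal_compare(longi_muts({}), sheet, "NOPE")


def test_multi_relapse_narrative_fixture():
    """A subject whose initial tumor carries a stop-gain that disappears at
    progression while a missense appears, then everything is lost."""
    sheet = longi_sheet([("S0", 0), ("S1", 1), ("S2", 2)])
    muts = longi_muts({"S0": [(11922, "G", "A")], "S1": [(7847, "G", "A")]})
    out = longitudinal_compare(muts, sheet, "PX")
    steps = out[out["kind"] == "longitudinal"].reset_index(drop=True)
    assert steps.loc[0, "lost"] == "11922:G>A"
    assert steps.loc[0, "gained"] == "7847:G>A"
    assert steps.loc[1, "lost"] == "7847:G>A"
    assert steps.loc[1, "gained"] == "."
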