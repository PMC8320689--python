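"""Cohort burden and heteroplasmy statistics.

Per-subtype mutation burden with t-based 95% CIs, the HGG-vs-LGG
Fisher contrast, recurrent-allele (hotspot) detection, and a worked
multi-specimen shared/lost/gained comparison.

Writes results/cohort/{subtype_summary.tsv, subtype_summary_small_n.tsv,
contrast_hgg_lgg.tsv, hotspots.tsv, longitudinal_demo.tsv}.
"""

import pandas as pd

from common import RESULTS, load_cohort, sample_sheet

from mitosoma.cohort import (
    contrast_groups,
    find_hotspots,
    longitudinal_compare,
    summarize_subtypes,
)

model, pairs = load_cohort()
sheet = sample_sheet(pairs)
annotated = pd.read_csv(RESULTS / "somatic_annotated.tsv", sep="\t")

main, small = summarize_subtypes(annotated, sheet, min_n=5)
main.to_csv(RESULTS / "subtype_summary.tsv", sep="\t", index=False)
small.to_csv(RESULTS / "subtype_summary_small_n.tsv", sep="\t", index=False)

contrast = contrast_groups(annotated, sheet, "HGG", "LGG", method="poisson")
pd.DataFrame(
    [
        {
            "group_a": contrast.group_a, "group_b": contrast.group_b,
            "with_a": contrast.table[0][0], "with_b": contrast.table[0][1],
            "without_a": contrast.table[1][0], "without_b": contrast.table[1][1],
            "fisher_p": contrast.fisher_p,
            "poisson_rate_p": contrast.rate_test_p,
            "burden_a": round(contrast.burden_a, 4),
            "burden_b": round(contrast.burden_b, 4),
        }
    ]
).to_csv(RESULTS / "contrast_hgg_lgg.tsv", sep="\t", index=False)

hotspots = find_hotspots(annotated)
hotspots.to_csv(RESULTS / "hotspots.tsv", sep="\t", index=False)

# worked multi-specimen example: initial stop-gain lost at progression,
# a missense gained, then everything lost at relapse
longi_sheet = pd.DataFrame(
    [
        {"sample_id": s, "subject_id": "DEMO", "subtype": "LGG",
         "role": "tumor", "timepoint": t}
        for s, t in (("D0", 0), ("D1", 1), ("D2", 2))
    ]
)
longi_muts = pd.DataFrame(
    [
        {"sample_id": "D0", "subject_id": "DEMO", "subtype": "LGG",
         "position": 11922, "ref": "G", "alt": "A", "vaf": 0.2},
        {"sample_id": "D1", "subject_id": "DEMO", "subtype": "LGG",
         "position": 7847, "ref": "G", "alt": "A", "vaf": 0.15},
    ]
)
longi = longitudinal_compare(longi_muts, longi_sheet, "DEMO")
longi.to_csv(RESULTS / "longitudinal_demo.tsv", sep="\t", index=False)

print("per-subtype burden (initial specimens):")
cols = ["subtype", "n_samples", "n_mutations", "mutations_per_sample", "mean_vaf"]
print(pd.concat([main, small])[cols].to_string(index=False))
print(
    f"\nHGG vs LGG: burden {contrast.burden_a:.2f} vs {contrast.burden_b:.2f}, "
    f"Fisher p = {contrast.fisher_p:.4f}, exact Poisson rate p = "
    f"{contrast.rate_test_p:.4f}"
)
print(f"hotspots (alleles in >=2 subjects): {len(hotspots)}")
print("\nmulti-specimen demo (consecutive timepoints):")
print(longi[longi["kind"] == "longitudinal"][
    ["comparison", "shared", "lost", "gained"]
].to_string(index=False))
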