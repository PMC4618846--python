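#!/usr/bin/env python
"""Generate every pipeline input with planted ground truth.

Writes, under results/inputs/: the 11-study ranked significant-miRNA
lists (five robust planted up-signals plus one fragile single-study
signal), a PRAD-scale RPM validation matrix with its raw-count twin, a
clinical cohort with copula-planted marker/covariate correlations,
19 per-cancer matrices carrying the (up, up, down) pattern only in PRAD,
and multi-source target-gene sets with a planted shared target.
"""

import json
from pathlib import Path

import mirmeta as mm
from mirmeta import scenarios

SEED = 20260921
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    lists = scenarios.meta_analysis_lists(seed=SEED)
    mm.write_ranked_lists(lists, OUT / "ranked_lists.tsv")
    print(f"wrote {len(lists)} ranked study lists "
          f"({sum(len(l) for l in lists)} entries)")

    raw, rpm = scenarios.prad_validation_matrix(seed=SEED + 1)
    mm.write_expression_matrix(rpm, OUT / "mirna_rpm.tsv",
                               OUT / "mirna_groups.tsv")
    mm.write_expression_matrix(raw, OUT / "mrna_counts.tsv",
                               OUT / "mrna_groups.tsv")
    print(f"wrote validation matrices: {rpm.data.shape[0]} features x "
          f"{rpm.data.shape[1]} samples ({rpm.n_tumor()} tumor / "
          f"{rpm.n_normal()} normal)")

    clin, markers = mm.simulate_clinical(
        550,
        {("mirA", "mirB"): 0.633, ("mirA", "mirC"): -0.479,
         ("mirB", "mirC"): -0.335, ("mirA", "age"): 0.17,
         ("mirA", "psa"): 0.17, ("mirC", "psa"): -0.21},
        group_shifts={("mirC", "gleason", "high"): -0.6},
        seed=SEED + 2)
    mm.write_clinical_table(clin, OUT / "clinical.tsv")
    mm.write_expression_matrix(markers, OUT / "markers_log2.tsv",
                               OUT / "markers_groups.tsv")
    print(f"wrote clinical table for {len(clin.sample_ids)} patients")

    pan = mm.simulate_pan_cancer(
        scenarios.CANCER_TYPES, scenarios.pan_cancer_pattern(["PRAD"]),
        n_tumor=60, n_normal=25, effect_lfc=2.5, sigma=0.8,
        seed=SEED + 3)
    pan_dir = OUT / "pan_cancer"
    pan_dir.mkdir(exist_ok=True)
    for cancer, matrix in pan.items():
        mm.write_expression_matrix(matrix, pan_dir / f"{cancer}.tsv",
                                   pan_dir / f"{cancer}_groups.tsv")
    print(f"wrote {len(pan)} pan-cancer matrices "
          "(pattern planted in PRAD only)")

    sim = mm.simulate_targets(
        ["miR-1", "miR-2", "miR-3"],
        anti_correlated_genes={"miR-1": {"GA"}, "miR-2": {"GB"},
                               "miR-3": {"GC"}},
        shared_gene="GSHARED", seed=SEED + 4)
    mm.write_target_sets(sim.collection, OUT / "target_sets.gmt")
    mm.write_expression_matrix(sim.mrna, OUT / "target_mrna_log2.tsv",
                               OUT / "target_mrna_groups.tsv")
    mm.write_expression_matrix(sim.mirna, OUT / "target_mirna_log2.tsv",
                               OUT / "target_mirna_groups.tsv")
    (OUT / "target_truth.json").write_text(json.dumps({
        "de_genes": sorted(sim.truth["de_genes"]),
        "shared_gene": sim.truth["shared_gene"],
    }, indent=2))
    print("wrote target sets "
          f"({len(sim.collection.sources)} prediction sources) "
          "and matched expression")


if __name__ == "__main__":
    main()
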