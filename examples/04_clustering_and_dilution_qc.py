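"""Two-way clustering of the expression heatmap and dilution QC.

Proteins and lanes are clustered with average linkage on Spearman
correlation distance after row-centring (each protein minus its mean).
The lane-axis 2-group cut should separate core-cuts from excisions; the
protein-axis cut should separate phospho from non-phospho targets. The
dilution QC clusters replicate lanes of the same sample measured at
several tag dilutions and checks each sample's replicates stay together.
"""

from proteofix import (
    SimParams,
    dilution_replicate_check,
    generate_cohort,
    generate_dilution_series,
    run_normalization,
    two_way_cluster,
)

dataset, _, _ = generate_cohort(SimParams(seed=1))
expr, _ = run_normalization(dataset)
rows, cols, _ = two_way_cluster(expr)

meta = dataset.sample_map()
for label in (1, 2):
    lanes = [l for l in cols.two_cut.index if cols.two_cut[l] == label]
    n_core = sum(meta[l].specimen == "core" for l in lanes)
    print(f"lane cluster {label}: {len(lanes)} lanes ({n_core} core, "
          f"{len(lanes) - n_core} excision)")

phospho = {a.probe_id for a in dataset.probes if a.is_phospho}
for label in (1, 2):
    probes = [p for p in rows.two_cut.index if rows.two_cut[p] == label]
    n_ph = sum(p in phospho for p in probes)
    print(f"protein cluster {label}: {len(probes)} proteins ({n_ph} phospho)")

print("\nlane tree (Newick, truncated):", cols.newick()[:80], "...")

series = generate_dilution_series(SimParams(seed=1), n_samples=6,
                                  dilutions=(5.0, 10.0, 20.0))
passes, report = dilution_replicate_check(series)
print(f"\ndilution QC: {sum(passes.values())}/{len(passes)} samples' replicates "
      "cluster together")
# Spearman distance is invariant to the per-lane dilution scaling, so
# replicates of one sample should always join before another sample does.
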