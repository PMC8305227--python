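"""Re-screen the packaged reference ceRNA axes.

Loads the eleven published stringent lncRNA-miRNA-mRNA axes from the
80-tumor uveal-melanoma cohort (bundled with the package as correlation
pair tables plus interaction-evidence flags) and re-runs the motif
predicate: inclusive |r| >= 0.6 on all three edges, sponge sign pattern,
and at least one database hit on each miRNA axis.
"""

from cernet import datasets, find_motifs, motifs_to_frame, threshold_sweep

mi_lnc, mi_m, lnc_m, interactions = datasets.uveal_melanoma_pair_tables()

motifs = find_motifs(mi_lnc, mi_m, lnc_m, interactions=interactions,
                     threshold=0.6, require_evidence=True)
print(f"motifs surviving the stringent evidence-gated screen: {len(motifs)}")
print(motifs_to_frame(motifs)[["lncrna", "mirna", "mrna",
                               "r_mi_lnc", "r_mi_m", "r_lnc_m"]].to_string(index=False))

sweep = threshold_sweep(mi_lnc, mi_m, lnc_m, interactions,
                        thresholds=[0.2, 0.4, 0.6, 0.7])
print("\nthreshold sweep (counts are non-increasing; gated <= ungated):")
print(sweep.to_string(index=False))
print("\nEach motif is a candidate miRNA-sponge axis: the lncRNA and mRNA "
      "rise and fall together while both anti-correlate with the shared miRNA.")
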