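"""Plant ceRNA triangles in synthetic expression data and recover them.

Generates an 80-sample matrix with five planted triangles (latent-factor
construction, expected |r| = 0.8 per edge at loadings 1 and noise 0.5),
filters low-expression features, computes the three cross-class Pearson
tables and enumerates motifs at threshold 0.6 with evidence gating.
"""

from cernet import corr, find_motifs
from cernet.synthetic import make_expression, make_interactions

matrix, truth = make_expression(n_samples=80, n_triangles=5, sigma=0.5, seed=1)
interactions = make_interactions(truth, seed=1)

filtered, report = corr.filter_expressed(matrix, min_fraction=0.75)
print(f"expression filter: kept {report.kept} of "
      f"{report.kept + report.dropped} features "
      f"(>0 in at least {report.min_samples}/{report.n_samples} samples)")

mi = filtered.by_class("miRNA")
lnc = filtered.by_class("lncRNA")
m = filtered.by_class("mRNA")
motifs = find_motifs(
    corr.pearson_pairs(mi, lnc),
    corr.pearson_pairs(mi, m),
    corr.pearson_pairs(lnc, m),
    interactions=interactions,
    threshold=0.6,
    require_evidence=True,
)
planted = {(t.lncrna, t.mirna, t.mrna) for t in truth.triangles}
got = {(x.lncrna, x.mirna, x.mrna) for x in motifs}
print(f"planted triangles: {len(planted)}; motifs found: {len(got)}; "
      f"recovered: {len(planted & got)}; spurious: {len(got - planted)}")
print("A planted expected |r| of 0.8 sits ~3.5 Fisher-z standard errors above "
      "the 0.6 threshold at n=80, so recovery should be (near-)perfect.")
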