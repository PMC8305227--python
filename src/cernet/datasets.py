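"""Packaged reference data.

``uveal_melanoma_axes`` returns the published reference set of eleven
stringent ceRNA axes from the 80-tumor TCGA uveal-melanoma cohort: the
lncRNA–miRNA–mRNA triples that survive the |r| >= 0.6 sponge-pattern screen
together with at least one interaction-database hit on each miRNA axis.
Each row carries the three pairwise Pearson coefficients and the binary
evidence flags (TarBase/miRTarBase for the miRNA–mRNA axis; miRcode,
LncBase validated/predicted and Encori for the miRNA–lncRNA axis). The
table is the worked example for the motif predicate: re-running enumeration
on it must return exactly these eleven axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .corr import correlation_pvalue
from .io import make_interaction_table

#: number of tumor samples behind the published correlations
N_SAMPLES = 80

# columns: miRNA, r(mi,mRNA), mRNA, TarBase, miRTarBase,
#          lncRNA, r(mi,lncRNA), miRcode, LncBase-V, LncBase-P, Encori,
#          r(lncRNA,mRNA)
_AXES = [
    ("hsa-miR-199a-5p", -0.65, "CDCA7L",   1, 0, "LINC00518", -0.66, 1, 0, 0, 0, 0.65),
    ("hsa-miR-199a-5p", -0.65, "CDCA7L",   1, 0, "SNHG7",     -0.69, 1, 0, 0, 0, 0.73),
    ("hsa-miR-195-5p",  -0.60, "SDC3",     1, 0, "LINC01128", -0.67, 0, 0, 0, 1, 0.72),
    ("hsa-miR-199a-5p", -0.66, "RPL15",    1, 0, "LINC00518", -0.66, 1, 0, 0, 0, 0.64),
    ("hsa-miR-199a-5p", -0.66, "RPL15",    1, 0, "SNHG7",     -0.69, 1, 0, 0, 0, 0.80),
    ("hsa-miR-199a-5p", -0.66, "RPL15",    1, 0, "WDFY3-AS2", -0.63, 1, 0, 0, 0, 0.62),
    ("hsa-miR-199a-5p", -0.63, "ZNF415",   0, 1, "LINC00518", -0.66, 1, 0, 0, 0, 0.72),
    ("hsa-miR-195-5p",  -0.66, "TPRG1L",   1, 0, "LINC01128", -0.66, 0, 0, 0, 1, 0.82),
    ("hsa-miR-508-3p",  -0.61, "GPR176",   0, 1, "HCP5",      -0.70, 1, 0, 0, 0, 0.63),
    ("hsa-miR-195-5p",  -0.65, "BSDC1",    1, 0, "LINC01128", -0.67, 0, 0, 0, 1, 0.61),
    ("hsa-miR-195-5p",  -0.65, "CTNNBIP1", 1, 0, "LINC01128", -0.67, 0, 0, 0, 1, 0.72),
]

_COLUMNS = ["mirna", "r_mi_m", "mrna", "TarBase", "miRTarBase",
            "lncrna", "r_mi_lnc", "miRcode", "LncBase-validated",
            "LncBase-predicted", "Encori", "r_lnc_m"]


def uveal_melanoma_axes() -> pd.DataFrame:
    """The eleven published stringent ceRNA axes, one row per axis."""
    return pd.DataFrame(_AXES, columns=_COLUMNS)


def _pair_frame(rows: dict, a_class: str, b_class: str) -> pd.DataFrame:
    recs = [
        {"a_id": a, "a_class": a_class, "b_id": b, "b_class": b_class,
         "r": r, "p": correlation_pvalue(r, N_SAMPLES), "n": N_SAMPLES}
        for (a, b), r in rows.items()
    ]
    return pd.DataFrame(recs, columns=["a_id", "a_class", "b_id", "b_class",
                                       "r", "p", "n"])


def uveal_melanoma_pair_tables() -> tuple[pd.DataFrame, pd.DataFrame,
                                          pd.DataFrame, pd.DataFrame]:
    """The reference axes as correlation pair tables plus evidence records.

    Returns ``(pairs_mi_lnc, pairs_mi_m, pairs_lnc_m, interactions)`` ready
    for :func:`cernet.circuits.find_motifs`. Duplicate pair mentions across
    axes are collapsed keeping the first occurrence (one published pair is
    printed with two roundings of the same coefficient, −0.67 vs −0.66;
    both clear the 0.6 threshold). P-values are recomputed from r and the
    cohort size via the t-transform.
    """
    axes = uveal_melanoma_axes()
    mi_lnc: dict[tuple[str, str], float] = {}
    mi_m: dict[tuple[str, str], float] = {}
    lnc_m: dict[tuple[str, str], float] = {}
    inter_rows = []
    seen_axis: set[tuple[str, str, str]] = set()
    for row in axes.to_dict("records"):
        mi_lnc.setdefault((row["mirna"], row["lncrna"]), row["r_mi_lnc"])
        mi_m.setdefault((row["mirna"], row["mrna"]), row["r_mi_m"])
        lnc_m.setdefault((row["lncrna"], row["mrna"]), row["r_lnc_m"])
        if (row["mirna"], row["mrna"], "m") not in seen_axis:
            seen_axis.add((row["mirna"], row["mrna"], "m"))
            for src in ("TarBase", "miRTarBase"):
                inter_rows.append({
                    "mirna_id": row["mirna"], "partner_id": row["mrna"],
                    "partner_class": "mRNA", "source": src,
                    "flag": int(row[src]),
                })
        if (row["mirna"], row["lncrna"], "l") not in seen_axis:
            seen_axis.add((row["mirna"], row["lncrna"], "l"))
            for src in ("miRcode", "LncBase-validated", "LncBase-predicted",
                        "Encori"):
                inter_rows.append({
                    "mirna_id": row["mirna"], "partner_id": row["lncrna"],
                    "partner_class": "lncRNA", "source": src,
                    "flag": int(row[src]),
                })
    interactions = make_interaction_table(
        pd.DataFrame(inter_rows, columns=["mirna_id", "partner_id",
                                          "partner_class", "source", "flag"])
    )
    return (
        _pair_frame(mi_lnc, "miRNA", "lncRNA"),
        _pair_frame(mi_m, "miRNA", "mRNA"),
        _pair_frame(lnc_m, "lncRNA", "mRNA"),
        interactions,
    )


#: published sense-antisense class counts for the same cohort: 198 pairs in
#: total — 60 convergent, 83 divergent, 40 lncRNA-within-mRNA, 15
#: mRNA-within-lncRNA (143 partial, 55 total-containment)
OVERLAP_CLASS_COUNTS = {
    "convergent": 60,
    "divergent": 83,
    "lncRNA_within_mRNA": 40,
    "mRNA_within_lncRNA": 15,
}
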