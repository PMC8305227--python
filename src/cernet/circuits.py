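"""Sign-constrained ceRNA triangle motifs with interaction-evidence gating.

A motif (a "triangular RNA circuit") is a lncRNA–miRNA–mRNA triple whose
three pairwise Pearson correlations follow the miRNA-sponge pattern:
miRNA:lncRNA negative, miRNA:mRNA negative, lncRNA:mRNA positive. Evidence
gating additionally requires at least one interaction-database hit on the
miRNA–mRNA axis and one on the miRNA–lncRNA axis; the lncRNA–mRNA edge is
never evidence-gated (the coupling there is correlational by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CernetError, MIRNA_LNCRNA_SOURCES, MIRNA_MRNA_SOURCES


@dataclass(frozen=True)
class TriangleMotif:
    """One lncRNA–miRNA–mRNA axis with its three correlations and evidence."""

    lncrna: str
    mirna: str
    mrna: str
    r_mi_lnc: float
    r_mi_m: float
    r_lnc_m: float
    p_mi_lnc: float
    p_mi_m: float
    p_lnc_m: float
    evidence_mi_m: tuple[str, ...] = field(default_factory=tuple)
    evidence_mi_lnc: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.r_mi_lnc < 0 and self.r_mi_m < 0 and self.r_lnc_m > 0):
            raise CernetError(
                f"motif ({self.lncrna},{self.mirna},{self.mrna}) violates the "
                f"sponge sign pattern: r_mi_lnc={self.r_mi_lnc}, "
                f"r_mi_m={self.r_mi_m}, r_lnc_m={self.r_lnc_m}"
            )

    @property
    def weakest_edge(self) -> float:
        """Magnitude of the weakest of the three correlations (ranking key)."""
        return min(abs(self.r_mi_lnc), abs(self.r_mi_m), abs(self.r_lnc_m))


def _oriented(pairs: pd.DataFrame, class_left: str, class_right: str) -> pd.DataFrame:
    """Return pair records with columns (left, right, r, p) where the left
    feature has ``class_left``. Accepts either orientation of the input."""
    a_cls = pairs["a_class"].astype(str)
    b_cls = pairs["b_class"].astype(str)
    fwd = pairs[(a_cls == class_left) & (b_cls == class_right)]
    rev = pairs[(a_cls == class_right) & (b_cls == class_left)]
    out = pd.concat(
        [
            pd.DataFrame(
                {
                    "left": fwd["a_id"].astype(str),
                    "right": fwd["b_id"].astype(str),
                    "r": fwd["r"].to_numpy(),
                    "p": fwd["p"].to_numpy(),
                }
            ),
            pd.DataFrame(
                {
                    "left": rev["b_id"].astype(str),
                    "right": rev["a_id"].astype(str),
                    "r": rev["r"].to_numpy(),
                    "p": rev["p"].to_numpy(),
                }
            ),
        ],
        ignore_index=True,
    )
    return out


def _evidence_map(interactions: pd.DataFrame | None,
                  partner_class: str,
                  sources: Sequence[str]) -> dict[tuple[str, str], tuple[str, ...]]:
    """(miRNA, partner) -> tuple of supporting source names (flag == 1)."""
    if interactions is None or len(interactions) == 0:
        return {}
    sub = interactions[
        (interactions["partner_class"] == partner_class)
        & (interactions["flag"] == 1)
    ]
    out: dict[tuple[str, str], list[str]] = {}
    for mi, partner, src in zip(sub["mirna_id"], sub["partner_id"], sub["source"]):
        out.setdefault((mi, partner), []).append(src)
    return {k: tuple(sorted(v)) for k, v in out.items()}


def find_motifs(
    pairs_mi_lnc: pd.DataFrame,
    pairs_mi_m: pd.DataFrame,
    pairs_lnc_m: pd.DataFrame,
    interactions: pd.DataFrame | None = None,
    threshold: float | None = None,
    p_max: float | None = None,
    require_evidence: bool = False,
    anchor: str | Iterable[str] | None = None,
    top_n: int | None = None,
) -> list[TriangleMotif]:
    """Enumerate sign-consistent triangle motifs from three pair tables.

    A triple (lncRNA y, miRNA x, mRNA z) is emitted iff
    ``r(x,y) <= -threshold``, ``r(x,z) <= -threshold`` and
    ``r(y,z) >= +threshold`` (inclusive comparisons), every edge passing
    ``p <= p_max`` when given, and — with ``require_evidence`` — at least
    one positive interaction flag on the miRNA–mRNA axis AND one on the
    miRNA–lncRNA axis. Records with undefined r (zero-variance features)
    never match. Either ``threshold`` or ``p_max`` must be supplied;
    supplying only ``p_max`` applies the sign pattern with threshold 0.

    ``anchor`` restricts output to motifs containing the given feature
    id(s); an anchor absent from every pair table is an error. Results are
    deterministically ordered by :func:`rank_motifs`; ``top_n`` truncates.
    """
    if threshold is None and p_max is None:
        raise CernetError("supply a correlation threshold and/or p_max")
    if threshold is not None and threshold < 0:
        raise CernetError(f"threshold must be >= 0, got {threshold}")
    thr = 0.0 if threshold is None else float(threshold)

    e_mi_lnc = _oriented(pairs_mi_lnc, "miRNA", "lncRNA")
    e_mi_m = _oriented(pairs_mi_m, "miRNA", "mRNA")
    e_lnc_m = _oriented(pairs_lnc_m, "lncRNA", "mRNA")

    if anchor is not None:
        anchors = {anchor} if isinstance(anchor, str) else set(anchor)
        known = (
            set(e_mi_lnc["left"]) | set(e_mi_lnc["right"])
            | set(e_mi_m["left"]) | set(e_mi_m["right"])
            | set(e_lnc_m["left"]) | set(e_lnc_m["right"])
        )
        unknown = anchors - known
        if unknown:
            raise CernetError(f"anchor id(s) not found in pair tables: {sorted(unknown)}")
    else:
        anchors = None

    def _pass(df: pd.DataFrame, keep_negative: bool) -> pd.DataFrame:
        r = df["r"].to_numpy()
        ok = (r <= -thr) if keep_negative else (r >= thr)
        ok &= ~np.isnan(r)
        if keep_negative:
            ok &= r < 0
        else:
            ok &= r > 0
        if p_max is not None:
            ok &= df["p"].to_numpy() <= p_max
        return df[ok]

    e1 = _pass(e_mi_lnc, keep_negative=True).rename(
        columns={"left": "mirna", "right": "lncrna", "r": "r_mi_lnc", "p": "p_mi_lnc"})
    e2 = _pass(e_mi_m, keep_negative=True).rename(
        columns={"left": "mirna", "right": "mrna", "r": "r_mi_m", "p": "p_mi_m"})
    e3 = _pass(e_lnc_m, keep_negative=False).rename(
        columns={"left": "lncrna", "right": "mrna", "r": "r_lnc_m", "p": "p_lnc_m"})

    tri = e1.merge(e2, on="mirna").merge(e3, on=["lncrna", "mrna"])

    ev_m = _evidence_map(interactions, "mRNA", MIRNA_MRNA_SOURCES)
    ev_lnc = _evidence_map(interactions, "lncRNA", MIRNA_LNCRNA_SOURCES)

    motifs: list[TriangleMotif] = []
    for row in tri.itertuples(index=False):
        evidence_mi_m = ev_m.get((row.mirna, row.mrna), ())
        evidence_mi_lnc = ev_lnc.get((row.mirna, row.lncrna), ())
        if require_evidence and not (evidence_mi_m and evidence_mi_lnc):
            continue
        if anchors is not None and not ({row.lncrna, row.mirna, row.mrna} & anchors):
            continue
        motifs.append(
            TriangleMotif(
                lncrna=row.lncrna, mirna=row.mirna, mrna=row.mrna,
                r_mi_lnc=float(row.r_mi_lnc), r_mi_m=float(row.r_mi_m),
                r_lnc_m=float(row.r_lnc_m),
                p_mi_lnc=float(row.p_mi_lnc), p_mi_m=float(row.p_mi_m),
                p_lnc_m=float(row.p_lnc_m),
                evidence_mi_m=evidence_mi_m,
                evidence_mi_lnc=evidence_mi_lnc,
            )
        )
    return rank_motifs(motifs, top_n)


def rank_motifs(motifs: Sequence[TriangleMotif],
                top_n: int | None = None) -> list[TriangleMotif]:
    """Deterministic "Top n" ordering: strongest weakest-edge first.

    Sorts by descending ``min(|r_mi_lnc|, |r_mi_m|, |r_lnc_m|)``, ties
    broken lexicographically by (lncRNA, miRNA, mRNA) id.
    """
    if top_n is not None and top_n < 1:
        raise CernetError(f"top_n must be >= 1, got {top_n}")
    ordered = sorted(
        motifs, key=lambda m: (-m.weakest_edge, m.lncrna, m.mirna, m.mrna)
    )
    return ordered if top_n is None else ordered[:top_n]


def threshold_sweep(
    pairs_mi_lnc: pd.DataFrame,
    pairs_mi_m: pd.DataFrame,
    pairs_lnc_m: pd.DataFrame,
    interactions: pd.DataFrame | None,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Motif counts (ungated and evidence-gated) over a threshold grid.

    ``thresholds`` must be sorted ascending; both count columns are
    non-increasing in the threshold and the gated count never exceeds the
    ungated one.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise CernetError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        all_m = find_motifs(pairs_mi_lnc, pairs_mi_m, pairs_lnc_m,
                            interactions=interactions, threshold=t)
        gated = [m for m in all_m if m.evidence_mi_m and m.evidence_mi_lnc]
        rows.append({"threshold": t, "n_motifs": len(all_m),
                     "n_evidence_gated": len(gated)})
    return pd.DataFrame(rows, columns=["threshold", "n_motifs", "n_evidence_gated"])


def motifs_to_frame(motifs: Sequence[TriangleMotif]) -> pd.DataFrame:
    """Tabular view of motifs (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "lncrna": m.lncrna, "mirna": m.mirna, "mrna": m.mrna,
                "r_mi_lnc": m.r_mi_lnc, "r_mi_m": m.r_mi_m, "r_lnc_m": m.r_lnc_m,
                "p_mi_lnc": m.p_mi_lnc, "p_mi_m": m.p_mi_m, "p_lnc_m": m.p_lnc_m,
                "evidence_mi_m": ",".join(m.evidence_mi_m),
                "evidence_mi_lnc": ",".join(m.evidence_mi_lnc),
            }
            for m in motifs
        ],
        columns=["lncrna", "mirna", "mrna", "r_mi_lnc", "r_mi_m", "r_lnc_m",
                 "p_mi_lnc", "p_mi_m", "p_lnc_m", "evidence_mi_m", "evidence_mi_lnc"],
    )


def motif_graph(motifs: Sequence[TriangleMotif]):
    """(nodes, edges) for :func:`cernet.io.export_graph`."""
    nodes: dict[str, str] = {}
    edges: dict[tuple[str, str], dict] = {}
    for m in motifs:
        nodes[m.lncrna] = "lncRNA"
        nodes[m.mirna] = "miRNA"
        nodes[m.mrna] = "mRNA"
        edges[(m.mirna, m.lncrna)] = {
            "source": m.mirna, "target": m.lncrna, "r": m.r_mi_lnc,
            "p": m.p_mi_lnc, "evidence": list(m.evidence_mi_lnc)}
        edges[(m.mirna, m.mrna)] = {
            "source": m.mirna, "target": m.mrna, "r": m.r_mi_m,
            "p": m.p_mi_m, "evidence": list(m.evidence_mi_m)}
        edges[(m.lncrna, m.mrna)] = {
            "source": m.lncrna, "target": m.mrna, "r": m.r_lnc_m,
            "p": m.p_lnc_m, "evidence": []}
    return list(nodes.items()), list(edges.values())
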