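"""Sense-antisense lncRNA/mRNA overlap detection and classification.

Two genes form a sense-antisense pair when they sit on the same chromosome,
on opposite strands, and at least one isoform of each overlaps by at least
one base. Pairs are classified on the union span of each gene's isoforms
into four mutually exclusive geometries:

- ``convergent``       — tail-to-tail: the shared region holds both 3' ends
- ``divergent``        — head-to-head: the shared region holds both 5' ends
- ``lncRNA_within_mRNA`` — the lncRNA span lies entirely inside the mRNA span
- ``mRNA_within_lncRNA`` — the mRNA span lies entirely inside the lncRNA span

Containment takes precedence over the terminus-based classes. Overlap
lengths (mean/min/max over overlapping isoform combinations) support the
overlap-length-versus-expression-correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CernetError, GeneLocus

OVERLAP_CLASSES = (
    "convergent",
    "divergent",
    "lncRNA_within_mRNA",
    "mRNA_within_lncRNA",
)


@dataclass
class OverlapPair:
    """A strand-opposed lncRNA/mRNA pair with overlap-length statistics."""

    lnc: GeneLocus
    mrna: GeneLocus
    overlap_mean: float
    overlap_min: int
    overlap_max: int
    n_overlapping_isoform_pairs: int
    overlap_class: str | None = None
    total_containment: bool = False
    degenerate: bool = False  # identical union spans (documented tie-break)
    expression_r: float | None = None
    expression_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.overlap_min <= self.overlap_mean <= self.overlap_max):
            raise CernetError(
                f"overlap stats out of order for ({self.lnc.gene_id},"
                f"{self.mrna.gene_id}): min {self.overlap_min} mean "
                f"{self.overlap_mean} max {self.overlap_max}"
            )


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def find_overlaps(
    lnc_loci: Sequence[GeneLocus],
    mrna_loci: Sequence[GeneLocus],
) -> list[OverlapPair]:
    """All opposite-strand lncRNA/mRNA pairs with >=1 overlapping base.

    The candidate sweep runs on per-chromosome, start-sorted union spans;
    a candidate is emitted only if at least one isoform combination
    overlaps. Same-strand overlaps are never emitted (the sense-antisense
    definition requires opposite strands). Output order is deterministic:
    sorted by (lncRNA id, mRNA id).
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for m in mrna_loci:
        by_chrom.setdefault(m.chrom, []).append(m)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.span[0])

    pairs: list[OverlapPair] = []
    for lnc in lnc_loci:
        candidates = by_chrom.get(lnc.chrom, ())
        ls, le = lnc.span
        for m in candidates:
            ms, me = m.span
            if ms >= le:
                break  # sorted by start: no later mRNA can overlap
            if me <= ls or m.strand == lnc.strand:
                continue
            lengths = [
                ov
                for iso_l in lnc.isoforms
                for iso_m in m.isoforms
                if (ov := _interval_overlap(iso_l, iso_m)) > 0
            ]
            if not lengths:
                continue
            pairs.append(
                OverlapPair(
                    lnc=lnc,
                    mrna=m,
                    overlap_mean=float(np.mean(lengths)),
                    overlap_min=int(min(lengths)),
                    overlap_max=int(max(lengths)),
                    n_overlapping_isoform_pairs=len(lengths),
                )
            )
    pairs.sort(key=lambda p: (p.lnc.gene_id, p.mrna.gene_id))
    return pairs


def classify_overlap(pair: OverlapPair) -> str:
    """Assign the pair's geometry class (also stored on the pair).

    Works on union spans. Containment first; identical spans count as
    ``lncRNA_within_mRNA`` with ``degenerate=True``. Partial overlaps are
    convergent when the shared region contains both genes' 3' termini and
    divergent when it contains both 5' termini; for opposite strands these
    two cases are exhaustive.
    """
    lnc, m = pair.lnc, pair.mrna
    if lnc.strand == m.strand:
        raise CernetError("classify_overlap requires opposite strands")
    (ls, le), (ms, me) = lnc.span, m.span
    if ls == ms and le == me:
        pair.overlap_class = "lncRNA_within_mRNA"
        pair.total_containment = True
        pair.degenerate = True
        return pair.overlap_class
    if ms <= ls and le <= me:
        pair.overlap_class = "lncRNA_within_mRNA"
        pair.total_containment = True
        return pair.overlap_class
    if ls <= ms and me <= le:
        pair.overlap_class = "mRNA_within_lncRNA"
        pair.total_containment = True
        return pair.overlap_class

    # partial overlap of the union spans
    lo, hi = max(ls, ms), min(le, me)
    if hi <= lo:
        raise CernetError("classify_overlap called on non-overlapping spans")
    region = range(lo, hi)  # inclusive positions lo .. hi-1
    both_three = lnc.three_prime in region and m.three_prime in region
    both_five = lnc.five_prime in region and m.five_prime in region
    if both_three and not both_five:
        pair.overlap_class = "convergent"
    elif both_five and not both_three:
        pair.overlap_class = "divergent"
    else:
        # one 5' and one 3' terminus in the shared region cannot occur for
        # opposite strands; reaching this means broken coordinates upstream
        raise CernetError(
            f"inconsistent terminus geometry for "
            f"({lnc.gene_id},{m.gene_id}) — check coordinate conventions"
        )
    pair.total_containment = False
    return pair.overlap_class


@dataclass
class ClassSummary:
    """Counts and percentages per overlap class plus the partial/total split."""

    classes: pd.DataFrame  # columns: class, count, percent
    total: int
    partial: int
    partial_percent: float
    containment: int
    containment_percent: float


def summarize_classes(pairs: Sequence[OverlapPair]) -> ClassSummary:
    """Per-class counts and one-decimal percentages over all classified pairs.

    Also reports the partial-overlap vs total-containment split (the two
    containment classes make up the "totally overlapping" fraction).
    """
    classified = [p for p in pairs if p.overlap_class is not None]
    total = len(classified)
    counts = {c: 0 for c in OVERLAP_CLASSES}
    for p in classified:
        counts[p.overlap_class] += 1
    rows = [
        {
            "class": c,
            "count": n,
            "percent": round(100.0 * n / total, 1) if total else float("nan"),
        }
        for c, n in counts.items()
    ]
    containment = counts["lncRNA_within_mRNA"] + counts["mRNA_within_lncRNA"]
    partial = total - containment
    return ClassSummary(
        classes=pd.DataFrame(rows, columns=["class", "count", "percent"]),
        total=total,
        partial=partial,
        partial_percent=round(100.0 * partial / total, 1) if total else float("nan"),
        containment=containment,
        containment_percent=(
            round(100.0 * containment / total, 1) if total else float("nan")
        ),
    )


def attach_expression(pairs: Sequence[OverlapPair],
                      pairs_lnc_m: pd.DataFrame) -> list[OverlapPair]:
    """Attach lncRNA-mRNA expression correlations to overlap pairs.

    ``pairs_lnc_m`` is a pair-correlation table (either orientation); pairs
    without a correlation record keep ``expression_r=None``.
    """
    lut: dict[tuple[str, str], tuple[float, float]] = {}
    for row in pairs_lnc_m.itertuples(index=False):
        lut[(str(row.a_id), str(row.b_id))] = (row.r, row.p)
        lut[(str(row.b_id), str(row.a_id))] = (row.r, row.p)
    for p in pairs:
        hit = lut.get((p.lnc.gene_id, p.mrna.gene_id))
        if hit is not None:
            p.expression_r, p.expression_p = float(hit[0]), float(hit[1])
    return list(pairs)


def overlap_length_vs_correlation(
    pairs: Sequence[OverlapPair],
) -> dict[str, float]:
    """Pearson r between expression correlation and overlap lengths.

    Returns ``{"r_mean": ..., "r_min": ..., "r_max": ...}`` — the
    correlation of the per-pair expression r against the mean, minimum and
    maximum overlap length across pairs. A zero-variance length vector
    yields NaN for its coefficient; fewer than 3 pairs is an error.
    """
    usable = [p for p in pairs if p.expression_r is not None]
    if len(usable) < 3:
        raise CernetError(
            f"need >= 3 pairs with expression correlations, got {len(usable)}"
        )
    expr = np.array([p.expression_r for p in usable], dtype=float)
    out: dict[str, float] = {}
    for key, lengths in (
        ("r_mean", [p.overlap_mean for p in usable]),
        ("r_min", [p.overlap_min for p in usable]),
        ("r_max", [p.overlap_max for p in usable]),
    ):
        x = np.asarray(lengths, dtype=float)
        if np.ptp(x) == 0 or np.ptp(expr) == 0:
            out[key] = float("nan")
        else:
            out[key] = float(np.corrcoef(x, expr)[0, 1])
    return out


def overlaps_to_frame(pairs: Sequence[OverlapPair]) -> pd.DataFrame:
    """Tabular view of (classified) overlap pairs."""
    return pd.DataFrame(
        [
            {
                "lncrna": p.lnc.gene_id,
                "mrna": p.mrna.gene_id,
                "chrom": p.lnc.chrom,
                "class": p.overlap_class,
                "total_containment": p.total_containment,
                "overlap_mean": p.overlap_mean,
                "overlap_min": p.overlap_min,
                "overlap_max": p.overlap_max,
                "n_isoform_pairs": p.n_overlapping_isoform_pairs,
                "expression_r": p.expression_r,
                "expression_p": p.expression_p,
            }
            for p in pairs
        ],
        columns=["lncrna", "mrna", "chrom", "class", "total_containment",
                 "overlap_mean", "overlap_min", "overlap_max",
                 "n_isoform_pairs", "expression_r", "expression_p"],
    )


def overlap_graph(pairs: Sequence[OverlapPair]):
    """(nodes, edges) for :func:`cernet.io.export_graph`; overlap details
    travel as edge attributes."""
    nodes: dict[str, str] = {}
    edges = []
    for p in pairs:
        nodes[p.lnc.gene_id] = "lncRNA"
        nodes[p.mrna.gene_id] = "mRNA"
        edges.append(
            {
                "source": p.lnc.gene_id,
                "target": p.mrna.gene_id,
                "r": p.expression_r if p.expression_r is not None else 0.0,
                "p": p.expression_p,
                "evidence": [],
                "overlap_class": p.overlap_class,
                "overlap_mean": p.overlap_mean,
                "overlap_min": p.overlap_min,
                "overlap_max": p.overlap_max,
            }
        )
    return list(nodes.items()), edges
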