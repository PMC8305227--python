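"""TF-target discovery: correlation screening gated by ChIP-seq binding.

Transcription factors (a subset of the mRNA matrix) are correlated against
every RNA class; candidate TF-target pairs must clear asymmetric per-class
correlation cutoffs and, optionally, carry at least one promoter-binding
flag from ENCODE, ChEA or TransmiR. Negative-correlation targets carry a
"(-)" label in tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import CernetError, ExpressionMatrix


@dataclass(frozen=True)
class TFTargetRecord:
    """A TF-xRNA correlation with per-source binding flags."""

    tf: str
    target: str
    target_class: str
    r: float
    p: float
    binding: tuple[str, ...] = field(default_factory=tuple)  # sources with flag 1

    @property
    def gated(self) -> bool:
        return len(self.binding) > 0

    @property
    def sign_label(self) -> str:
        return "(-)" if self.r < 0 else ""

    @property
    def labeled_target(self) -> str:
        return f"{self.target}{self.sign_label}"


def extract_tfs(
    matrix: ExpressionMatrix, tf_list: Sequence[str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict an expression matrix to a transcription-factor id list.

    Returns the TF sub-matrix plus the list members absent from the matrix;
    an empty intersection is an error.
    """
    if not tf_list:
        raise CernetError("tf_list is empty")
    present = [t for t in tf_list if t in set(matrix.feature_ids)]
    absent = [t for t in tf_list if t not in set(matrix.feature_ids)]
    if not present:
        raise CernetError("none of the listed TFs occur in the expression matrix")
    return matrix.subset(present), absent


#: default per-class (negative, positive) correlation cutoffs — the most
#: stringent evaluable screen: |r| >= 0.9 for mRNA targets, -0.6/+0.7 for
#: miRNA targets, -0.7/+0.8 for lncRNA targets
DEFAULT_CUTOFFS: dict[str, tuple[float, float]] = {
    "mRNA": (-0.9, 0.9),
    "miRNA": (-0.6, 0.7),
    "lncRNA": (-0.7, 0.8),
}


def _binding_map(binding: pd.DataFrame | None) -> dict[tuple[str, str], tuple[str, ...]]:
    if binding is None or len(binding) == 0:
        return {}
    sub = binding[binding["flag"] == 1]
    out: dict[tuple[str, str], list[str]] = {}
    for tf, tgt, src in zip(sub["tf_id"], sub["target_id"], sub["source"]):
        out.setdefault((tf, tgt), []).append(src)
    return {k: tuple(sorted(v)) for k, v in out.items()}


def tf_target_search(
    pair_tables: pd.DataFrame | Sequence[pd.DataFrame],
    binding: pd.DataFrame | None = None,
    cutoffs: Mapping[str, tuple[float, float]] | None = None,
    require_binding: bool = False,
    tf: str | None = None,
    target: str | None = None,
) -> list[TFTargetRecord]:
    """Screen TF-xRNA correlation tables against per-class cutoffs.

    ``pair_tables`` are pair-correlation frames whose *a* side is the TF
    (as produced by ``pearson_pairs(tf_matrix, target_matrix)``). A record
    is emitted iff ``r <= neg_cut`` or ``r >= pos_cut`` for its target
    class and — with ``require_binding`` — at least one ChIP-seq flag is
    set for the (TF, target) pair. ``tf``/``target`` restrict the scan to
    one factor or one target id. Output is sorted by (TF, target class,
    target).
    """
    cuts = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cuts.update(cutoffs)
    for cls, (neg, pos) in cuts.items():
        if not (neg <= 0 <= pos):
            raise CernetError(
                f"{cls}: cutoffs must satisfy neg <= 0 <= pos, got ({neg}, {pos})"
            )
    if isinstance(pair_tables, pd.DataFrame):
        pair_tables = [pair_tables]
    bind = _binding_map(binding)

    records: list[TFTargetRecord] = []
    for table in pair_tables:
        for row in table.itertuples(index=False):
            tf_id, tgt = str(row.a_id), str(row.b_id)
            cls = str(row.b_class)
            if cls not in cuts:
                raise CernetError(f"no cutoffs for target class {cls!r}")
            if tf is not None and tf_id != tf:
                continue
            if target is not None and tgt != target:
                continue
            r = row.r
            if pd.isna(r):
                continue
            neg, pos = cuts[cls]
            if not (r <= neg or r >= pos):
                continue
            flags = bind.get((tf_id, tgt), ())
            if require_binding and not flags:
                continue
            records.append(
                TFTargetRecord(tf=tf_id, target=tgt, target_class=cls,
                               r=float(r), p=float(row.p), binding=flags)
            )
    records.sort(key=lambda rec: (rec.tf, rec.target_class, rec.target))
    return records


def frequent_tfs(
    records: Sequence[TFTargetRecord], min_targets: int = 3
) -> pd.DataFrame:
    """TFs with at least ``min_targets`` distinct targets across all classes.

    One row per qualifying TF with per-class target lists (negative
    correlations labeled "(-)"), sorted by total target count descending,
    ties by TF id.
    """
    by_tf: dict[str, list[TFTargetRecord]] = {}
    for rec in records:
        by_tf.setdefault(rec.tf, []).append(rec)
    rows = []
    for tf_id, recs in by_tf.items():
        distinct = {(r.target, r.target_class) for r in recs}
        if len(distinct) < min_targets:
            continue
        per_class = {"mRNA": [], "miRNA": [], "lncRNA": []}
        for r in sorted(recs, key=lambda x: x.target):
            if (r.target, r.target_class) in distinct:
                per_class[r.target_class].append(r.labeled_target)
                distinct.discard((r.target, r.target_class))  # dedupe repeats
        rows.append(
            {
                "tf": tf_id,
                "n_targets": sum(len(v) for v in per_class.values()),
                "mrna_targets": ", ".join(per_class["mRNA"]),
                "mirna_targets": ", ".join(per_class["miRNA"]),
                "lncrna_targets": ", ".join(per_class["lncRNA"]),
            }
        )
    rows.sort(key=lambda r: (-r["n_targets"], r["tf"]))
    return pd.DataFrame(
        rows, columns=["tf", "n_targets", "mrna_targets", "mirna_targets",
                       "lncrna_targets"]
    )


def records_to_frame(records: Sequence[TFTargetRecord],
                     sources: Sequence[str] = ("ENCODE", "ChEA", "TransmiR")
                     ) -> pd.DataFrame:
    """Binary-flag table mirroring the interactive TF view: r, p, 0/1 per source."""
    return pd.DataFrame(
        [
            {
                "tf": r.tf,
                "target": r.labeled_target,
                "target_class": r.target_class,
                "r": r.r,
                "p": r.p,
                **{src: int(src in r.binding) for src in sources},
            }
            for r in records
        ],
        columns=["tf", "target", "target_class", "r", "p", *sources],
    )
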