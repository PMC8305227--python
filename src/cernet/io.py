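"""Readers/writers for expression, interaction, locus, binding and clinical
tables, plus graph export.

All tabular inputs are UTF-8 TSV with a header row. Genomic intervals are
held internally as 0-based half-open ``(start, end)``; GTF input (1-based,
closed) is converted on ingest, BED is taken as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
#: classes accepted in annotation files; TF rows are mRNAs kept separately
ANNOTATION_CLASSES = RNA_CLASSES + ("TF",)

#: evidence sources for miRNA-target interaction records
INTERACTION_SOURCES = (
    "TarBase",
    "miRTarBase",
    "miRcode",
    "LncBase-validated",
    "LncBase-predicted",
    "Encori",
)
#: miRNA-mRNA axis sources vs miRNA-lncRNA axis sources
MIRNA_MRNA_SOURCES = ("TarBase", "miRTarBase")
MIRNA_LNCRNA_SOURCES = ("miRcode", "LncBase-validated", "LncBase-predicted", "Encori")

#: ChIP-seq binding evidence sources
BINDING_SOURCES = ("ENCODE", "ChEA", "TransmiR")


class CernetError(ValueError):
    """Raised on any validated input contract violation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A dense features x samples expression matrix with RNA-class labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids. Values must
        be finite; missing cells are rejected rather than imputed.
    feature_class
        Mapping feature id -> class in :data:`ANNOTATION_CLASSES`.
    units
        Free-text unit tag per class, e.g. ``{"miRNA": "log2(RPM+1)"}``.
    """

    values: pd.DataFrame
    feature_class: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise CernetError(f"duplicate feature ids: {dups}")
        missing = [f for f in idx if f not in self.feature_class]
        if missing:
            raise CernetError(
                f"{len(missing)} features without class annotation: "
                f"{missing[:10]}"
            )
        bad = {
            f: c
            for f, c in self.feature_class.items()
            if f in idx and c not in ANNOTATION_CLASSES
        }
        if bad:
            raise CernetError(f"unknown feature classes: {bad}")
        arr = self.values.to_numpy()
        if arr.dtype.kind not in "fiu":
            raise CernetError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise CernetError("expression values must be finite (no NaN/inf)")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> pd.Series:
        """Per-feature class, aligned to the matrix row order."""
        return pd.Series(
            [self.feature_class[f] for f in self.values.index],
            index=self.values.index,
            name="class",
        )

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving class labels and units."""
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise CernetError(f"features not in matrix: {missing[:10]}")
        return ExpressionMatrix(
            values=self.values.loc[list(feature_ids)],
            feature_class={f: self.feature_class[f] for f in feature_ids},
            units=dict(self.units),
        )

    def by_class(self, rna_class: str) -> "ExpressionMatrix":
        keep = [f for f in self.values.index if self.feature_class[f] == rna_class]
        return self.subset(keep)


@dataclass(frozen=True)
class GeneLocus:
    """A gene with one or more isoform intervals on a single chromosome/strand.

    Coordinates are 0-based half-open. ``span`` is the union extent over all
    isoforms (used for overlap classification); per-isoform intervals feed
    overlap-length statistics.
    """

    gene_id: str
    gene_class: str | None
    chrom: str
    strand: str
    isoforms: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CernetError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.isoforms:
            raise CernetError(f"{self.gene_id}: at least one isoform required")
        for s, e in self.isoforms:
            if s >= e:
                raise CernetError(f"{self.gene_id}: empty/inverted interval ({s},{e})")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.isoforms), max(e for _, e in self.isoforms))

    @property
    def five_prime(self) -> int:
        """5' terminus position (inclusive coordinate of the first base)."""
        s, e = self.span
        return s if self.strand == "+" else e - 1

    @property
    def three_prime(self) -> int:
        """3' terminus position (inclusive coordinate of the last base)."""
        s, e = self.span
        return e - 1 if self.strand == "+" else s


@dataclass
class ClinicalTable:
    """Sample-level clinicopathological parameters with a kind registry.

    ``kinds`` maps each parameter name to ``"categorical"`` or ``"numeric"``.
    Unregistered parameters default to numeric when their column is numeric
    dtype, categorical otherwise.
    """

    data: pd.DataFrame  # index: sample id
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.data.columns:
            if p not in self.kinds:
                self.kinds[p] = (
                    "numeric"
                    if pd.api.types.is_numeric_dtype(self.data[p])
                    else "categorical"
                )
        bad = {p: k for p, k in self.kinds.items() if k not in ("categorical", "numeric")}
        if bad:
            raise CernetError(f"unknown parameter kinds: {bad}")

    @property
    def parameters(self) -> list[str]:
        return self.data.columns.tolist()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a feature -> class table (columns: feature_id, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CernetError(f"{path}: annotation needs feature_id and class columns")
    df = df.iloc[:, :2]
    df.columns = ["feature_id", "class"]
    bad = df[~df["class"].isin(ANNOTATION_CLASSES)]
    if len(bad):
        raise CernetError(
            f"{path}: unknown classes for features "
            f"{bad['feature_id'].tolist()[:10]} (classes {sorted(bad['class'].unique())})"
        )
    return dict(zip(df["feature_id"], df["class"]))


def read_expression(
    path: str | Path,
    annotation_path: str | Path,
    units: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a features x samples TSV plus its class annotation.

    The TSV has sample ids in the header and feature ids in the first
    column. Every feature must appear in the annotation; duplicate feature
    ids and non-numeric cells are hard errors.
    """
    # round_trip parsing so write/read cycles are bit-exact
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise CernetError(f"{path}: duplicate feature ids {dups}")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad_rows = raw.index[coerced.isna()].tolist()
            raise CernetError(
                f"{path}: non-numeric value in column {col!r}, row(s) {bad_rows[:5]}"
            )
    annotation = read_annotation(annotation_path)
    unannotated = [f for f in raw.index if f not in annotation]
    if unannotated:
        raise CernetError(
            f"{path}: {len(unannotated)} features missing from annotation: "
            f"{unannotated[:10]}"
        )
    return ExpressionMatrix(
        values=raw.astype(float),
        feature_class={f: annotation[f] for f in raw.index},
        units=dict(units or {}),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally its annotation) as TSV.

    Floats are serialized with shortest-round-trip repr, so a write/read
    cycle reproduces values bit-exactly.
    """
    matrix.values.map(repr).to_csv(path, sep="\t", index_label="feature_id")
    if annotation_path is not None:
        pd.DataFrame(
            {"feature_id": matrix.feature_ids,
             "class": [matrix.feature_class[f] for f in matrix.feature_ids]}
        ).to_csv(annotation_path, sep="\t", index=False)


def _namespace_source(source: str, known: tuple[str, ...]) -> str:
    # unknown databases are accepted but namespaced so they never collide
    # with the recognised evidence sources
    return source if source in known else f"other:{source}"


def read_interactions(path: str | Path,
                      feature_class: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read miRNA-target interaction evidence records.

    Columns: ``mirna_id, partner_id, partner_class, source, flag`` with
    binary flags and unique (miRNA, partner, source) triples.
    """
    df = pd.read_csv(path, sep="\t", dtype={"flag": int})
    required = {"mirna_id", "partner_id", "partner_class", "source", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise CernetError(f"{path}: missing columns {sorted(missing)}")
    return make_interaction_table(df, feature_class=feature_class)


def make_interaction_table(df: pd.DataFrame,
                           feature_class: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Validate an in-memory interaction table (see :func:`read_interactions`)."""
    df = df.copy()
    if not df["flag"].isin((0, 1)).all():
        raise CernetError("interaction flags must be binary 0/1")
    if not df["partner_class"].isin(("mRNA", "lncRNA")).all():
        bad = sorted(set(df["partner_class"]) - {"mRNA", "lncRNA"})
        raise CernetError(f"interaction partner_class must be mRNA or lncRNA, got {bad}")
    df["source"] = [_namespace_source(s, INTERACTION_SOURCES) for s in df["source"]]
    key = df[["mirna_id", "partner_id", "source"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise CernetError(f"duplicate interaction record {tuple(dup)}")
    if feature_class is not None:
        mismatch = [
            (p, c, feature_class[p])
            for p, c in zip(df["partner_id"], df["partner_class"])
            if p in feature_class and feature_class[p] != c
        ]
        if mismatch:
            raise CernetError(f"partner class disagrees with annotation: {mismatch[:5]}")
    return df


def read_binding(path: str | Path) -> pd.DataFrame:
    """Read TF-promoter ChIP-seq binding flags.

    Columns: ``tf_id, target_id, source, flag``; binary flags, unique
    (TF, target, source).
    """
    df = pd.read_csv(path, sep="\t", dtype={"flag": int})
    required = {"tf_id", "target_id", "source", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise CernetError(f"{path}: missing columns {sorted(missing)}")
    return make_binding_table(df)


def make_binding_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if not df["flag"].isin((0, 1)).all():
        raise CernetError("binding flags must be binary 0/1")
    df["source"] = [_namespace_source(s, BINDING_SOURCES) for s in df["source"]]
    key = df[["tf_id", "target_id", "source"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise CernetError(f"duplicate binding record {tuple(dup)}")
    return df


def read_clinical(path: str | Path,
                  kinds: Mapping[str, str] | None = None,
                  sample_ids: Sequence[str] | None = None) -> ClinicalTable:
    """Read a sample x parameter clinical table (first column: sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_ids is not None:
        extra = [s for s in df.index if s not in set(sample_ids)]
        if extra:
            raise CernetError(
                f"{path}: clinical samples absent from expression matrix: {extra[:10]}"
            )
    return ClinicalTable(data=df, kinds=dict(kinds or {}))


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------


def read_loci(
    path: str | Path,
    dialect: str = "bed",
    feature_class: Mapping[str, str] | None = None,
) -> list[GeneLocus]:
    """Read gene loci from BED6 (0-based half-open) or GTF (1-based closed).

    Coordinates are normalized to the internal 0-based half-open convention
    (pyranges performs the GTF shift). All intervals sharing a gene id are
    grouped into one :class:`GeneLocus`; for GTF, transcript records define
    the isoforms (falling back to per-transcript exon extents).
    """
    import pyranges as pr

    dialect = dialect.lower()
    if dialect == "bed":
        df = pr.read_bed(str(path)).df
        if "Strand" not in df.columns:
            raise CernetError(f"{path}: BED input must carry a strand column (BED6)")
        df = df.rename(columns={"Name": "gene_id"})
    elif dialect == "gtf":
        df = pr.read_gtf(str(path)).df
        if "Strand" not in df.columns:
            raise CernetError(f"{path}: GTF input must carry a strand column")
        if "transcript_id" in df.columns and (df["Feature"] == "transcript").any():
            df = df[df["Feature"] == "transcript"]
        elif "transcript_id" in df.columns and (df["Feature"] == "exon").any():
            # collapse exons to per-transcript extents
            df = (
                df[df["Feature"] == "exon"]
                .groupby(["gene_id", "transcript_id", "Chromosome", "Strand"],
                         as_index=False, observed=True)
                .agg(Start=("Start", "min"), End=("End", "max"))
            )
    else:
        raise CernetError(f"unknown locus dialect {dialect!r} (use 'bed' or 'gtf')")

    if df["Strand"].astype(str).isin([".", ""]).any():
        raise CernetError(f"{path}: missing strand for one or more records")

    loci: list[GeneLocus] = []
    for (gid, chrom, strand), grp in df.groupby(
        ["gene_id", "Chromosome", "Strand"], sort=True, observed=True
    ):
        isoforms = tuple(
            sorted((int(s), int(e)) for s, e in zip(grp["Start"], grp["End"]))
        )
        loci.append(
            GeneLocus(
                gene_id=str(gid),
                gene_class=feature_class.get(str(gid)) if feature_class else None,
                chrom=str(chrom),
                strand=str(strand),
                isoforms=isoforms,
            )
        )
    # a gene split over several chromosomes/strands is malformed input
    seen: dict[str, GeneLocus] = {}
    for loc in loci:
        if loc.gene_id in seen:
            raise CernetError(
                f"gene {loc.gene_id} appears on multiple chromosomes/strands"
            )
        seen[loc.gene_id] = loc
    return loci


# ---------------------------------------------------------------------------
# graph export
# ---------------------------------------------------------------------------


def build_graph(nodes: Iterable[tuple[str, str]],
                edges: Iterable[Mapping]) -> nx.Graph:
    """Assemble a networkx graph from (id, class) nodes and edge records.

    Each edge mapping needs ``source``, ``target``, ``r`` and optionally
    ``p`` and ``evidence`` (list of database names). Edge attributes encode
    the correlation polarity (``sign``) and evidence styling: solid when at
    least one database supports the pair, dotted otherwise.
    """
    g = nx.Graph()
    for node_id, node_class in nodes:
        g.add_node(node_id, rna_class=node_class)
    for e in edges:
        u, v = e["source"], e["target"]
        if u not in g or v not in g:
            missing = u if u not in g else v
            raise CernetError(f"edge references unknown node {missing!r}")
        r = float(e["r"])
        evidence = list(e.get("evidence", ()))
        extra = {k: v2 for k, v2 in e.items()
                 if k not in ("source", "target", "r", "p", "evidence")}
        g.add_edge(
            u,
            v,
            r=r,
            p=float(e["p"]) if e.get("p") is not None else float("nan"),
            sign="correlated" if r >= 0 else "anti-correlated",
            evidence=evidence,
            style="solid" if evidence else "dotted",
            **extra,
        )
    return g


def export_graph(nodes: Iterable[tuple[str, str]],
                 edges: Iterable[Mapping],
                 path: str | Path,
                 graphml_path: str | Path | None = None) -> nx.Graph:
    """Write a node-link JSON graph (optionally also GraphML)."""
    g = build_graph(nodes, edges)
    payload = nx.node_link_data(g, edges="edges")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    if graphml_path is not None:
        gml = g.copy()
        for _, _, attrs in gml.edges(data=True):
            attrs["evidence"] = ",".join(attrs["evidence"])
        nx.write_graphml(gml, graphml_path)
    return g
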