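"""Seeded ground-truth generators emulating a TCGA-tumor-cohort-shaped input
bundle: an 80-sample expression matrix over three RNA classes with planted
sign-consistent ceRNA triangles, strand-opposed locus pairs realizing each
overlap geometry, and TF regulons with ChIP-seq binding flags.

Planted triangles use a shared latent factor: for loadings (a, b, c) and
noise scale sigma,

    lncRNA = a*z + sigma*eps,  mRNA = b*z + sigma*eps',  miRNA = -c*z + sigma*eps''

with z, eps ~ N(0,1) i.i.d., so the expected Pearson correlation of, e.g.,
the lncRNA-mRNA edge is ab / sqrt((a^2+sigma^2)(b^2+sigma^2)) — 0.8 at the
default a=b=c=1, sigma=0.5 — and the miRNA edges are its negative
counterparts. Values are shifted by a constant to be predominantly
positive (a shift leaves Pearson correlations exactly unchanged), so the
expression filter keeps planted features.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CernetError,
    ExpressionMatrix,
    GeneLocus,
    make_binding_table,
    make_interaction_table,
)


@dataclass(frozen=True)
class PlantedTriangle:
    lncrna: str
    mirna: str
    mrna: str
    expected_r_lnc_m: float
    expected_r_mi_lnc: float
    expected_r_mi_m: float


@dataclass
class PlantedTruth:
    """Everything a recovery test needs: ids, expectations, seed, noise."""

    seed: int
    n_samples: int
    sigma: float
    triangles: list[PlantedTriangle] = field(default_factory=list)
    overlap_pairs: list[dict] = field(default_factory=list)
    regulons: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def expected_edge_r(load_a: float, load_b: float, sigma: float) -> float:
    """Closed-form expected Pearson r between two latent-driven vectors."""
    return load_a * load_b / np.sqrt(
        (load_a**2 + sigma**2) * (load_b**2 + sigma**2)
    )


def make_expression(
    n_samples: int = 80,
    n_mrna: int = 30,
    n_lncrna: int = 15,
    n_mirna: int = 15,
    n_triangles: int = 5,
    loadings: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sigma: float = 0.5,
    shift: float = 8.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Expression matrix with ``n_triangles`` planted ceRNA triangles.

    Triangle i occupies the i-th lncRNA/miRNA/mRNA feature; remaining
    features are independent unit-normal noise. The same seed reproduces
    the matrix bit-exactly.
    """
    if sigma <= 0:
        raise CernetError(f"sigma must be > 0, got {sigma}")
    if n_triangles > min(n_mrna, n_lncrna, n_mirna):
        raise CernetError(
            f"{n_triangles} planted triangles exceed the smallest class size "
            f"{min(n_mrna, n_lncrna, n_mirna)}"
        )
    a, b, c = loadings
    rng = np.random.default_rng(seed)

    lnc_ids = [f"LNC{i:04d}" for i in range(1, n_lncrna + 1)]
    mi_ids = [f"MIR{i:04d}" for i in range(1, n_mirna + 1)]
    m_ids = [f"MRNA{i:04d}" for i in range(1, n_mrna + 1)]

    lnc = rng.standard_normal((n_lncrna, n_samples))
    mrna = rng.standard_normal((n_mrna, n_samples))
    mirna = rng.standard_normal((n_mirna, n_samples))

    triangles: list[PlantedTriangle] = []
    for i in range(n_triangles):
        z = rng.standard_normal(n_samples)
        lnc[i] = a * z + sigma * rng.standard_normal(n_samples)
        mrna[i] = b * z + sigma * rng.standard_normal(n_samples)
        mirna[i] = -c * z + sigma * rng.standard_normal(n_samples)
        triangles.append(
            PlantedTriangle(
                lncrna=lnc_ids[i], mirna=mi_ids[i], mrna=m_ids[i],
                expected_r_lnc_m=float(expected_edge_r(a, b, sigma)),
                expected_r_mi_lnc=float(-expected_edge_r(c, a, sigma)),
                expected_r_mi_m=float(-expected_edge_r(c, b, sigma)),
            )
        )

    values = pd.DataFrame(
        np.vstack([mrna, lnc, mirna]) + shift,
        index=m_ids + lnc_ids + mi_ids,
        columns=[f"SAMPLE{j:03d}" for j in range(1, n_samples + 1)],
    )
    feature_class = (
        {f: "mRNA" for f in m_ids}
        | {f: "lncRNA" for f in lnc_ids}
        | {f: "miRNA" for f in mi_ids}
    )
    matrix = ExpressionMatrix(
        values=values,
        feature_class=feature_class,
        units={"miRNA": "log2(RPM+1)", "mRNA": "log2(norm_count+1)",
               "lncRNA": "log2(norm_count+1)"},
    )
    truth = PlantedTruth(seed=seed, n_samples=n_samples, sigma=sigma,
                         triangles=triangles)
    return matrix, truth


def make_interactions(
    truth: PlantedTruth,
    evidence_coverage: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Interaction-evidence table covering the planted triangles.

    Each planted miRNA-mRNA pair gets a TarBase flag and each miRNA-lncRNA
    pair a miRcode flag, independently with probability
    ``evidence_coverage`` (1.0: every planted axis is supported).
    """
    if not 0 <= evidence_coverage <= 1:
        raise CernetError("evidence_coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for t in truth.triangles:
        rows.append({
            "mirna_id": t.mirna, "partner_id": t.mrna, "partner_class": "mRNA",
            "source": "TarBase",
            "flag": int(rng.random() < evidence_coverage),
        })
        rows.append({
            "mirna_id": t.mirna, "partner_id": t.lncrna, "partner_class": "lncRNA",
            "source": "miRcode",
            "flag": int(rng.random() < evidence_coverage),
        })
    df = pd.DataFrame(rows, columns=["mirna_id", "partner_id", "partner_class",
                                     "source", "flag"])
    return make_interaction_table(df)


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------

_GEOMETRIES = ("convergent", "divergent", "lncRNA_within_mRNA", "mRNA_within_lncRNA")


def make_loci(
    planted: dict[str, int],
    n_decoys: int = 5,
    chrom: str = "chr1",
    chrom_length: int = 10_000_000,
    multi_isoform: bool = False,
    seed: int = 0,
) -> tuple[list[GeneLocus], list[GeneLocus], PlantedTruth]:
    """Opposite-strand lncRNA/mRNA locus pairs realizing requested geometries.

    ``planted`` maps class name -> pair count (classes: convergent,
    divergent, lncRNA_within_mRNA, mRNA_within_lncRNA). Decoy genes never
    overlap anything. Each pair is laid out in its own 20 kb window, so
    pairs never interfere. With ``multi_isoform`` each planted gene gains a
    second, trimmed isoform inside its span (the union span and hence the
    class are unchanged, but isoform overlap lengths differ).
    """
    unknown = set(planted) - set(_GEOMETRIES)
    if unknown:
        raise CernetError(f"unknown overlap geometries {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    window = 20_000
    total = sum(planted.values()) + n_decoys
    if total * window > chrom_length:
        raise CernetError("chromosome too short for the requested geometry")

    lnc_loci: list[GeneLocus] = []
    m_loci: list[GeneLocus] = []
    truth = PlantedTruth(seed=seed, n_samples=0, sigma=0.0)
    slot = 0

    def _isoforms(s: int, e: int) -> tuple[tuple[int, int], ...]:
        if not multi_isoform or e - s < 400:
            return ((s, e),)
        trim = int(rng.integers(100, (e - s) // 3))
        # second isoform trimmed on one side; union span preserved by iso 1
        side = rng.integers(0, 2)
        iso2 = (s + trim, e) if side else (s, e - trim)
        return tuple(sorted(((s, e), iso2)))

    idx = 0
    for geometry in _GEOMETRIES:
        for _ in range(planted.get(geometry, 0)):
            base = slot * window + 1000
            slot += 1
            idx += 1
            len_a = int(rng.integers(2000, 6000))
            len_b = int(rng.integers(2000, 6000))
            ov = int(rng.integers(200, min(len_a, len_b) - 100))
            if geometry == "convergent":
                # left gene ends inside right gene; both 3' ends in overlap
                a = (base, base + len_a)                      # + strand, 3' right
                b = (base + len_a - ov, base + len_a - ov + len_b)  # - strand
                lnc_span, m_span, lnc_strand, m_strand = a, b, "+", "-"
            elif geometry == "divergent":
                a = (base, base + len_a)                      # - strand, 5' right
                b = (base + len_a - ov, base + len_a - ov + len_b)  # + strand
                lnc_span, m_span, lnc_strand, m_strand = a, b, "-", "+"
            elif geometry == "lncRNA_within_mRNA":
                inner_len = min(len_a, len_b + 500) - 500
                start_in = base + int(rng.integers(100, len_a - inner_len - 100))
                lnc_span, m_span = (start_in, start_in + inner_len), (base, base + len_a)
                lnc_strand, m_strand = "-", "+"
            else:  # mRNA_within_lncRNA
                inner_len = min(len_a, len_b + 500) - 500
                start_in = base + int(rng.integers(100, len_a - inner_len - 100))
                m_span, lnc_span = (start_in, start_in + inner_len), (base, base + len_a)
                lnc_strand, m_strand = "+", "-"
            lnc_id, m_id = f"SLNC{idx:03d}", f"SMRNA{idx:03d}"
            lnc_loci.append(GeneLocus(lnc_id, "lncRNA", chrom, lnc_strand,
                                      _isoforms(*lnc_span)))
            m_loci.append(GeneLocus(m_id, "mRNA", chrom, m_strand,
                                    _isoforms(*m_span)))
            truth.overlap_pairs.append(
                {"lncrna": lnc_id, "mrna": m_id, "class": geometry}
            )

    for d in range(n_decoys):
        base = slot * window + 1000
        slot += 1
        length = int(rng.integers(1000, 4000))
        strand = "+" if rng.integers(0, 2) else "-"
        locus = GeneLocus(
            f"DECOY{d:03d}", "lncRNA" if d % 2 else "mRNA", chrom, strand,
            ((base, base + length),),
        )
        (lnc_loci if d % 2 else m_loci).append(locus)
    return lnc_loci, m_loci, truth


def loci_to_bed(loci: Sequence[GeneLocus], path: str | Path) -> None:
    """Write loci as BED6, one line per isoform."""
    with open(path, "w", encoding="utf-8") as fh:
        for loc in loci:
            for s, e in loc.isoforms:
                fh.write(f"{loc.chrom}\t{s}\t{e}\t{loc.gene_id}\t0\t{loc.strand}\n")


# ---------------------------------------------------------------------------
# TF regulons
# ---------------------------------------------------------------------------


def make_tf_regulons(
    n_tfs: int = 4,
    targets_per_tf: int = 3,
    negative_fraction: float = 0.5,
    binding_coverage: float = 1.0,
    n_samples: int = 80,
    sigma: float = 0.3,
    shift: float = 8.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], pd.DataFrame, PlantedTruth]:
    """Planted TF regulons: TF expression drives its targets' expression.

    Target j of a TF follows ``sign_j * tf + sigma * noise`` with sign
    drawn negative with probability ``negative_fraction``; target classes
    cycle through mRNA/miRNA/lncRNA. Binding flags (source cycling through
    ENCODE/ChEA/TransmiR) are set for each planted pair with probability
    ``binding_coverage``. Returns (expression with TFs and targets, TF id
    list, binding table, truth).
    """
    if not 0 <= binding_coverage <= 1:
        raise CernetError("binding_coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    classes = ("mRNA", "miRNA", "lncRNA")
    bind_sources = ("ENCODE", "ChEA", "TransmiR")

    rows, ids, feature_class = [], [], {}
    tf_list: list[str] = []
    binding_rows = []
    truth = PlantedTruth(seed=seed, n_samples=n_samples, sigma=sigma)

    for i in range(n_tfs):
        tf_id = f"TF{i:03d}"
        tf_expr = rng.standard_normal(n_samples)
        tf_list.append(tf_id)
        ids.append(tf_id)
        feature_class[tf_id] = "mRNA"  # TFs are protein-coding transcripts
        rows.append(tf_expr)
        for j in range(targets_per_tf):
            cls = classes[j % 3]
            sign = -1.0 if rng.random() < negative_fraction else 1.0
            tgt_id = f"TGT{i:03d}_{j}"
            ids.append(tgt_id)
            feature_class[tgt_id] = cls
            rows.append(sign * tf_expr + sigma * rng.standard_normal(n_samples))
            bound = bool(rng.random() < binding_coverage)
            if bound:
                binding_rows.append({
                    "tf_id": tf_id, "target_id": tgt_id,
                    "source": bind_sources[j % 3], "flag": 1,
                })
            truth.regulons.append(
                {"tf": tf_id, "target": tgt_id, "class": cls,
                 "sign": int(sign), "bound": bound,
                 # corr(tf, sign*tf + sigma*eps) = sign / sqrt(1 + sigma^2)
                 "expected_r": float(sign / np.sqrt(1.0 + sigma**2))}
            )

    values = pd.DataFrame(
        np.vstack(rows) + shift,
        index=ids,
        columns=[f"SAMPLE{j:03d}" for j in range(1, n_samples + 1)],
    )
    matrix = ExpressionMatrix(values=values, feature_class=feature_class)
    binding = make_binding_table(
        pd.DataFrame(binding_rows, columns=["tf_id", "target_id", "source", "flag"])
    )
    return matrix, tf_list, binding, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def make_clinical(sample_ids: Sequence[str], seed: int = 0,
                  missing_rate: float = 0.05) -> pd.DataFrame:
    """Synthetic clinicopathological table: stage, thickness, metastasis."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.2, 0.35, 0.3, 0.15])
    thickness = np.round(rng.uniform(2.0, 12.0, size=n), 1)
    metastasis = rng.choice(["yes", "no"], size=n, p=[0.3, 0.7]).astype(object)
    miss = rng.random(n) < missing_rate
    metastasis[miss] = np.nan
    return pd.DataFrame(
        {"stage": stage, "tumor_thickness": thickness, "metastasis": metastasis},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def write_bundle(
    outdir: str | Path,
    n_samples: int = 80,
    n_mrna: int = 30,
    n_lncrna: int = 15,
    n_mirna: int = 15,
    n_triangles: int = 5,
    sigma: float = 0.5,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete synthetic input bundle + ground-truth JSON.

    Files: expression.tsv, annotation.tsv, interactions.tsv, loci.bed,
    binding.tsv, tf_list.txt, clinical.tsv, truth.json. Deterministic under
    the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = make_expression(
        n_samples=n_samples, n_mrna=n_mrna, n_lncrna=n_lncrna,
        n_mirna=n_mirna, n_triangles=n_triangles, sigma=sigma, seed=seed)
    interactions = make_interactions(truth, seed=seed)
    lnc_loci, m_loci, loci_truth = make_loci(
        {"convergent": 2, "divergent": 2, "lncRNA_within_mRNA": 1,
         "mRNA_within_lncRNA": 1},
        n_decoys=4, seed=seed)
    tf_matrix, tf_list, binding, tf_truth = make_tf_regulons(
        n_samples=n_samples, seed=seed)
    clinical = make_clinical(matrix.sample_ids, seed=seed)

    # merge the TF block into the main matrix (shared samples)
    tf_vals = tf_matrix.values
    tf_vals.columns = matrix.values.columns
    merged = ExpressionMatrix(
        values=pd.concat([matrix.values, tf_vals]),
        feature_class={**matrix.feature_class, **tf_matrix.feature_class},
        units=matrix.units,
    )
    truth.overlap_pairs = loci_truth.overlap_pairs
    truth.regulons = tf_truth.regulons

    from .io import write_expression

    paths = {name: outdir / fname for name, fname in [
        ("expression", "expression.tsv"), ("annotation", "annotation.tsv"),
        ("interactions", "interactions.tsv"), ("loci", "loci.bed"),
        ("binding", "binding.tsv"), ("tf_list", "tf_list.txt"),
        ("clinical", "clinical.tsv"), ("truth", "truth.json")]}
    write_expression(merged, paths["expression"], paths["annotation"])
    interactions.to_csv(paths["interactions"], sep="\t", index=False)
    loci_to_bed(lnc_loci + m_loci, paths["loci"])
    binding.to_csv(paths["binding"], sep="\t", index=False)
    paths["tf_list"].write_text("\n".join(tf_list) + "\n", encoding="utf-8")
    clinical.to_csv(paths["clinical"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
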