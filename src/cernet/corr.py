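"""Expression filtering and Pearson correlation with p-values.

The correlation tables produced here (feature pairs across two RNA classes,
with r, two-sided p and the sample count) are the substrate for every
downstream query: ceRNA triangle motifs, sense-antisense expression
coupling and TF target search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CernetError, ExpressionMatrix

PAIR_COLUMNS = ["a_id", "a_class", "b_id", "b_class", "r", "p", "n"]


@dataclass
class FilterReport:
    """Per-class retention bookkeeping from :func:`filter_expressed`."""

    min_fraction: float
    min_samples: int
    n_samples: int
    per_class: pd.DataFrame  # columns: class, kept, dropped

    @property
    def kept(self) -> int:
        return int(self.per_class["kept"].sum())

    @property
    def dropped(self) -> int:
        return int(self.per_class["dropped"].sum())


def filter_expressed(
    matrix: ExpressionMatrix, min_fraction: float = 0.75
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features not strictly positive in enough samples.

    A feature is retained iff its value is > 0 in at least
    ``ceil(min_fraction * n_samples)`` samples — with the default 0.75 and
    80 samples this is the "positive in at least 60 of 80" rule. Returns
    the filtered matrix plus a per-class kept/dropped report.
    """
    if not 0 < min_fraction <= 1:
        raise CernetError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise CernetError("cannot filter an empty expression matrix")
    min_samples = math.ceil(min_fraction * matrix.n_samples)
    positive = (matrix.values.to_numpy() > 0).sum(axis=1)
    keep_mask = positive >= min_samples
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep_mask) if k]

    classes = matrix.classes()
    rows = []
    for cls, grp in classes.groupby(classes, sort=True):
        kept = int(keep_mask[classes.index.get_indexer(grp.index)].sum())
        rows.append({"class": cls, "kept": kept, "dropped": len(grp) - kept})
    report = FilterReport(
        min_fraction=min_fraction,
        min_samples=min_samples,
        n_samples=matrix.n_samples,
        per_class=pd.DataFrame(rows, columns=["class", "kept", "dropped"]),
    )
    return matrix.subset(kept_ids), report


def correlation_pvalue(r, n):
    """Two-sided p-value for a Pearson coefficient under the t-transform.

    Uses ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.
    Accepts scalars or arrays; ``|r| = 1`` maps to the smallest positive
    float rather than 0, undefined r (NaN) propagates.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 3):
        raise CernetError("p-value needs n >= 3 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r_arr) * np.sqrt((n_arr - 2) / (1.0 - r_arr**2))
        p = 2.0 * stats.t.sf(t, n_arr - 2)
    tiny = np.finfo(float).tiny
    p = np.where(np.abs(r_arr) >= 1.0, tiny, p)
    p = np.where(np.isnan(r_arr), np.nan, p)
    p = np.clip(p, tiny, 1.0)
    if np.ndim(r) == 0 and np.ndim(n) == 0:
        return float(p)
    return p


def pair_count(matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix) -> int:
    """Number of records :func:`pearson_pairs` emits: |A|*|B| minus self-pairs.

    Self-pairs arise only when the same feature id occurs in both inputs.
    """
    shared = set(matrix_a.feature_ids) & set(matrix_b.feature_ids)
    return matrix_a.n_features * matrix_b.n_features - len(shared)


def pearson_pairs(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    adjust: str | None = None,
) -> pd.DataFrame:
    """All-pairs Pearson correlations between two feature sets.

    Both matrices must carry the identical sample ordering; correlations use
    all shared samples, zeros included (the expression filter has already
    removed mostly-zero features). Zero-variance features yield r = NaN
    records which downstream thresholds ignore. Self-pairs (same id in both
    inputs) are excluded, so the record count is exactly
    ``|A| * |B| - |A ∩ B|``.

    ``adjust="bh"`` appends a Benjamini–Hochberg ``q`` column; raw p-values
    are always reported.
    """
    if matrix_a.sample_ids != matrix_b.sample_ids:
        raise CernetError("sample ids/order differ between the two matrices")
    n = matrix_a.n_samples
    if n < 3:
        raise CernetError("need at least 3 samples for correlation")

    xa = matrix_a.values.to_numpy(dtype=float)
    xb = matrix_b.values.to_numpy(dtype=float)
    xa_c = xa - xa.mean(axis=1, keepdims=True)
    xb_c = xb - xb.mean(axis=1, keepdims=True)
    sa = np.sqrt((xa_c**2).sum(axis=1))
    sb = np.sqrt((xb_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xa_c @ xb_c.T) / np.outer(sa, sb)
    r[sa == 0, :] = np.nan
    r[:, sb == 0] = np.nan
    # guard rounding overshoot so p-values stay defined
    r = np.clip(r, -1.0, 1.0, out=r)

    na, nb = len(sa), len(sb)
    a_codes = np.repeat(np.arange(na), nb)
    b_codes = np.tile(np.arange(nb), na)
    r_flat = r.ravel()
    p_flat = correlation_pvalue(r_flat, n)

    a_ids = np.asarray(matrix_a.feature_ids, dtype=object)
    b_ids = np.asarray(matrix_b.feature_ids, dtype=object)
    a_classes = matrix_a.classes().to_numpy(dtype=object)
    b_classes = matrix_b.classes().to_numpy(dtype=object)
    df = pd.DataFrame(
        {
            "a_id": pd.Categorical.from_codes(a_codes, categories=a_ids),
            "b_id": pd.Categorical.from_codes(b_codes, categories=b_ids),
            "r": r_flat,
            "p": p_flat,
        }
    )
    # class columns as small categoricals mapped through the row/col codes
    ac_codes, ac_cats = pd.factorize(a_classes)
    bc_codes, bc_cats = pd.factorize(b_classes)
    df["a_class"] = pd.Categorical.from_codes(ac_codes[a_codes], categories=ac_cats)
    df["b_class"] = pd.Categorical.from_codes(bc_codes[b_codes], categories=bc_cats)
    df["n"] = n
    df = df[PAIR_COLUMNS]

    shared = set(matrix_a.feature_ids) & set(matrix_b.feature_ids)
    if shared:
        mask = df["a_id"].astype(object) == df["b_id"].astype(object)
        df = df[~mask].reset_index(drop=True)

    if adjust is not None:
        if adjust.lower() != "bh":
            raise CernetError(f"unknown p-value adjustment {adjust!r}")
        q = np.full(len(df), np.nan)
        ok = ~df["p"].isna().to_numpy()
        q[ok] = stats.false_discovery_control(df["p"].to_numpy()[ok], method="bh")
        df["q"] = q
    return df


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Serialize a pair-correlation table as TSV (the downloadable artifact)."""
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise CernetError(f"{path}: missing pair columns {sorted(missing)}")
    return df
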