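"""Single-RNA expression summaries: clinical grouping and heatmap scaling.

The heatmap convention maps each feature's values piecewise-linearly onto
[0, 1] with the minimum at 0, the median at 0.5 and the maximum at 1 —
the green/black/red scale used for circuit heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CernetError, ClinicalTable, ExpressionMatrix

NA_GROUP = "NA"


@dataclass
class GroupedExpression:
    """Expression of one feature grouped/ordered by a clinical parameter."""

    feature_id: str
    parameter: str
    kind: str  # "categorical" | "numeric"
    table: pd.DataFrame  # columns: sample_id, value, group (cat) or order key

    @property
    def group_sizes(self) -> pd.Series:
        if self.kind != "categorical":
            raise CernetError("group_sizes is defined for categorical parameters")
        return self.table.groupby("group", sort=True, observed=True).size()


def group_expression(
    matrix: ExpressionMatrix,
    feature_id: str,
    clinical: ClinicalTable,
    parameter: str,
) -> GroupedExpression:
    """Group (categorical) or order (numeric) one feature's samples.

    Categorical: samples are partitioned by parameter value, samples with a
    missing value land in an explicit ``"NA"`` group. Numeric: samples are
    sorted ascending by the parameter (missing values last), ties broken by
    sample id; every sample appears exactly once either way.
    """
    if feature_id not in matrix.values.index:
        raise CernetError(f"feature {feature_id!r} not in expression matrix")
    if parameter not in clinical.kinds:
        raise CernetError(
            f"unknown clinical parameter {parameter!r}; available: "
            f"{sorted(clinical.parameters)}"
        )
    values = matrix.values.loc[feature_id]
    param = clinical.data[parameter].reindex(values.index)
    kind = clinical.kinds[parameter]

    if kind == "categorical":
        group = param.astype(object).where(param.notna(), NA_GROUP).astype(str)
        table = pd.DataFrame(
            {"sample_id": values.index, "value": values.to_numpy(), "group": group.to_numpy()}
        ).sort_values(["group", "sample_id"], kind="stable").reset_index(drop=True)
    else:
        table = pd.DataFrame(
            {
                "sample_id": values.index,
                "value": values.to_numpy(),
                parameter: pd.to_numeric(param, errors="coerce").to_numpy(),
            }
        )
        table["_missing"] = table[parameter].isna()
        table = (
            table.sort_values(["_missing", parameter, "sample_id"], kind="stable")
            .drop(columns="_missing")
            .reset_index(drop=True)
        )
    return GroupedExpression(feature_id=feature_id, parameter=parameter,
                             kind=kind, table=table)


def heatmap_scale(values, reference=None) -> np.ndarray:
    """Min/median/max piecewise-linear scaling to [0, 1], per feature.

    Accepts a 1-D vector (one feature) or a 2-D array/DataFrame (features
    in rows; each row scaled independently). Within a feature: minimum -> 0,
    median -> 0.5, maximum -> 1, linear in between. A constant vector maps
    to all 0.5; when the median coincides with an extreme, values at that
    extreme map to 0.5 (the degenerate half-segment collapses). Values
    outside the anchor range clip to [0, 1].

    ``reference`` (1-D only) supplies the vector whose min/median/max anchor
    the scale, letting new values be placed on an existing feature's scale.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        ref = None if reference is None else np.asarray(reference, dtype=float)
        return _scale_row(arr, ref)
    if reference is not None:
        raise CernetError("reference is only supported for 1-D input")
    if arr.ndim == 2:
        out = np.vstack([_scale_row(row) for row in arr])
        if isinstance(values, pd.DataFrame):
            return pd.DataFrame(out, index=values.index, columns=values.columns)
        return out
    raise CernetError("heatmap_scale expects a 1-D or 2-D input")


def _scale_row(row: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    anchor = row if reference is None else reference
    if row.size == 0 or anchor.size == 0:
        raise CernetError("heatmap_scale needs at least one value per feature")
    lo, med, hi = np.min(anchor), np.median(anchor), np.max(anchor)
    if hi == lo:
        return np.full_like(row, 0.5)
    out = np.empty_like(row)
    lower = row < med
    if med > lo:
        out[lower] = 0.5 * (row[lower] - lo) / (med - lo)
    else:  # med == lo: lower half degenerate
        out[lower] = 0.5
    upper = row > med
    if hi > med:
        out[upper] = 0.5 + 0.5 * (row[upper] - med) / (hi - med)
    else:
        out[upper] = 0.5
    out[row == med] = 0.5
    return np.clip(out, 0.0, 1.0)


def scaled_heatmap_frame(matrix: ExpressionMatrix,
                         feature_ids=None) -> pd.DataFrame:
    """Heatmap-scaled values (rows: features, columns: samples) as a frame."""
    sub = matrix.values if feature_ids is None else matrix.subset(list(feature_ids)).values
    return heatmap_scale(sub)


def plot_heatmap(matrix: ExpressionMatrix, feature_ids, ax=None):
    """Optional plotting convenience (green-black-red, scaled per feature)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    scaled = scaled_heatmap_frame(matrix, feature_ids)
    cmap = LinearSegmentedColormap.from_list("gbr", ["green", "black", "red"])
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.4 * len(scaled) + 1))
    im = ax.imshow(scaled.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_yticks(range(len(scaled)), scaled.index)
    ax.set_xlabel("samples")
    return im
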