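"""Entropy-weight synthesis of composite community indices.

Three composites are assembled from the 24 base indices: C-diversity from
the eight alpha indices (per site), C-phyl from the eight phylogenetic
indices (per site), and C-stability from the eight stability indices (per
community group).

Method: min-max normalize each index over the alternatives (benefit columns
r = (x-min)/(max-min); cost columns r = (max-x)/(max-min)); form column
shares p_ij = r_ij / sum_i r_ij; Shannon entropy e_j = -(1/ln n) sum p ln p
(0 ln 0 = 0); weight w_j = (1-e_j) / sum_k (1-e_k); composite score of an
alternative = sum_j w_j r_ij. Constant columns carry zero information and
get zero weight.

Orientations are user-overridable; NRI, being centered at zero, enters as
|NRI| and is treated as a cost by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BenthosError
from .alpha import ALPHA_INDICES
from .phylo import PHYLO_INDICES
from .network import STABILITY_INDICES

BENEFIT, COST = "benefit", "cost"

#: default orientation of every base index
DEFAULT_ORIENTATION: dict[str, str] = {
    **{k: BENEFIT for k in ALPHA_INDICES},
    "PD": BENEFIT, "MPD": BENEFIT, "MNTD": BENEFIT,
    "NRI": COST,  # applied to |NRI|: departure from the null either way
    "PSV": BENEFIT, "PSR": BENEFIT, "PSE": BENEFIT, "PSC": BENEFIT,
    "ICV": BENEFIT, "C_pos": BENEFIT, "C_neg": BENEFIT,  # applied to |C_neg|
    "C_total": BENEFIT, "AVD": COST,  # higher mean |z| = more erratic
    "Robustness_R": BENEFIT, "Robustness_Y": BENEFIT, "Vulnerability": COST,
}

#: columns folded through absolute value before normalization
ABS_COLUMNS = ("NRI", "C_neg")

SCHEMAS = {
    "diversity": list(ALPHA_INDICES),
    "phyl": list(PHYLO_INDICES),
    "stability": list(STABILITY_INDICES),
}


@dataclass
class CompositeResult:
    normalized: pd.DataFrame
    weights: pd.Series
    entropy: pd.Series
    scores: pd.Series
    constant_columns: list = field(default_factory=list)
    imputed_cells: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)


def assemble(kind: str, records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Select the 8-column schema for one composite and patch missing cells.

    Missing values (an index undefined for one alternative) are imputed as
    the column minimum and reported; entirely missing columns are dropped.
    |NRI| and |C_neg| folding happens here so orientations stay simple.
    """
    if kind not in SCHEMAS:
        raise BenthosError(f"unknown composite kind {kind!r}")
    cols = [c for c in SCHEMAS[kind] if c in records.columns]
    absent = [c for c in SCHEMAS[kind] if c not in records.columns]
    df = records[cols].astype(float).copy()
    for c in ABS_COLUMNS:
        if c in df.columns:
            df[c] = df[c].abs()
    dropped = absent + [c for c in cols if df[c].isna().all()]
    df = df.drop(columns=[c for c in dropped if c in df.columns])
    imputed = []
    for c in df.columns:
        if df[c].isna().any():
            fill = df[c].min()
            for unit in df.index[df[c].isna()]:
                imputed.append((unit, c))
            df[c] = df[c].fillna(fill)
    orientation = {c: DEFAULT_ORIENTATION[c] for c in df.columns}
    df.attrs["imputed_cells"] = imputed
    df.attrs["dropped_columns"] = dropped
    return df, orientation


def normalize(matrix: pd.DataFrame, orientation: dict) -> tuple[pd.DataFrame, list]:
    """Min-max normalization with benefit/cost orientation.

    Constant columns map to all-zero and are flagged (they will get zero
    weight downstream).
    """
    missing = [c for c in matrix.columns if c not in orientation]
    if missing:
        raise BenthosError(f"orientation missing for columns: {missing}")
    if len(matrix) < 2:
        raise BenthosError("need at least 2 alternatives")
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    constant = []
    for c in matrix.columns:
        x = matrix[c].astype(float)
        rng = x.max() - x.min()
        if rng == 0 or not np.isfinite(rng):
            out[c] = 0.0
            constant.append(c)
        elif orientation[c] == BENEFIT:
            out[c] = (x - x.min()) / rng
        elif orientation[c] == COST:
            out[c] = (x.max() - x) / rng
        else:
            raise BenthosError(f"orientation for {c!r} must be benefit or cost")
    return out, constant


def entropy_weights(normalized: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Entropy e_j and weights w_j of the normalized matrix."""
    n = len(normalized)
    r = normalized.to_numpy(float)
    col_sum = r.sum(axis=0)
    e = np.ones(r.shape[1])  # constant (all-zero) column -> maximal entropy
    nz = col_sum > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nz, r / np.where(nz, col_sum, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e[nz] = -plogp[:, nz].sum(axis=0) / math.log(n)
    info = 1.0 - e
    if info.sum() <= 0:
        raise BenthosError("all columns constant: no information to weight")
    w = info / info.sum()
    return (
        pd.Series(w, index=normalized.columns, name="weight"),
        pd.Series(e, index=normalized.columns, name="entropy"),
    )


def composite_scores(normalized: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted sum of normalized indices per alternative."""
    return (normalized * weights).sum(axis=1).rename("score")


def evaluate(matrix: pd.DataFrame, orientation: dict | None = None) -> CompositeResult:
    """Full entropy-weight evaluation of an alternatives x indices matrix."""
    if orientation is None:
        orientation = {c: DEFAULT_ORIENTATION.get(c, BENEFIT) for c in matrix.columns}
    norm, constant = normalize(matrix, orientation)
    w, e = entropy_weights(norm)
    scores = composite_scores(norm, w)
    return CompositeResult(
        normalized=norm, weights=w, entropy=e, scores=scores,
        constant_columns=constant,
        imputed_cells=list(matrix.attrs.get("imputed_cells", [])),
        dropped_columns=list(matrix.attrs.get("dropped_columns", [])),
    )


def group_summary(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Mean +- sd of composite scores per group label."""
    df = pd.DataFrame({"score": scores, "group": labels.reindex(scores.index)})
    out = df.groupby("group")["score"].agg(["mean", "std", "count"])
    out.columns = ["mean", "sd", "n"]
    return out


def relative_decrease(reference: float, value: float) -> float:
    """Percent decrease of ``value`` relative to ``reference``.

    The comparison used when contrasting a disturbed group's composite with
    its control, e.g. the post-flood south-vs-north contrast.
    """
    if reference == 0:
        return math.nan
    return 100.0 * (reference - value) / reference
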