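"""Reference-based Cq normalization and per-assay group fold changes.

Relative expression of assay *a* in sample *s* is

    expr(s, a) = 2 ** -(Cq(s, a) - meanRefCq(s)),

where meanRefCq(s) is the arithmetic mean of the sample's detected
reference-miRNA Cq values. Lower Cq means more template, so expression is
dimensionless, positive, and equals 1 exactly when an assay's Cq matches
the sample's reference mean. A global Cq offset applied to every assay of a
sample (pipetting/input variation) cancels through the reference mean.

Fold change per assay is the quotient of arithmetic mean normalized
expression, cases (HT) over controls, computed on complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CqMatrix


@dataclass
class NormalizedMatrix:
    """Relative expression (samples x target assays) after reference normalization."""

    expr: pd.DataFrame
    reference_assays: tuple
    mean_reference_cq: pd.Series
    n_references_used: pd.Series

    @property
    def sample_ids(self) -> list:
        return list(self.expr.index)

    @property
    def assay_ids(self) -> list:
        return list(self.expr.columns)


def mean_reference_cq(cq, reference_assays) -> tuple[pd.Series, pd.Series]:
    """Per-sample arithmetic mean of the detected reference Cq values.

    Returns ``(mean, n_used)``; a sample with no detected reference at all
    is an error (such samples are QC exclusions, not normalization inputs).
    """
    values = cq.values if isinstance(cq, CqMatrix) else cq
    refs = [a for a in reference_assays]
    missing = [a for a in refs if a not in values.columns]
    if missing:
        raise KeyError(f"reference assay(s) not in matrix: {missing}")
    ref = values[refs]
    n_used = ref.notna().sum(axis=1)
    if (n_used == 0).any():
        bad = list(n_used.index[n_used == 0])
        raise ValueError(f"no detected reference Cq for sample(s) {bad}")
    return ref.mean(axis=1, skipna=True), n_used


class CqNormalizer(TransformerMixin, BaseEstimator):
    """Transformer from Cq values to reference-normalized relative expression.

    Parameters
    ----------
    reference_assays : sequence of str
        Column names of the reference miRNAs. They must be present in every
        frame passed to :meth:`transform`; the transform is stateless per
        sample (the reference mean is computed from the transformed frame
        itself, as the normalization is within-sample).
    drop_references : bool, default True
        Drop the reference columns from the output.
    """

    def __init__(self, reference_assays=("hsa-miR-30c-5p", "hsa-miR-103a-3p", "hsa-miR-23a-3p"),
                 drop_references: bool = True):
        self.reference_assays = reference_assays
        self.drop_references = drop_references

    def fit(self, X, y=None):
        values = X.values if isinstance(X, CqMatrix) else pd.DataFrame(X)
        refs = list(self.reference_assays)
        missing = [a for a in refs if a not in values.columns]
        if missing:
            raise ValueError(f"reference assay(s) not in input: {missing}")
        self.reference_assays_ = tuple(refs)
        self.n_features_in_ = values.shape[1]
        self.feature_names_in_ = np.asarray(values.columns, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "reference_assays_"):
            self.fit(X)
        values = X.values if isinstance(X, CqMatrix) else pd.DataFrame(X)
        mean_ref, _ = mean_reference_cq(values, self.reference_assays_)
        expr = np.power(2.0, -(values.sub(mean_ref, axis=0)))
        if self.drop_references:
            expr = expr.drop(columns=list(self.reference_assays_))
        return expr

    def get_feature_names_out(self, input_features=None):
        feats = list(input_features if input_features is not None else self.feature_names_in_)
        if self.drop_references:
            feats = [f for f in feats if f not in set(self.reference_assays_)]
        return np.asarray(feats, dtype=object)


def normalize_expression(cq: CqMatrix, reference_assays=None, target_assays=None) -> NormalizedMatrix:
    """Normalize a QC-retained :class:`CqMatrix` against its reference assays.

    ``target_assays`` defaults to the matrix's role-``target`` assays;
    missing Cq stays missing in the output.
    """
    if reference_assays is None:
        reference_assays = cq.assays_with_role("reference")
        if not reference_assays:
            raise ValueError("no reference assays annotated and none supplied")
    mean_ref, n_used = mean_reference_cq(cq, reference_assays)
    if target_assays is None:
        target_assays = cq.assays_with_role("target")
    expr = np.power(2.0, -(cq.values[list(target_assays)].sub(mean_ref, axis=0)))
    return NormalizedMatrix(
        expr=expr,
        reference_assays=tuple(reference_assays),
        mean_reference_cq=mean_ref,
        n_references_used=n_used,
    )


def fold_change(norm, groups: pd.Series, geometric: bool = False) -> pd.DataFrame:
    """Per-assay fold change of mean normalized expression, case over control.

    Group means are arithmetic over complete cases (observations with a
    detected value), matching the headline definition; ``geometric=True``
    switches to geometric means. Assays with an entirely missing group are
    marked non-evaluable (NaN fold change).
    """
    expr = norm.expr if isinstance(norm, NormalizedMatrix) else pd.DataFrame(norm)
    groups = groups.reindex(expr.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label ('case'/'control')")
    case = expr.loc[groups == "case"]
    ctrl = expr.loc[groups == "control"]
    if geometric:
        mean_case = np.exp(np.log(case).mean(axis=0, skipna=True))
        mean_ctrl = np.exp(np.log(ctrl).mean(axis=0, skipna=True))
    else:
        mean_case = case.mean(axis=0, skipna=True)
        mean_ctrl = ctrl.mean(axis=0, skipna=True)
    n_case = case.notna().sum(axis=0)
    n_ctrl = ctrl.notna().sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_ctrl
        log2_fc = np.log2(fc)
    out = pd.DataFrame(
        {
            "n_case": n_case,
            "n_control": n_ctrl,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fc": fc,
            "log2_fc": log2_fc,
        }
    )
    out["evaluable"] = (n_case > 0) & (n_ctrl > 0)
    out.loc[~out["evaluable"], ["fc", "log2_fc"]] = np.nan
    out.index.name = "assay"
    return out
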