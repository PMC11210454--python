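"""Sample- and assay-level quality gates applied before normalization.

Covers the four gates of a plasma-miRNA qPCR screen: spike-in monitoring of
isolation/RT efficiency, hemolysis detection via the miR-23a/miR-451a dCq
rule, detection of samples with aberrant reference-miRNA signal, and
assay-level filtering on missingness plus manual exclusions (e.g. assays
flagged for non-specific amplification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqMatrix


@dataclass
class QCReport:
    """Per-sample and per-assay QC outcomes.

    ``samples`` is indexed by sample id (spike-in Cq columns, hemolysis_dcq,
    hemolysis_flag, mean_reference_cq, reference_outlier_flag, reasons);
    ``assays`` by assay id (role, missing_fraction, excluded,
    exclusion_reason); ``spike_summary`` holds min/max/median per spike-in.
    """

    samples: pd.DataFrame
    assays: pd.DataFrame
    spike_summary: pd.DataFrame | None = None
    messages: list = field(default_factory=list)


def compute_hemolysis_dcq(
    cq: CqMatrix,
    pair: tuple[str, str] = ("hsa-miR-23a-3p", "hsa-miR-451a"),
    threshold: float = 7.0,
) -> pd.DataFrame:
    """Per-sample hemolysis indicator dCq = Cq(constant) - Cq(RBC marker).

    Hemolysis releases the red-blood-cell miR-451a into plasma, lowering its
    Cq and raising dCq; samples are flagged when dCq exceeds ``threshold``
    strictly (the customary cutoff is 7 cycles). Samples missing either
    marker get a missing dCq and flag, with a warning.
    """
    constant, rbc = pair
    for m in pair:
        if m not in cq.values.columns:
            raise KeyError(f"hemolysis marker {m!r} not present in Cq matrix")
    dcq = cq.values[constant] - cq.values[rbc]
    flag = pd.Series(pd.array(dcq > threshold, dtype="boolean"), index=dcq.index)
    flag[dcq.isna()] = pd.NA
    if dcq.isna().any():
        bad = list(dcq.index[dcq.isna()])
        warnings.warn(f"hemolysis markers missing for sample(s) {bad}; dCq undefined", UserWarning)
    return pd.DataFrame({"hemolysis_dcq": dcq, "hemolysis_flag": flag})


def spike_in_report(
    cq: CqMatrix,
    spike_ids: list | None = None,
    window: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike-in Cq per sample with deviation warnings, plus cohort summary.

    A sample is warned on a spike-in when its Cq deviates from the cohort
    median of that spike-in by more than ``window`` cycles. Returns
    ``(per_sample, summary)``; both are empty (with a warning) when no
    spike-ins are annotated.
    """
    if spike_ids is None:
        spike_ids = cq.assays_with_role("spike_in")
    spike_ids = [s for s in spike_ids if s in cq.values.columns]
    if not spike_ids:
        warnings.warn("no spike-in assays annotated; spike-in QC skipped", UserWarning)
        return (
            pd.DataFrame(index=cq.values.index),
            pd.DataFrame(columns=["min_cq", "max_cq", "median_cq", "n_warned"]),
        )
    per_sample = cq.values[spike_ids].copy()
    summary = pd.DataFrame(
        {
            "min_cq": per_sample.min(),
            "max_cq": per_sample.max(),
            "median_cq": per_sample.median(),
        }
    )
    for s in spike_ids:
        dev = (per_sample[s] - summary.loc[s, "median_cq"]).abs()
        per_sample[f"{s}_warn"] = dev > window
    warn_cols = [f"{s}_warn" for s in spike_ids]
    summary["n_warned"] = [int(per_sample[f"{s}_warn"].sum()) for s in spike_ids]
    per_sample["spike_warn_any"] = per_sample[warn_cols].any(axis=1)
    return per_sample, summary


def detect_reference_outlier_samples(
    cq: CqMatrix,
    reference_assays: list | None = None,
    rule: str = "robust_z",
    cutoff: float = 3.5,
    gap: float = 3.0,
) -> pd.DataFrame:
    """Flag samples whose mean reference-miRNA Cq is aberrant.

    A sample with unusually high mean reference Cq carries too little
    material (many targets will be undetected) and should be excluded.
    Two explicit rules are offered:

    - ``robust_z``: |x - median| / (1.4826 * MAD) > ``cutoff`` (default 3.5).
      With MAD = 0, only samples actually deviating from the median flag.
    - ``gap``: mean exceeds the highest other sample's mean by more than
      ``gap`` cycles (default 3).

    Samples with no detected reference signal at all are flagged with
    reason ``no_reference_signal``.
    """
    if reference_assays is None:
        reference_assays = cq.assays_with_role("reference")
    missing = [a for a in reference_assays if a not in cq.values.columns]
    if missing:
        raise KeyError(f"reference assay(s) not in matrix: {missing}")
    ref = cq.values[list(reference_assays)]
    mean_ref = ref.mean(axis=1, skipna=True)
    no_signal = ref.isna().all(axis=1)

    flag = no_signal.copy()
    reason = pd.Series("", index=mean_ref.index, dtype=object)
    reason[no_signal] = "no_reference_signal"

    usable = mean_ref[~no_signal]
    if len(usable) < 2:
        if len(usable) == 1:
            warnings.warn("single sample: reference-outlier detection undefined", UserWarning)
    elif rule == "robust_z":
        med = usable.median()
        dev = (usable - med).abs()
        mad = dev.median()
        if mad == 0:
            out = dev > 0
        else:
            out = dev / (1.4826 * mad) > cutoff
        flag.loc[out.index[out]] = True
        reason.loc[out.index[out]] = "reference_outlier"
    elif rule == "gap":
        for s in usable.index:
            others = usable.drop(s)
            if usable[s] - others.max() > gap:
                flag[s] = True
                reason[s] = "reference_outlier"
    else:
        raise ValueError(f"unknown outlier rule {rule!r}; use 'robust_z' or 'gap'")

    return pd.DataFrame(
        {"mean_reference_cq": mean_ref, "reference_outlier_flag": flag, "outlier_reason": reason}
    )


def apply_missingness_filter(
    cq: CqMatrix,
    threshold: float = 0.5,
) -> tuple[list, list, pd.DataFrame]:
    """Split target assays into retained/excluded by missing fraction.

    An assay is excluded iff its fraction of not-detected samples exceeds
    ``threshold`` strictly ("more than 50%" at the default). Reference,
    hemolysis-marker and spike-in assays are exempt but reported. The
    denominators are the samples currently in ``cq`` (i.e. after any sample
    exclusions).
    """
    frac = cq.missing_fraction()
    table = pd.DataFrame(
        {
            "role": [cq.assay_role[a] for a in cq.values.columns],
            "missing_fraction": frac,
        }
    )
    is_target = table["role"] == "target"
    table["excluded"] = is_target & (table["missing_fraction"] > threshold)
    table["exclusion_reason"] = np.where(table["excluded"], "missingness", "")
    retained = list(table.index[~table["excluded"]])
    excluded = list(table.index[table["excluded"]])
    return retained, excluded, table


def apply_manual_exclusions(
    cq: CqMatrix,
    exclusions,
    already_excluded: dict | None = None,
) -> tuple[CqMatrix, pd.DataFrame]:
    """Remove manually flagged assays/samples (e.g. non-specific amplification).

    ``exclusions`` is an iterable of ``(id, kind, reason)`` with kind in
    {'assay', 'sample'}. Re-excluding an id already removed earlier is
    idempotent (no duplicate log entry); an id never seen is an error.
    Returns the reduced matrix and the exclusion log.
    """
    already = dict(already_excluded or {})
    records = []
    drop_assays, drop_samples = [], []
    for ident, kind, reason in exclusions:
        if kind not in ("assay", "sample"):
            raise ValueError(f"exclusion kind must be 'assay' or 'sample', got {kind!r}")
        pool = cq.values.columns if kind == "assay" else cq.values.index
        if ident in already or ident in drop_assays or ident in drop_samples:
            continue  # idempotent
        if ident not in pool:
            raise KeyError(f"cannot exclude unknown {kind} {ident!r}")
        (drop_assays if kind == "assay" else drop_samples).append(ident)
        records.append({"id": ident, "kind": kind, "reason": reason})
    values = cq.values.drop(index=drop_samples, columns=drop_assays)
    out = CqMatrix(values, {a: cq.assay_role[a] for a in values.columns})
    return out, pd.DataFrame(records, columns=["id", "kind", "reason"])


def build_qc_report(
    cq: CqMatrix,
    hemolysis_pair: tuple[str, str] = ("hsa-miR-23a-3p", "hsa-miR-451a"),
    hemolysis_threshold: float = 7.0,
    reference_assays: list | None = None,
    spike_window: float = 2.0,
    missingness_threshold: float = 0.5,
    outlier_rule: str = "robust_z",
    outlier_cutoff: float = 3.5,
    outlier_gap: float = 3.0,
) -> QCReport:
    """Run all QC gates on a Cq matrix and assemble a :class:`QCReport`."""
    msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        hemo = compute_hemolysis_dcq(cq, hemolysis_pair, hemolysis_threshold)
        spikes, spike_summary = spike_in_report(cq, window=spike_window)
        outliers = detect_reference_outlier_samples(
            cq, reference_assays, rule=outlier_rule, cutoff=outlier_cutoff, gap=outlier_gap
        )
    msgs.extend(str(w.message) for w in caught)
    samples = pd.concat([spikes, hemo, outliers], axis=1)
    _, _, assays = apply_missingness_filter(cq, missingness_threshold)
    return QCReport(samples=samples, assays=assays, spike_summary=spike_summary, messages=msgs)
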