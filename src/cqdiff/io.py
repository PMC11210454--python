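"""Data model and readers/writers for wide-format qPCR Cq tables.

The canonical in-memory containers are thin wrappers around pandas
DataFrames: a :class:`CqMatrix` holds quantification-cycle (Cq) values with
samples as rows, assays as columns and ``NaN`` marking "not detected";
:class:`SampleMetadata` holds per-sample group labels (case = hemorrhagic
transformation, control = no HT) and matching covariates.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ASSAY_ROLES = ("target", "reference", "hemolysis_marker", "spike_in")

#: Tokens interpreted as "not detected" when reading Cq tables. qPCR export
#: dialects vary; the list is configurable at the reader.
DEFAULT_NA_TOKENS = ("", "NA", "N/A", "nan", "NaN", "ND", "Undetermined", "undetermined", "not detected")

CQ_MIN = 0.0   # exclusive
CQ_MAX = 45.0  # inclusive; customary qPCR cycle ceiling


def _check_unique(ids: Iterable, what: str) -> None:
    seen, dups = set(), set()
    for i in map(str, ids):
        if i in seen:
            dups.add(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} id(s): {sorted(dups)}")


@dataclass
class CqMatrix:
    """Samples x assays matrix of Cq values with per-assay roles.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with assay ids as columns. Missing
        ("not detected") entries are ``NaN``. Every present value must lie
        in the open-closed interval (0, 45].
    assay_role
        Mapping assay id -> one of ``target``, ``reference``,
        ``hemolysis_marker``, ``spike_in``. Assays absent from the mapping
        default to ``target``.
    """

    values: pd.DataFrame
    assay_role: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "assay")
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        bad = np.where(~np.isnan(arr) & ((arr <= CQ_MIN) | (arr > CQ_MAX)))
        if bad[0].size:
            s = self.values.index[bad[0][0]]
            a = self.values.columns[bad[1][0]]
            raise ValueError(
                f"Cq value {arr[bad[0][0], bad[1][0]]!r} at sample {s!r}, assay {a!r} "
                f"outside valid interval ({CQ_MIN}, {CQ_MAX}]"
            )
        role = {}
        for a in self.values.columns:
            r = self.assay_role.get(a, "target")
            if r not in ASSAY_ROLES:
                raise ValueError(f"unknown role {r!r} for assay {a!r}; must be one of {ASSAY_ROLES}")
            role[a] = r
        self.assay_role = role

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list:
        return list(self.values.columns)

    def assays_with_role(self, role: str) -> list:
        return [a for a in self.values.columns if self.assay_role[a] == role]

    def missing_fraction(self) -> pd.Series:
        """Per-assay fraction of samples with no detected signal."""
        return self.values.isna().mean(axis=0)

    def subset(self, samples: Sequence | None = None, assays: Sequence | None = None) -> "CqMatrix":
        v = self.values
        if samples is not None:
            missing = [s for s in samples if s not in v.index]
            if missing:
                raise KeyError(f"unknown sample id(s): {missing}")
            v = v.loc[list(samples)]
        if assays is not None:
            missing = [a for a in assays if a not in v.columns]
            if missing:
                raise KeyError(f"unknown assay id(s): {missing}")
            v = v[list(assays)]
        return CqMatrix(v.copy(), {a: self.assay_role[a] for a in v.columns})


@dataclass
class SampleMetadata:
    """Per-sample group labels, covariates and exclusion flags.

    ``table`` is indexed by sample id and has at least a ``group`` column
    with values ``case`` / ``control``; further columns are matching
    covariates. ``excluded`` / ``exclusion_reason`` columns are added when
    absent.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        t = self.table.copy()
        if "group" not in t.columns:
            raise ValueError("sample metadata must have a 'group' column")
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclusion_reason" not in t.columns:
            t["exclusion_reason"] = ""
        t["excluded"] = t["excluded"].astype(bool)
        bad = set(t.loc[~t["excluded"], "group"].dropna()) - {"case", "control"}
        if bad:
            raise ValueError(f"unmappable group token(s): {sorted(bad)}; expected 'case'/'control'")
        if t.loc[~t["excluded"], "group"].isna().any():
            raise ValueError("group must be defined for all non-excluded samples")
        self.table = t

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def covariate_names(self) -> list:
        return [c for c in self.table.columns if c not in ("group", "excluded", "exclusion_reason")]


DEFAULT_GROUP_MAP = {"HT": "case", "non-HT": "control", "case": "case", "control": "control"}


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis, with the study's defaults."""

    reference_assays: tuple = ("hsa-miR-30c-5p", "hsa-miR-103a-3p", "hsa-miR-23a-3p")
    hemolysis_pair: tuple = ("hsa-miR-23a-3p", "hsa-miR-451a")
    hemolysis_threshold: float = 7.0     # dCq cycles, strict >
    missingness_threshold: float = 0.5   # fraction, strict >
    trim_proportion: float = 0.10        # gamma, trimmed fraction per tail
    n_permutations: int = 1000
    rng_seed: int = 123
    alpha: float = 0.10
    fc_low: float = 0.67
    fc_high: float = 1.5
    spike_window: float = 2.0            # cycles around cohort median
    outlier_rule: str = "robust_z"       # or "gap"
    outlier_cutoff: float = 3.5          # robust z
    outlier_gap: float = 3.0             # cycles over next-highest mean

    def __post_init__(self) -> None:
        if not (0 <= self.trim_proportion < 0.5):
            raise ValueError("trim_proportion must satisfy 0 <= gamma < 0.5")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.fc_low < 1 < self.fc_high):
            raise ValueError("need 0 < fc_low < 1 < fc_high")
        self.reference_assays = tuple(self.reference_assays)
        self.hemolysis_pair = tuple(self.hemolysis_pair)
        if len(self.hemolysis_pair) != 2:
            raise ValueError("hemolysis_pair must name (constant_marker, rbc_marker)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_assays"] = list(self.reference_assays)
        d["hemolysis_pair"] = list(self.hemolysis_pair)
        return d


def load_analysis_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON file (field-for-field)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return AnalysisConfig(**data)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_assay_annotation(path_or_df) -> dict:
    """Read an assay-role table (columns ``assay_id``, ``role``) into a dict."""
    if isinstance(path_or_df, Mapping):
        return dict(path_or_df)
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=_sep_for(path_or_df))
    if not {"assay_id", "role"} <= set(df.columns):
        raise ValueError("assay annotation needs 'assay_id' and 'role' columns")
    return dict(zip(df["assay_id"].astype(str), df["role"].astype(str)))


def read_cq_table(
    path,
    annotation=None,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
    transpose: bool = False,
    sep: str | None = None,
) -> CqMatrix:
    """Read a delimited wide Cq table into a :class:`CqMatrix`.

    First column holds sample ids, remaining columns assay ids (pass
    ``transpose=True`` for assay-row exports). Blank cells and any token in
    ``na_tokens`` mean "not detected". Values outside (0, 45] and duplicate
    ids are hard errors.
    """
    sep = sep or _sep_for(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        keep_default_na=False, skipinitialspace=True,
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if transpose:
        df = df.T
    tokens = {t.strip().lower() for t in na_tokens}
    def parse(cell: str):
        c = str(cell).strip()
        if c.lower() in tokens:
            return np.nan
        try:
            return float(c)
        except ValueError:
            raise ValueError(f"cannot parse Cq value {cell!r}") from None
    parsed = df.map(parse)
    roles = read_assay_annotation(annotation) if annotation is not None else {}
    return CqMatrix(parsed, roles)


def write_cq_table(cq: CqMatrix, path, na_token: str = "") -> None:
    """Serialize a :class:`CqMatrix`; inverse of :func:`read_cq_table`."""
    out = cq.values.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep=_sep_for(path), na_rep=na_token, float_format="%.10g")


def read_sample_metadata(
    path,
    group_map: Mapping[str, str] | None = None,
    case_insensitive: bool = False,
    sep: str | None = None,
) -> SampleMetadata:
    """Read per-sample metadata; maps group tokens (default HT -> case)."""
    gmap = dict(DEFAULT_GROUP_MAP if group_map is None else group_map)
    if case_insensitive:
        gmap = {k.lower(): v for k, v in gmap.items()}
    sep = sep or _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    if "group" not in df.columns:
        raise ValueError("metadata must have a 'group' column")
    def map_group(tok):
        if pd.isna(tok):
            return np.nan
        key = str(tok).strip()
        if case_insensitive:
            key = key.lower()
        if key not in gmap:
            raise ValueError(f"unmappable group token {tok!r}")
        return gmap[key]
    df["group"] = df["group"].map(map_group)
    return SampleMetadata(df)


def validate_dataset(cq: CqMatrix, metadata: SampleMetadata) -> None:
    """Check that metadata and Cq matrix describe the same samples."""
    extra = set(metadata.sample_ids) - set(cq.sample_ids)
    if extra:
        raise ValueError(f"metadata sample(s) absent from Cq matrix: {sorted(extra)}")
    missing = set(cq.sample_ids) - set(metadata.sample_ids)
    if missing:
        raise ValueError(f"Cq matrix sample(s) absent from metadata: {sorted(missing)}")


DIFF_COLUMNS = ["assay", "n_case", "n_control", "fc", "log2_fc", "t_yuen", "p_perm", "p_adj", "class"]


def write_results(diff_table: pd.DataFrame, qc_report, out_dir, manifest: dict | None = None) -> dict:
    """Write diff_table.tsv, qc_report.tsv and manifest.json to ``out_dir``.

    Returns the paths written. The QC report file carries a sample section
    and an assay section, separated by ``# samples`` / ``# assays`` lines.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    dt = diff_table.copy() if diff_table is not None else pd.DataFrame(columns=DIFF_COLUMNS)
    for col in DIFF_COLUMNS:
        if col not in dt.columns:
            dt[col] = np.nan
    extra = [c for c in dt.columns if c not in DIFF_COLUMNS]
    dt = dt[DIFF_COLUMNS + extra]
    paths["diff_table"] = out / "diff_table.tsv"
    dt.to_csv(paths["diff_table"], sep="\t", index=False, float_format="%.10g")

    paths["qc_report"] = out / "qc_report.tsv"
    with open(paths["qc_report"], "w") as fh:
        fh.write("# samples\n")
        if qc_report is not None and getattr(qc_report, "samples", None) is not None:
            qc_report.samples.to_csv(fh, sep="\t", index_label="sample_id", float_format="%.10g")
        fh.write("# assays\n")
        if qc_report is not None and getattr(qc_report, "assays", None) is not None:
            qc_report.assays.to_csv(fh, sep="\t", index_label="assay_id", float_format="%.10g")

    if manifest is not None:
        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    return paths
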