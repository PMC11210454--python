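"""Per-assay robust permutation testing and dysregulation classification.

Each QC-retained target assay is tested for a case/control difference in
normalized expression with the permutation Yuen-Welch test on complete
cases, p-values are Benjamini-Hochberg adjusted across all tested assays,
and assays are classified on fold change and the raw permutation p:

    down  iff fc < fc_low  and p < alpha      (defaults 0.67, 0.10)
    up    iff fc > fc_high and p < alpha      (defaults 1.5,  0.10)

all inequalities strict. Classification deliberately uses the raw
permutation p (the adjusted values are reported alongside): in a small
pilot screen the BH-adjusted values rarely clear any threshold and the
screening call is made on the unadjusted p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import AnalysisConfig, DIFF_COLUMNS
from .normalization import NormalizedMatrix, fold_change
from .stats import bh_adjust, permutation_yuen_test

CLASSES = ("up", "down", "not_significant", "excluded")


def classify_dysregulation(fc: float, p: float, config: AnalysisConfig | None = None,
                           fc_low: float | None = None, fc_high: float | None = None,
                           alpha: float | None = None) -> str:
    """Classify one assay from its fold change and (raw) permutation p."""
    cfg = config or AnalysisConfig()
    fc_low = cfg.fc_low if fc_low is None else fc_low
    fc_high = cfg.fc_high if fc_high is None else fc_high
    alpha = cfg.alpha if alpha is None else alpha
    if fc is None or p is None or np.isnan(fc) or np.isnan(p):
        return "excluded"
    if fc < fc_low and p < alpha:
        return "down"
    if fc > fc_high and p < alpha:
        return "up"
    return "not_significant"


def run_differential(norm, groups: pd.Series, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Test every assay of a normalized matrix and classify it.

    Per assay: complete cases are split by group; with fewer than 2 complete
    cases in either group the assay is excluded from testing (reason
    logged). Otherwise the Monte-Carlo permutation Yuen-Welch test runs on
    an assay-specific RNG stream spawned from the root seed in assay order,
    so results are reproducible and independent of which other assays are
    present. BH adjustment spans all tested assays.
    """
    cfg = config or AnalysisConfig()
    expr = norm.expr if isinstance(norm, NormalizedMatrix) else pd.DataFrame(norm)
    fc_table = fold_change(norm, groups)
    groups = groups.reindex(expr.index)

    streams = np.random.SeedSequence(cfg.rng_seed).spawn(len(expr.columns))
    rows = []
    for assay, stream in zip(expr.columns, streams):
        col = expr[assay]
        x = col[(groups == "case") & col.notna()].to_numpy()
        y = col[(groups == "control") & col.notna()].to_numpy()
        rec = {
            "assay": assay,
            "n_case": len(x),
            "n_control": len(y),
            "fc": fc_table.loc[assay, "fc"],
            "log2_fc": fc_table.loc[assay, "log2_fc"],
            "t_yuen": np.nan,
            "p_perm": np.nan,
            "reason": "",
        }
        if len(x) < 2 or len(y) < 2:
            rec["class"] = "excluded"
            rec["reason"] = "too_few_complete_cases"
        else:
            res = permutation_yuen_test(
                x, y, trim=cfg.trim_proportion,
                n_permutations=cfg.n_permutations,
                random_state=np.random.default_rng(stream),
            )
            rec["t_yuen"] = res.statistic
            rec["p_perm"] = res.pvalue
            rec["class"] = classify_dysregulation(rec["fc"], res.pvalue, cfg)
        rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        import warnings

        warnings.warn("no assays testable; empty differential table", UserWarning)
        return pd.DataFrame(columns=DIFF_COLUMNS + ["reason"])
    table["p_adj"] = bh_adjust(table["p_perm"].to_numpy())
    return table[DIFF_COLUMNS + ["reason"]]


class DifferentialExpressionTest(BaseEstimator):
    """Estimator-style wrapper around :func:`run_differential`.

    ``fit(X, y)`` takes a samples x assays expression DataFrame and
    case/control labels and exposes the resulting table as ``results_``.
    """

    def __init__(self, trim_proportion: float = 0.10, n_permutations: int = 1000,
                 rng_seed: int = 123, alpha: float = 0.10,
                 fc_low: float = 0.67, fc_high: float = 1.5):
        self.trim_proportion = trim_proportion
        self.n_permutations = n_permutations
        self.rng_seed = rng_seed
        self.alpha = alpha
        self.fc_low = fc_low
        self.fc_high = fc_high

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        cfg = AnalysisConfig(
            trim_proportion=self.trim_proportion,
            n_permutations=self.n_permutations,
            rng_seed=self.rng_seed,
            alpha=self.alpha,
            fc_low=self.fc_low,
            fc_high=self.fc_high,
        )
        self.results_ = run_differential(X, y, cfg)
        self.n_features_in_ = X.shape[1]
        return self


def volcano_coordinates(diff: pd.DataFrame, config: AnalysisConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """(log2 FC, -log10 p) pairs for plotting, plus guide-line positions.

    Excluded rows produce no coordinates. Guide lines sit at p = alpha and
    at the two fold-change thresholds.
    """
    cfg = config or AnalysisConfig()
    ok = diff[diff["class"] != "excluded"].copy()
    coords = pd.DataFrame(
        {
            "assay": ok["assay"],
            "x": ok["log2_fc"].astype(float),
            "y": -np.log10(ok["p_perm"].astype(float)),
            "class": ok["class"],
        }
    ).reset_index(drop=True)
    lines = {
        "p": cfg.alpha,
        "y": -np.log10(cfg.alpha),
        "x_low": np.log2(cfg.fc_low),
        "x_high": np.log2(cfg.fc_high),
    }
    return coords, lines


def classified_expression_long(diff: pd.DataFrame, norm, groups: pd.Series,
                               classes: tuple = ("up", "down")) -> pd.DataFrame:
    """Long-format expression values (assay, sample, group, expr) for every
    assay in the given classes — the data behind per-assay group box plots."""
    expr = norm.expr if isinstance(norm, NormalizedMatrix) else pd.DataFrame(norm)
    assays = diff.loc[diff["class"].isin(classes), "assay"]
    records = expr[list(assays)].stack().rename("expr").reset_index()
    records.columns = ["sample", "assay", "expr"]
    records["group"] = records["sample"].map(groups)
    return records[["assay", "sample", "group", "expr"]]


def volcano_plot(diff: pd.DataFrame, path=None, config: AnalysisConfig | None = None):
    """Render the volcano plot of a differential table (optional output file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords, lines = volcano_coordinates(diff, config)
    colors = {"up": "tab:red", "down": "tab:blue", "not_significant": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in coords.groupby("class"):
        ax.scatter(sub["x"], sub["y"], s=18, c=colors.get(cls, "0.6"), label=cls)
    ax.axhline(lines["y"], color="tab:blue", lw=0.8, ls="--")
    ax.axvline(lines["x_low"], color="tab:red", lw=0.8, ls="--")
    ax.axvline(lines["x_high"], color="tab:red", lw=0.8, ls="--")
    ax.set_xlabel("log2 fold change (case / control)")
    ax.set_ylabel("-log10 permutation p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
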