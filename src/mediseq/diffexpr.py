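"""Quantile normalization, regularized fold changes, paired testing with
Benjamini-Hochberg FDR, DEG calling, and volcano/heatmap matrices.

The fold change is regularized with a pseudocount r (default 5,
alternatively 10) added to both terms, which caps the apparent fold
change of genes whose expression sits around or below r. DEGs require
|FC| > fc_cut together with p < p_cut and q < q_cut under a paired
two-sided t-test across sample pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix, QUANTILE, RAW

DEFAULT_REGULARIZER = 5.0
FC_CUT = 1.5
ALPHA = 0.05
P_FLOOR = 1e-300  # before -log10, keeps volcano values finite


@dataclass(frozen=True)
class PairedDesign:
    """Ordered (control, treated) sample pairs; no sample reused."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("paired testing needs >= 2 pairs")
        flat = [s for p in self.pairs for s in p]
        if len(set(flat)) != len(flat):
            raise ValueError("a sample appears in more than one design slot")

    @property
    def controls(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def treated(self) -> list[str]:
        return [t for _, t in self.pairs]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = (set(self.controls) | set(self.treated)) - set(matrix.samples)
        if missing:
            raise ValueError(f"design samples absent from matrix: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path) -> "PairedDesign":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(zip(df["control"], df["treated"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "pair_id": [f"pair{i + 1}" for i in range(len(self.pairs))],
                "control": self.controls,
                "treated": self.treated,
            }
        ).to_csv(path, sep="\t", index=False)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common rank-mean distribution.

    The reference distribution is the across-sample mean of the
    column-sorted values; each entry is replaced by the reference value
    at its within-column rank, ties receiving the mean of the reference
    values at their tied ranks (via average ranks + interpolation).
    """
    if matrix.normalization_state != RAW:
        raise ValueError("matrix is already normalized")
    values = matrix.values.to_numpy(dtype=float)
    n, m = values.shape
    if m < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        QUANTILE,
    )


def regularized_log2fc(a, b, r: float = DEFAULT_REGULARIZER):
    """log2((a + r) / (b + r)); antisymmetric in (a, b). r damps the
    apparent fold change of values at or below r."""
    if r <= 0:
        raise ValueError("regularizer must be > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    result = np.log2((a + r) / (b + r))
    return float(result) if result.ndim == 0 else result


def paired_test(differences: np.ndarray) -> float:
    """Two-sided p from the t distribution with n-1 df on the mean of the
    paired differences; NaN when the differences have zero variance."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        return float("nan")
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(2.0 * stats.t.sf(abs(t), d.size - 1))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j, capped
    at 1, returned in the input order. NaN entries stay NaN and do not
    count toward m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    valid = ~np.isnan(p)
    q = np.full(p.shape, np.nan)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.minimum(qv, 1.0)
        out = np.empty(m)
        out[order] = qv
        q[valid] = out
    return q


def differential_table(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    regularizer: float = DEFAULT_REGULARIZER,
    per_pair_fc: bool = False,
    log_before_test: bool = False,
) -> pd.DataFrame:
    """Per-gene means, regularized log2 FC (treated vs control), paired
    p, and BH q. FC uses means across pairs before the ratio unless
    ``per_pair_fc`` averages per-pair regularized ratios instead."""
    design.validate_against(matrix)
    ctrl = matrix.values[design.controls].to_numpy(dtype=float)
    treat = matrix.values[design.treated].to_numpy(dtype=float)
    mean_ctrl = ctrl.mean(axis=1)
    mean_treat = treat.mean(axis=1)
    if per_pair_fc:
        l2fc = regularized_log2fc(treat, ctrl, regularizer).mean(axis=1)
    else:
        l2fc = regularized_log2fc(mean_treat, mean_ctrl, regularizer)

    vals_t, vals_c = (np.log2(treat + 1), np.log2(ctrl + 1)) if log_before_test \
        else (treat, ctrl)
    d = vals_t - vals_c
    n = d.shape[1]
    sd = d.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d.mean(axis=1) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p[sd == 0] = np.nan  # degenerate: excluded from FDR ranking
    q = fdr_adjust(p)
    return pd.DataFrame(
        {
            "mean_ctrl": mean_ctrl,
            "mean_treat": mean_treat,
            "log2fc_reg": l2fc,
            "p_value": p,
            "q_value": q,
        },
        index=matrix.values.index,
    )


def call_degs(
    results: pd.DataFrame,
    fc_cut: float = FC_CUT,
    p_cut: float = ALPHA,
    q_cut: float = ALPHA,
) -> pd.DataFrame:
    """Flag genes passing |FC| > fc_cut AND p < p_cut AND q < q_cut."""
    out = results.copy()
    lfc_gate = np.abs(out["log2fc_reg"]) > np.log2(fc_cut)
    out["is_deg"] = (
        lfc_gate
        & (out["p_value"] < p_cut)
        & (out["q_value"] < q_cut)
    ).fillna(False)
    out.attrs["summary"] = deg_summary(out)
    return out


def deg_summary(results: pd.DataFrame) -> dict[str, int]:
    deg = results[results["is_deg"]]
    return {
        "total": int(len(deg)),
        "up": int((deg["log2fc_reg"] > 0).sum()),
        "down": int((deg["log2fc_reg"] < 0).sum()),
    }


def volcano_table(results: pd.DataFrame, fc_cut: float = FC_CUT) -> pd.DataFrame:
    """(log2fc, -log10 p, highlight) per gene; p floored to stay finite.
    ``highlight`` marks which side of the FC cutoff a gene falls on;
    color semantics are left to the caller."""
    p = results["p_value"].to_numpy(dtype=float)
    neglog = -np.log10(np.clip(p, P_FLOOR, None))
    return pd.DataFrame(
        {
            "log2fc": results["log2fc_reg"],
            "neg_log10_p": neglog,
            "highlight": np.abs(results["log2fc_reg"]) > np.log2(fc_cut),
        },
        index=results.index,
    )


def heatmap_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Elementwise log2(value + 1) of the expression matrix."""
    values = matrix.values.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    return pd.DataFrame(
        np.log2(values + 1.0), index=matrix.values.index,
        columns=matrix.values.columns,
    )
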