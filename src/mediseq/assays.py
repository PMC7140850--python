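"""Proliferation-assay and qPCR quantification plus group comparisons.

EdU fractions pool counts within the aggregation unit (sum of EdU+ over
sum of DAPI+, as a percentage) rather than averaging per-field
percentages; a flag restores per-field averaging. qPCR fold changes use
the standard reference-gene Ct normalization (2^-ddCt).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EXPECTED_FIELDS = 9  # imaged areas per coverslip


def validate_assay_counts(table: pd.DataFrame) -> pd.DataFrame:
    required = {"coverslip_id", "condition", "field_index", "dapi_count", "edu_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"assay table missing columns {sorted(missing)}")
    if (table["edu_count"] > table["dapi_count"]).any():
        bad = table[table["edu_count"] > table["dapi_count"]].iloc[0]
        raise ValueError(
            f"edu_count exceeds dapi_count for coverslip {bad['coverslip_id']!r} "
            f"field {bad['field_index']}"
        )
    if (table[["dapi_count", "edu_count"]] < 0).any().any():
        raise ValueError("negative counts")
    n_fields = table.groupby("coverslip_id")["field_index"].size()
    odd = n_fields[n_fields != EXPECTED_FIELDS]
    for cs, n in odd.items():
        log.warning("coverslip %s has %d fields (expected %d)", cs, n, EXPECTED_FIELDS)
    return table


def edu_fraction(
    table: pd.DataFrame, per: str = "coverslip", pool: bool = True
) -> pd.DataFrame:
    """Percentage of EdU+ among DAPI+ nuclei per aggregation unit.

    ``per`` is 'coverslip' or 'condition'. Pooling sums counts across the
    unit's fields; ``pool=False`` averages per-field percentages instead.
    Units with zero DAPI+ get NaN with a warning.
    """
    validate_assay_counts(table)
    key = {"coverslip": ["coverslip_id", "condition"], "condition": ["condition"]}[per]
    if pool:
        g = table.groupby(key, as_index=False)[["dapi_count", "edu_count"]].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            g["edu_percent"] = 100.0 * g["edu_count"] / g["dapi_count"]
        g.loc[g["dapi_count"] == 0, "edu_percent"] = np.nan
    else:
        t = table.copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t["field_pct"] = 100.0 * t["edu_count"] / t["dapi_count"]
        g = t.groupby(key, as_index=False)["field_pct"].mean()
        g = g.rename(columns={"field_pct": "edu_percent"})
    if g["edu_percent"].isna().any():
        log.warning("units with zero DAPI+ nuclei reported as NA")
    return g


def compare_conditions(
    fractions: pd.DataFrame,
    design: str,
    control: str | None = None,
    value: str = "edu_percent",
    condition: str = "condition",
    unit: str = "coverslip_id",
) -> pd.DataFrame:
    """Group comparison of per-unit fractions.

    ``design``: 'paired' (t-test on matched units, matched by sorted unit
    suffix order), 'unpaired' (Welch off, classic two-sample t) or
    'anova' (one-way across all conditions). Returns statistic, two-sided
    p and fold change vs control per contrast.
    """
    if design not in ("paired", "unpaired", "anova"):
        raise ValueError("design must be paired, unpaired or anova")
    conds = list(dict.fromkeys(fractions[condition]))
    if control is None:
        control = conds[0]
    if control not in conds:
        raise ValueError(f"control condition {control!r} absent")
    groups = {
        c: fractions.loc[fractions[condition] == c].sort_values(unit)
        for c in conds
    }
    for c, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"condition {c!r} has < 2 units")

    if design == "anova":
        stat, p = stats.f_oneway(*[g[value].to_numpy() for g in groups.values()])
        ctrl_mean = groups[control][value].mean()
        return pd.DataFrame(
            [
                {
                    "contrast": "one-way ANOVA (" + " vs ".join(conds) + ")",
                    "statistic": float(stat),
                    "p_value": float(p),
                    "fold_change": np.nan if ctrl_mean == 0
                    else float(fractions[value].mean() / ctrl_mean),
                }
            ]
        )

    rows = []
    ctrl = groups[control]
    for c in conds:
        if c == control:
            continue
        gr = groups[c]
        if design == "paired":
            if len(gr) != len(ctrl):
                orphans = abs(len(gr) - len(ctrl))
                raise ValueError(
                    f"paired design: {c!r} and {control!r} differ by "
                    f"{orphans} unmatched unit(s)"
                )
            d = gr[value].to_numpy() - ctrl[value].to_numpy()
            if d.std(ddof=1) == 0:
                # degenerate: identical pairs carry no evidence at all
                stat, p = 0.0, 1.0 if (d == 0).all() else np.nan
            else:
                stat, p = stats.ttest_rel(
                    gr[value].to_numpy(), ctrl[value].to_numpy()
                )
        else:
            a, b = gr[value].to_numpy(), ctrl[value].to_numpy()
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                stat, p = 0.0, 1.0 if a.mean() == b.mean() else np.nan
            else:
                stat, p = stats.ttest_ind(a, b)
        ctrl_mean = ctrl[value].mean()
        rows.append(
            {
                "contrast": f"{c} vs {control} ({design} t-test)",
                "statistic": float(stat),
                "p_value": float(p),
                "fold_change": np.nan if ctrl_mean == 0
                else float(gr[value].mean() / ctrl_mean),
            }
        )
    return pd.DataFrame(rows)


def ddct_fold_change(
    records: pd.DataFrame,
    control_condition: str,
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Reference-normalized qPCR fold change per gene and condition.

    dCt = ct(gene) - ct(reference) per sample (technical replicates are
    averaged per sample first); ddCt = mean dCt(condition) - mean
    dCt(control); fold = 2^-ddCt. The reference gene must be measured in
    every sample.
    """
    required = {"sample_id", "gene", "ct", "condition"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    per_sample = (
        records.groupby(["sample_id", "condition", "gene"], as_index=False)["ct"]
        .mean()
    )
    ref = per_sample[per_sample["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = per_sample[per_sample["gene"] != reference_gene]
    missing_ref = set(targets["sample_id"]) - set(ref.index)
    if missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for samples "
            f"{sorted(missing_ref)}"
        )
    targets = targets.assign(
        dct=targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()
    )
    mean_dct = targets.groupby(["gene", "condition"], as_index=False)["dct"].mean()
    rows = []
    for gene, sub in mean_dct.groupby("gene"):
        sub = sub.set_index("condition")["dct"]
        if control_condition not in sub.index:
            raise ValueError(
                f"gene {gene!r}: control condition {control_condition!r} missing"
            )
        for cond, dct in sub.items():
            ddct = dct - sub[control_condition]
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "ddct": float(ddct),
                    "fold_change": float(2.0 ** -ddct),
                }
            )
    return pd.DataFrame(rows)
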