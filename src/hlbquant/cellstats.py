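"""Per-embryo cell-class statistics and relative qPCR quantification.

Cells carry boolean labels (EdU incorporation, cytoplasmic FISH signal,
nascent FISH at the locus body, mitotic and fate markers); classes are
boolean expressions over those labels (e.g. ``fish & ~edu`` for cells that
accumulated histone mRNA without replicating).  Proportions are computed per
embryo and compared across genotypes with two-tailed t-test variants and
Benjamini-Hochberg FDR; the FDR family is whatever set of comparisons is
submitted in one call.

``ddct`` implements Livak relative quantification: technical replicates are
averaged, dCt = Ct_gene - Ct_reference within each (genotype, biological
replicate), ddCt = dCt - mean dCt of the control genotype, and
log2 fold change = -ddCt (fold change = 2^-ddCt).
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["class_counts", "group_test", "group_tests", "ddct"]

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_KEYWORDS = {"and", "or", "not", "True", "False"}


def class_counts(
    cells: pd.DataFrame,
    expr: str,
    denominator: str | None = None,
    group: list[str] | None = None,
) -> pd.DataFrame:
    """Per-embryo counts and proportions of a boolean cell class.

    ``expr`` (and the optional ``denominator`` class, default: all counted
    cells) is a boolean expression over label columns using ``& | ~`` or
    ``and/or/not``.  Returns one row per group with count, denominator and
    proportion in [0, 1].
    """
    group = group or ["embryo", "genotype"]
    for e in filter(None, [expr, denominator]):
        for name in set(_NAME_RE.findall(e)) - _KEYWORDS:
            if name not in cells.columns:
                raise ValueError(f"unknown label {name!r} in class expression")
    member = cells.eval(expr).astype(bool)
    denom_member = cells.eval(denominator).astype(bool) if denominator else pd.Series(True, index=cells.index)
    out = (
        pd.DataFrame({"member": member, "denom": denom_member})
        .groupby([cells[g] for g in group])
        .agg(count=("member", "sum"), denominator=("denom", "sum"))
        .reset_index()
    )
    if (out["denominator"] == 0).any():
        bad = out.loc[out["denominator"] == 0, group].to_dict("records")
        raise ValueError(f"zero denominator for groups: {bad}")
    out["proportion"] = out["count"] / out["denominator"]
    return out


def group_test(a, b, design: str = "unpaired") -> dict:
    """Two-tailed t test of the requested variant.

    design: ``unpaired`` (pooled variance), ``welch`` (unequal variances) or
    ``paired``.  A degenerate paired test (all differences equal) is
    reported as t=0, p=1 with a warning rather than failing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if design == "unpaired":
        res = _st.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif design == "welch":
        res = _st.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    elif design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires equal group lengths")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            warnings.warn("zero-variance paired differences; reporting p = 1", RuntimeWarning)
            return {"t": 0.0, "p": 1.0, "df": len(a) - 1, "design": design}
        res = _st.ttest_rel(a, b)
        df = len(a) - 1
    else:
        raise ValueError(f"unknown design {design!r}")
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": df, "design": design}


def group_tests(comparisons: list[tuple[str, np.ndarray, np.ndarray, str]]) -> pd.DataFrame:
    """Run several group tests and BH-adjust across them (the FDR family)."""
    rows = []
    for name, a, b, design in comparisons:
        res = group_test(a, b, design)
        res["comparison"] = name
        rows.append(res)
    out = pd.DataFrame(rows)[["comparison", "design", "t", "df", "p"]]
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def ddct(ct: pd.DataFrame, reference_gene: str, control_genotype: str) -> pd.DataFrame:
    """Livak ddCt quantification of a long-format Ct table.

    ``ct`` needs gene/genotype/bio_rep/ct columns (technical replicates, if
    present as extra rows, are averaged first).  Returns one row per
    (gene, genotype) with per-biological-replicate spread, mean ddCt,
    log2 fold change (-ddCt) and fold change (2^-ddCt) relative to the
    control genotype.
    """
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if control_genotype not in set(ct["genotype"]):
        raise ValueError(f"control genotype {control_genotype!r} absent from table")

    tech_avg = ct.groupby(["gene", "genotype", "bio_rep"], as_index=False)["ct"].mean()
    ref = tech_avg[tech_avg["gene"] == reference_gene][["genotype", "bio_rep", "ct"]].rename(
        columns={"ct": "ref_ct"}
    )
    merged = tech_avg.merge(ref, on=["genotype", "bio_rep"], how="left")
    if merged["ref_ct"].isna().any():
        missing = merged.loc[merged["ref_ct"].isna(), ["genotype", "bio_rep"]].drop_duplicates()
        raise ValueError(f"missing reference gene for replicates: {missing.to_dict('records')}")
    merged["dct"] = merged["ct"] - merged["ref_ct"]

    control_mean = (
        merged[merged["genotype"] == control_genotype].groupby("gene")["dct"].mean().rename("control_dct")
    )
    merged = merged.join(control_mean, on="gene")
    merged["ddct"] = merged["dct"] - merged["control_dct"]

    out = (
        merged.groupby(["gene", "genotype"], as_index=False)
        .agg(n_bio=("ddct", "size"), ddct_mean=("ddct", "mean"), ddct_sd=("ddct", "std"))
    )
    out["log2fc"] = -out["ddct_mean"]
    out["fold_change"] = 2.0 ** out["log2fc"]
    return out
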