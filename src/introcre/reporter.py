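"""Quantification of allelic regulatory activity from qPCR plate data.

Amplification efficiency E per amplicon comes from a dilution series
(least-squares slope of mean Ct against log10 relative input; E =
10^(-1/slope), so perfect doubling gives slope -1/log10(2) ~ -3.32).
Relative expression per transfection replicate is the efficiency-corrected
delta-Ct, normalised by plasmid DNA:

    expression = E ** (mean Ct_pDNA - mean Ct_cDNA)

with technical replicates collapsed by the arithmetic mean of Ct first.
The archaic / non-archaic ratio per construct and cell line is tested on
log2 scale with a one-sample t-test against 0 (paired by transfection
replicate when the design permits), BH-corrected across all constructs and
cell lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ARCHAIC, NONARCHAIC_ALLELE = "ARCHAIC", "NONARCHAIC"

__all__ = [
    "estimate_efficiency",
    "relative_expression",
    "allelic_ratio_test",
    "run_reporter_analysis",
]


def estimate_efficiency(dilutions: pd.DataFrame) -> pd.DataFrame:
    """Per-amplicon amplification efficiency from a serial-dilution series.

    ``dilutions`` columns: amplicon, log10_input (relative), ct.  Technical
    replicates at the same input are averaged before the fit.  A
    non-negative slope (Ct not increasing with dilution) raises with
    diagnostics.
    """
    rows = []
    for amplicon, grp in dilutions.groupby("amplicon", sort=True):
        means = grp.groupby("log10_input")["ct"].mean()
        if len(means) < 3:
            raise ValueError(f"{amplicon}: need >= 3 dilution points")
        fit = stats.linregress(means.index.to_numpy(), means.to_numpy())
        if fit.slope >= 0:
            raise ValueError(
                f"{amplicon}: non-monotone dilution series (slope {fit.slope:.3f}); "
                f"mean Ct by log10 input: {means.to_dict()}"
            )
        rows.append(
            {
                "amplicon": amplicon,
                "slope": fit.slope,
                "r_squared": fit.rvalue**2,
                "efficiency": 10 ** (-1.0 / fit.slope),
            }
        )
    return pd.DataFrame(rows)


def relative_expression(
    ct_table: pd.DataFrame, efficiencies: pd.DataFrame | dict
) -> pd.DataFrame:
    """pDNA-normalised expression per (construct, allele, cell line,
    transfection replicate).

    ``ct_table`` columns: construct, allele, cell_line, transfection,
    template (cDNA/pDNA), tech_rep, ct.  Constructs missing a template arm
    are skipped and reported in the ``skipped`` attribute of the result.
    """
    if isinstance(efficiencies, pd.DataFrame):
        eff = dict(zip(efficiencies["amplicon"], efficiencies["efficiency"]))
    else:
        eff = dict(efficiencies)
    mean_ct = (
        ct_table.groupby(
            ["construct", "allele", "cell_line", "transfection", "template"],
            sort=True,
        )["ct"]
        .mean()
        .unstack("template")
    )
    skipped = mean_ct[mean_ct.isna().any(axis=1)].index.to_list()
    ok = mean_ct.dropna()
    out = ok.reset_index()
    e = out["construct"].map(eff)
    if e.isna().any():
        missing = sorted(out.loc[e.isna(), "construct"].unique())
        raise KeyError(f"no efficiency estimate for amplicons {missing}")
    out["expression"] = e ** (out["pDNA"] - out["cDNA"])
    out = out[["construct", "allele", "cell_line", "transfection", "expression"]]
    out.attrs["skipped"] = skipped
    return out


def allelic_ratio_test(expression: pd.DataFrame) -> pd.DataFrame:
    """Archaic / non-archaic expression ratio per (construct, cell line).

    The ratio is the geometric-mean ratio; the test is a one-sample t-test
    of per-replicate log2 ratios against 0 when replicates pair up, else an
    unpaired two-sample t-test on log2 expressions (flagged in ``paired``).
    q-values are BH-adjusted across all constructs and cell lines in the
    run.
    """
    from .enrich import bh_adjust

    rows = []
    for (construct, cell_line), grp in expression.groupby(
        ["construct", "cell_line"], sort=True
    ):
        arch = grp[grp["allele"] == ARCHAIC].set_index("transfection")["expression"]
        non = grp[grp["allele"] == NONARCHAIC_ALLELE].set_index("transfection")[
            "expression"
        ]
        if len(arch) < 2 or len(non) < 2:
            continue
        ratio = float(
            np.exp(np.mean(np.log(arch.to_numpy())) - np.mean(np.log(non.to_numpy())))
        )
        paired = arch.index.sort_values().equals(non.index.sort_values())
        if paired:
            logr = np.log2(arch.sort_index().to_numpy()) - np.log2(
                non.sort_index().to_numpy()
            )
            if np.allclose(logr, logr[0]):
                # zero variance: the t statistic is undefined off the null
                p = 1.0 if np.allclose(logr, 0) else np.nan
            else:
                p = float(stats.ttest_1samp(logr, 0.0).pvalue)
        else:
            p = float(
                stats.ttest_ind(
                    np.log2(arch.to_numpy()), np.log2(non.to_numpy())
                ).pvalue
            )
        rows.append(
            {
                "construct": construct,
                "cell_line": cell_line,
                "ratio": ratio,
                "n_archaic": len(arch),
                "n_nonarchaic": len(non),
                "paired": paired,
                "p": p,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def run_reporter_analysis(
    ct_table: pd.DataFrame, dilutions: pd.DataFrame
) -> pd.DataFrame:
    """Dilution fit, expression computation and allelic ratio tests in one go."""
    eff = estimate_efficiency(dilutions)
    expr = relative_expression(ct_table, eff)
    return allelic_ratio_test(expr)
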