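"""Simulate qPCR plates for the allelic reporter assay.

Ct values follow the standard amplification model

    Ct = intercept - log_E(quantity) + Gaussian noise

with a per-amplicon efficiency E.  The cDNA quantity of a construct/allele
is its plasmid quantity times its expression level; archaic-allele
expression is the non-archaic level times the configured true fold change,
so with zero noise the downstream allelic ratio recovers the fold change
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..reporter import ARCHAIC, NONARCHAIC_ALLELE
from .config import ReporterConfig


@dataclass
class ReporterPlateData:
    dilutions: pd.DataFrame
    ct_table: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        from .. import io

        outdir = Path(outdir)
        (outdir / "reporter").mkdir(parents=True, exist_ok=True)
        io.write_table(self.dilutions, outdir / "reporter" / "dilutions.tsv")
        io.write_table(self.ct_table, outdir / "reporter" / "ct_table.tsv")
        io.write_table(self.truth, outdir / "reporter" / "truth.tsv")


def simulate_reporter_plate(config: ReporterConfig) -> ReporterPlateData:
    rng = np.random.default_rng(config.seed)

    def noise() -> float:
        return float(rng.normal(0, config.noise_sd)) if config.noise_sd > 0 else 0.0

    dil_rows = []
    ct_rows = []
    truth_rows = []
    for construct in config.constructs:
        e = config.efficiency_of(construct)
        log_e = math.log(e)
        intercept = float(rng.uniform(18, 25))
        fold = config.fold_changes.get(construct, 1.0)
        truth_rows.append({"construct": construct, "fold_change": fold, "efficiency": e})

        # dilution series: 1:10 steps from undiluted cDNA
        for d in range(config.n_dilutions):
            log10_input = -float(d)
            for tech in range(config.n_technical_reps):
                ct = intercept - (log10_input * math.log(10)) / log_e + noise()
                dil_rows.append(
                    {
                        "amplicon": construct,
                        "log10_input": log10_input,
                        "tech_rep": tech,
                        "ct": round(ct, 6),
                    }
                )

        base_expr = float(rng.lognormal(0.0, 0.25))
        for cell_line in config.cell_lines:
            for trans in range(config.n_transfection_reps):
                q_pdna = float(rng.lognormal(0.0, 0.2))
                for allele in (ARCHAIC, NONARCHAIC_ALLELE):
                    expr = base_expr * (fold if allele == ARCHAIC else 1.0)
                    for template, q in (("pDNA", q_pdna), ("cDNA", q_pdna * expr)):
                        for tech in range(config.n_technical_reps):
                            ct = intercept - math.log(q) / log_e + noise()
                            ct_rows.append(
                                {
                                    "construct": construct,
                                    "allele": allele,
                                    "cell_line": cell_line,
                                    "transfection": trans,
                                    "template": template,
                                    "tech_rep": tech,
                                    "ct": round(ct, 6),
                                }
                            )
    return ReporterPlateData(
        dilutions=pd.DataFrame(dil_rows),
        ct_table=pd.DataFrame(ct_rows),
        truth=pd.DataFrame(truth_rows),
    )
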