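import numpy as np
import pandas as pd
import pytest

from introcre import variantfilter as vf
from introcre.synthdata import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def messy_cohort():
    """Small cohort exercising every exclusion path (leaks, missing
    ancestral calls, ancestral mismatches)."""
    cfg = CohortConfig(
        n_individuals=20,
        n_sites=300,
        chrom_length=2_000_000,
        archaic_site_fraction=0.3,
        outgroup_leak_rate=0.08,
        archaic_background_leak=0.15,
        ancestral_missing_rate=0.04,
        ancestral_mismatch_rate=0.02,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def messy_calls(messy_cohort):
    vs = vf.from_cohort(messy_cohort)
    calls, ledger = vf.run_filter_cascade(
        vs, messy_cohort.ancestral, messy_cohort.altai, messy_cohort.outgroup
    )
    return calls, ledger


@pytest.fixture(scope="session")
def clean_cohort():
    """Leak-free cohort for classification-accuracy checks."""
    cfg = CohortConfig(
        n_individuals=28, n_sites=800, chrom_length=4_000_000, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_calls(clean_cohort):
    vs = vf.from_cohort(clean_cohort)
    return vf.run_filter_cascade(
        vs, clean_cohort.ancestral, clean_cohort.altai, clean_cohort.outgroup
    )


def make_variant_set(geno, context, ref=None, alt=None, positions=None, chrom="1"):
    """Hand-rolled VariantSet for targeted unit tests."""
    geno = np.asarray(geno, dtype=np.int8)
    context = np.asarray(context, dtype=np.int8)
    n = geno.shape[0]
    return vf.VariantSet(
        chrom=chrom,
        positions=np.asarray(positions if positions is not None else np.arange(1, n + 1)),
        ref=np.asarray(ref if ref is not None else ["A"] * n),
        alt=np.asarray(alt if alt is not None else ["G"] * n),
        geno=geno,
        context=context,
        multiallelic=np.zeros(n, dtype=bool),
    )


def ancestral_table(vs, alleles=None):
    return pd.DataFrame(
        {
            "chrom": vs.chrom,
            "pos": vs.positions,
            "allele": alleles if alleles is not None else vs.ref,
        }
    )
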