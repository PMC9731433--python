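"""Simulate a motif library, a background genome and planted allelic
TFBS disruptions with known delta-PWM sign.

Planted SNPs sit inside an embedded consensus instance of a sharp motif:
the strong allele is the consensus base at the SNP column (so that allele
matches the motif at any reasonable p-value threshold) and the weak allele
is the column's least-preferred base.  Whether the introgressed allele is
the weak one (negative expected delta) or the strong one (positive) is
drawn per site and recorded as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..motifimpact import BASES, MotifModel, reverse_complement
from .config import MotifConfig


@dataclass
class MotifData:
    models: list
    counts: dict = field(repr=False)  # raw count matrices by motif name
    clusters: pd.DataFrame = None
    genome: str = ""
    snps: pd.DataFrame = None
    chrom: str = "syn1"

    def write(self, outdir) -> None:
        from pathlib import Path

        from .. import io
        from ..motifimpact import write_pfm

        outdir = Path(outdir)
        for m in self.models:
            d = outdir / "pfms" / m.source_db
            d.mkdir(parents=True, exist_ok=True)
            write_pfm(self.counts[m.name], m.name, m.tf_name, d / f"{m.name}.jaspar")
        io.write_table(self.clusters, outdir / "clusters.tsv")
        io.write_fasta({self.chrom: self.genome}, outdir / "genome.fa")
        io.write_table(self.snps, outdir / "snps.tsv")


def _random_counts(width: int, sharpness: float, rng: np.random.Generator) -> np.ndarray:
    counts = np.ones((4, width))
    consensus = rng.integers(0, 4, size=width)
    soft = rng.random(width) < 0.2  # a few degenerate columns
    for i in range(width):
        if soft[i]:
            counts[:, i] = rng.integers(5, 15, size=4)
        counts[consensus[i], i] = sharpness
    return counts


def _consensus(counts: np.ndarray) -> str:
    return "".join(BASES[i] for i in counts.argmax(axis=0))


def simulate_motif_data(config: MotifConfig) -> MotifData:
    rng = np.random.default_rng(config.seed)
    bg = np.array([config.background[b] for b in BASES])

    models: list[MotifModel] = []
    counts_by_name: dict[str, np.ndarray] = {}
    cluster_rows = []
    for i in range(config.n_motifs):
        tf = f"TF{i + 1:02d}"
        cluster = f"C{i % 4 + 1}"
        width = int(rng.integers(config.width_range[0], config.width_range[1] + 1))
        while True:
            counts = _random_counts(width, config.sharpness, rng)
            cons = _consensus(counts)
            if cons != reverse_complement(cons):  # avoid palindromes
                break
        dbs = ["JASPAR"] if i % 2 == 0 else ["HOCOMOCO"]
        if i < config.n_duplicated_tfs:
            dbs = ["JASPAR", "HOCOMOCO"]
        for db in dbs:
            name = f"{'MA' if db == 'JASPAR' else 'HC'}{i + 1:04d}.1"
            c = counts.copy()
            if db == dbs[-1] and len(dbs) > 1:
                c = c + rng.integers(0, 3, size=c.shape)  # slightly different version
            models.append(
                MotifModel.from_counts(name, tf, db, c, background=config.background)
            )
            counts_by_name[name] = c
            cluster_rows.append({"motif": name, "tf_name": tf, "cluster": cluster})
    clusters = pd.DataFrame(cluster_rows)

    genome = list(rng.choice(list(BASES), size=config.genome_length, p=bg))

    # planted disruptions, spaced so embedded instances never overlap
    snp_rows = []
    slots = np.linspace(
        100, config.genome_length - 100, max(config.n_planted + config.n_neutral_snps, 1)
    ).astype(int)
    primaries = [m for m in models if m.source_db == "JASPAR" or m.tf_name not in {
        x.tf_name for x in models if x.source_db == "JASPAR"
    }]
    for j in range(config.n_planted):
        model = primaries[int(rng.integers(len(primaries)))]
        counts = counts_by_name[model.name]
        w = model.width
        sharp_cols = np.flatnonzero(counts.max(axis=0) >= config.sharpness)
        col = int(rng.choice(sharp_cols if len(sharp_cols) else np.arange(w)))
        cons = _consensus(counts)
        start = int(slots[j]) - col  # SNP lands on column `col`
        genome[start : start + w] = list(cons)
        pos = start + col + 1  # 1-based
        strong = cons[col]
        weak = BASES[int(counts[:, col].argmin())]
        intro_is_weak = bool(rng.random() < 0.5)
        intro, other = (weak, strong) if intro_is_weak else (strong, weak)
        snp_rows.append(
            {
                "variant_id": f"syn1:{pos}",
                "pos": pos,
                "ref": strong,
                "alt": weak,
                "introgressed_allele": intro,
                "other_allele": other,
                "motif": model.name,
                "tf_name": model.tf_name,
                "expected_sign": -1 if intro_is_weak else 1,
                "planted": True,
            }
        )
    for j in range(config.n_neutral_snps):
        pos = int(slots[config.n_planted + j]) + 1
        ref = genome[pos - 1]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        snp_rows.append(
            {
                "variant_id": f"syn1:{pos}",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "introgressed_allele": alt,
                "other_allele": ref,
                "motif": "",
                "tf_name": "",
                "expected_sign": 0,
                "planted": False,
            }
        )
    snps = pd.DataFrame(snp_rows)
    return MotifData(
        models=models,
        counts=counts_by_name,
        clusters=clusters,
        genome="".join(genome),
        snps=snps,
    )
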