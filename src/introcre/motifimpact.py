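"""Allelic impact of variants on transcription-factor binding motifs.

A motif is a 4 x w probability matrix; windows are scored as the sum of
log2 probability ratios against a fixed background (A/T 0.3, G/C 0.2).
A window "matches" when its score exceeds the motif's exact p-value
threshold, computed by dynamic programming over the discretised score
distribution under the background model.  For each (variant, motif) pair we
take the best-scoring window over all offsets covering the variant and both
strands, independently per allele, and report the allelic score difference
polarised by the introgressed (or derived) allele:

    delta_pwm = score(introgressed or derived) - score(other allele)

so a negative delta means the introgressed/derived allele weakens the motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")
DEFAULT_BACKGROUND = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
PROB_FLOOR = 1e-4


@dataclass
class MotifModel:
    """A position probability matrix with its scoring background."""

    name: str
    tf_name: str
    source_db: str
    matrix: np.ndarray  # (4, width) probabilities, rows in ACGT order
    background: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.2, 0.2, 0.3])
    )

    def __post_init__(self) -> None:
        self.matrix = regularize(self.matrix)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    @classmethod
    def from_counts(
        cls, name, tf_name, source_db, counts, pseudocount: float = 1.0, background=None
    ) -> "MotifModel":
        counts = np.asarray(counts, dtype=float)
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {name}: column with non-positive total")
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        bg = (
            np.array([background[b] for b in BASES])
            if background
            else np.array([0.3, 0.2, 0.2, 0.3])
        )
        return cls(name, tf_name, source_db, probs, bg)


def regularize(matrix: np.ndarray) -> np.ndarray:
    """Floor probabilities at 1e-4 and renormalise each column."""
    m = np.maximum(np.asarray(matrix, dtype=float), PROB_FLOOR)
    return m / m.sum(axis=0)


# ---------------------------------------------------------------------------
# JASPAR-dialect I/O


def load_pfms(path_or_dir, source_db: str, background=None) -> list[MotifModel]:
    """Read JASPAR-dialect count matrices (via Biopython) into models."""
    from Bio import motifs as bio_motifs

    paths = (
        sorted(Path(path_or_dir).glob("*.jaspar"))
        if Path(path_or_dir).is_dir()
        else [Path(path_or_dir)]
    )
    models = []
    for p in paths:
        with open(p) as fh:
            for m in bio_motifs.parse(fh, "jaspar"):
                counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
                models.append(
                    MotifModel.from_counts(
                        m.matrix_id or p.stem,
                        m.name or p.stem,
                        source_db,
                        counts,
                        background=background,
                    )
                )
    return models


def write_pfm(counts: np.ndarray, name: str, tf_name: str, path) -> None:
    """Write one count matrix in the JASPAR text dialect."""
    with open(path, "w") as fh:
        fh.write(f">{name} {tf_name}\n")
        for b, row in zip(BASES, np.asarray(counts)):
            vals = " ".join(f"{v:.0f}" for v in row)
            fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# scoring


def pwm_score(window: str, motif: MotifModel) -> float:
    """Log-odds score of one window (must equal the motif width)."""
    if len(window) != motif.width:
        raise ValueError("window length must equal motif width")
    lo = motif.log_odds
    try:
        return float(sum(lo[BASE_INDEX[b], i] for i, b in enumerate(window)))
    except KeyError as e:
        raise AmbiguousBaseError(f"ambiguous base {e} in window") from None


class AmbiguousBaseError(ValueError):
    pass


def score_distribution(motif: MotifModel, n_bins: int = 10_000):
    """Exact distribution of the window score under the background model,
    discretised onto ``n_bins`` bins spanning the attainable score range.

    Returns ``(scores, pmf)`` with ``pmf`` summing to 1."""
    lo = motif.log_odds
    span = float(lo.max(axis=0).sum() - lo.min(axis=0).sum())
    width_b = span / n_bins if span > 0 else 1.0
    k = np.round(lo / width_b).astype(np.int64)  # (4, w) integer scores
    kmin = k.min(axis=0)
    kmax = k.max(axis=0)
    dist = np.zeros(int((kmax - kmin).sum()) + 1)
    dist[0] = 1.0
    cur_len = 1
    bg = motif.background
    for i in range(motif.width):
        new = np.zeros(cur_len + int(kmax[i] - kmin[i]))
        for b in range(4):
            off = int(k[b, i] - kmin[i])
            new[off : off + cur_len] += bg[b] * dist[:cur_len]
        dist = new
        cur_len = len(new)
    offset = int(kmin.sum())
    scores = (np.arange(cur_len) + offset) * width_b
    return scores, dist


def match_threshold(motif: MotifModel, pvalue: float = 1e-5, n_bins: int = 10_000) -> float:
    """Smallest score s with P(score >= s | background) <= pvalue."""
    if not (0.0 < pvalue <= 1.0):
        raise ValueError("pvalue must lie in (0, 1]")
    scores, pmf = score_distribution(motif, n_bins)
    tail = np.cumsum(pmf[::-1])[::-1]
    ok = np.flatnonzero(tail <= pvalue)
    if len(ok) == 0:
        return float(scores[-1]) + 1e-9  # no attainable score is that rare
    return float(scores[ok[0]])


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def score_snp(
    sequence: str,
    pos: int,
    allele_focal: str,
    allele_other: str,
    motif: MotifModel,
    threshold: float,
    variant_id: str | None = None,
    ancestry: str = "",
    effect_threshold: float = 0.0,
) -> dict | None:
    """Best-window allelic scores for one SNP against one motif.

    ``pos`` is 1-based on ``sequence``; the focal allele is the introgressed
    (aSNP) or derived (naSNP) allele.  Each allele independently takes its
    best score over all windows covering the SNP on both strands.  A record
    is returned only when at least one allele passes ``threshold``.
    """
    w = motif.width
    p0 = pos - 1
    if not (0 <= p0 < len(sequence)):
        raise ValueError("variant outside the sequence")
    best: dict[str, tuple] = {}
    for allele in (allele_focal, allele_other):
        seq = sequence[:p0] + allele + sequence[p0 + 1 :]
        top = (-math.inf, -1, "+")
        for s0 in range(max(0, p0 - w + 1), min(len(seq) - w, p0) + 1):
            window = seq[s0 : s0 + w]
            for strand, win in (("+", window), ("-", reverse_complement(window))):
                try:
                    s = pwm_score(win, motif)
                except AmbiguousBaseError:
                    continue
                if s > top[0]:
                    top = (s, s0, strand)
        if not math.isfinite(top[0]):
            return None  # no valid window (e.g. all ambiguous)
        best[allele] = top
    s_focal, off_f, strand_f = best[allele_focal]
    s_other, off_o, strand_o = best[allele_other]
    if max(s_focal, s_other) < threshold:
        return None
    delta = s_focal - s_other
    return {
        "variant_id": variant_id or f"pos{pos}",
        "ancestry": ancestry,
        "tf_name": motif.tf_name,
        "motif": motif.name,
        "source_db": motif.source_db,
        "score_focal": s_focal,
        "score_other": s_other,
        "offset_focal": off_f,
        "strand_focal": strand_f,
        "offset_other": off_o,
        "strand_other": strand_o,
        "delta_pwm": delta,
        "is_disrupting": abs(delta) > effect_threshold,
    }


# ---------------------------------------------------------------------------
# record-level operations


def consolidate(records: pd.DataFrame, db_priority=("JASPAR", "HOCOMOCO")) -> pd.DataFrame:
    """One record per (variant, TF): the association with the largest
    absolute delta; ties broken by database priority, then motif name."""
    if records.empty:
        return records.copy()
    rank = {db: i for i, db in enumerate(db_priority)}
    df = records.copy()
    df["_absd"] = df["delta_pwm"].abs()
    df["_dbrank"] = df["source_db"].map(lambda d: rank.get(d, len(rank)))
    df = df.sort_values(
        ["variant_id", "tf_name", "_absd", "_dbrank", "motif"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    out = df.drop_duplicates(subset=["variant_id", "tf_name"], keep="first")
    return out.drop(columns=["_absd", "_dbrank"]).reset_index(drop=True)


def cluster_excess_test(
    records_case: pd.DataFrame,
    records_control: pd.DataFrame,
    clusters: dict | pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 10_000,
):
    """Chi-square test for an excess of TFBS-disrupting case variants in any
    motif cluster, against controls.

    Records whose motif has no cluster assignment are dropped (mirroring the
    removal of unclustered PWMs).  When more than 20% of expected counts
    fall below 5, the global p-value is replaced by a seeded Monte-Carlo
    permutation p (fixed margins).  Also returns per-cluster 2x2 chi-square
    tests with BH correction.
    """
    from .enrich import bh_adjust

    if isinstance(clusters, pd.DataFrame):
        clusters = dict(zip(clusters["motif"], clusters["cluster"]))

    def cluster_counts(records: pd.DataFrame) -> pd.Series:
        df = records[records["is_disrupting"]].copy()
        df["cluster"] = df["motif"].map(clusters)
        df = df.dropna(subset=["cluster"])
        return df.groupby("cluster").size()

    case = cluster_counts(records_case)
    ctrl = cluster_counts(records_control)
    table = pd.DataFrame({"case": case, "control": ctrl}).fillna(0).astype(int)
    table = table[(table.sum(axis=1) > 0)]
    if len(table) < 2:
        raise ValueError("cluster excess test needs at least 2 occupied clusters")
    obs = table.to_numpy()
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    method = "chi2"
    if (expected < 5).mean() > 0.20:
        method = "monte_carlo"
        p = _permutation_p(obs, chi2, seed, n_permutations)

    rows = []
    tot_case, tot_ctrl = obs[:, 0].sum(), obs[:, 1].sum()
    for cl, (a, c) in zip(table.index, obs):
        t = np.array([[a, tot_case - a], [c, tot_ctrl - c]])
        if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
            pc = np.nan
        else:
            pc = stats.chi2_contingency(t, correction=False)[1]
        rows.append({"cluster": cl, "case": int(a), "control": int(c), "p": pc})
    per_cluster = pd.DataFrame(rows)
    per_cluster["q"] = bh_adjust(per_cluster["p"].to_numpy())
    return {"statistic": chi2, "p": p, "dof": dof, "method": method, "table": table,
            "per_cluster": per_cluster}


def _permutation_p(obs: np.ndarray, stat_obs: float, seed: int, n_perm: int) -> float:
    rng = np.random.default_rng(seed)
    row_tot = obs.sum(axis=1)
    n_case = int(obs[:, 0].sum())
    n_tot = int(obs.sum())
    hits = 0
    for _ in range(n_perm):
        a = rng.multivariate_hypergeometric(row_tot, n_case)
        sim = np.column_stack([a, row_tot - a])
        exp = np.outer(row_tot, [n_case, n_tot - n_case]) / n_tot
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.nansum((sim - exp) ** 2 / exp)
        if s >= stat_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def compare_delta_distributions(records_a: pd.DataFrame, records_b: pd.DataFrame) -> float:
    """Two-sided Wilcoxon rank-sum p for a shift between two delta-PWM
    distributions (normal approximation with tie correction)."""
    a = records_a["delta_pwm"].to_numpy(dtype=float)
    b = records_b["delta_pwm"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both record sets must be non-empty")
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )
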