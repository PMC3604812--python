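"""tRNA adaptation index (tAI) and cross-species translational-efficiency comparison.

The tAI of a gene is the geometric mean, over its codons, of per-codon
relative adaptiveness values w.  A codon's absolute adaptiveness is

    W_c = sum_j (1 - s_cj) * tGCN_j

over the tRNA anticodons j that can decode codon c, where tGCN_j is
the genomic copy number of the anticodon and s_cj the selective
penalty of the codon:anticodon pairing at the wobble (third) position.
Watson-Crick pairings carry s = 0; non-WC wobble pairings carry the
standard penalties (G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68,
lysidine-modified C reading AUA 0.89).  w_c = W_c / max W; codons with
W = 0 receive the geometric mean of the nonzero w values so that an
undecodable codon does not zero out a whole gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

SENSE_CODONS = tuple(sorted(GENETIC_CODE))

# (codon 3rd base, anticodon 1st base) -> selective penalty s.
# WC rows are explicit so the rule table is self-contained.
DEFAULT_WOBBLE: dict[tuple[str, str], float] = {
    ("T", "A"): 0.0,     # A:U Watson-Crick
    ("C", "G"): 0.0,     # G:C Watson-Crick
    ("A", "T"): 0.0,     # U:A Watson-Crick
    ("G", "C"): 0.0,     # C:G Watson-Crick
    ("T", "G"): 0.41,    # G:U wobble
    ("C", "A"): 0.28,    # I:C (inosine at 34)
    ("A", "A"): 0.9999,  # I:A
    ("G", "T"): 0.68,    # U:G wobble
}

# lysidine-modified CAU anticodon reads AUA (Ile) in addition to AUG
LYSIDINE_S = 0.89


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def wc_anticodon(codon: str) -> str:
    """The Watson-Crick anticodon (5'->3') of a codon."""
    return reverse_complement(codon)


def _recognizers(
    codon: str, rules: Mapping[tuple[str, str], float]
) -> list[tuple[str, float]]:
    """Anticodons able to decode ``codon`` with their penalties.

    Wobble pairings are only admitted when the wobble anticodon's own
    WC codon encodes the same amino acid, so decoding never crosses
    amino-acid families; the lysidine rule for AUA is the exception.
    """
    aa = GENETIC_CODE[codon]
    stem = reverse_complement(codon[:2])  # anticodon positions 2-3
    out = []
    for (third, ac_first), s in rules.items():
        if third != codon[2]:
            continue
        anticodon = ac_first + stem
        wc_codon = reverse_complement(anticodon)
        if wc_codon != codon:  # a wobble pairing
            if wc_codon in STOP_CODONS or GENETIC_CODE.get(wc_codon) != aa:
                continue
        out.append((anticodon, s))
    if codon == "ATA":
        out.append(("CAT", LYSIDINE_S))
    return out


def absolute_adaptiveness(
    codon: str,
    pool: Mapping[str, int],
    rules: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """W of a sense codon given a tRNA pool (anticodon -> gene copy number)."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no adaptiveness")
    if codon not in GENETIC_CODE:
        raise ValueError(f"invalid codon {codon!r}")
    rules = DEFAULT_WOBBLE if rules is None else rules
    return sum((1.0 - s) * pool.get(ac, 0) for ac, s in _recognizers(codon, rules))


def relative_adaptiveness(
    pool: Mapping[str, int],
    rules: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, float]:
    """Per-codon w for all sense codons; zero-W codons get the geometric
    mean of the nonzero w values."""
    W = {c: absolute_adaptiveness(c, pool, rules) for c in SENSE_CODONS}
    w_max = max(W.values())
    if w_max == 0:
        raise ValueError("tRNA pool decodes no codon")
    w = {c: v / w_max for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    return {c: (v if v > 0 else gm) for c, v in w.items()}


def gene_tai(sequence: str, w: Mapping[str, float]) -> float:
    """tAI of one coding sequence: geometric mean of codon w values.

    A single terminal stop codon is excluded; an internal stop is an
    error.
    """
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no sense codons in sequence")
    log_sum = 0.0
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"premature stop codon at codon {i}")
        if c not in GENETIC_CODE:
            raise ValueError(f"invalid codon {c!r} at codon {i}")
        log_sum += math.log(w[c])
    return math.exp(log_sum / len(codons))


@dataclass
class TAIProfile:
    """tRNA pool plus derived per-codon adaptiveness and per-gene tAI."""

    pool: dict[str, int]
    w: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.w = relative_adaptiveness(self.pool)

    def tai(self, sequence: str) -> float:
        return gene_tai(sequence, self.w)

    def tai_table(self, sequences: Mapping[str, str]) -> dict[str, float]:
        return {name: self.tai(seq) for name, seq in sequences.items()}


def _exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of splits."""
    pooled = list(a) + list(b)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    obs = float(sum(ranks[: len(a)]))
    total = 0
    at_least = 0
    mean_r = sum(ranks) * len(a) / n
    for idx in combinations(range(n), len(a)):
        r = float(sum(ranks[i] for i in idx))
        total += 1
        if abs(r - mean_r) >= abs(obs - mean_r) - 1e-12:
            at_least += 1
    return at_least / total


def family_tai_compare(
    tai_a: Sequence[float], tai_b: Sequence[float]
) -> tuple[float, float, int]:
    """Wilcoxon rank-sum comparison of tAI values between two species.

    Exact null by enumeration for combined n <= 20, otherwise normal
    approximation with continuity correction.  Returns (U statistic
    for sample A, two-sided p, direction) where direction is the sign
    of median(A) - median(B).
    """
    a = np.asarray(tai_a, dtype=float)
    b = np.asarray(tai_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    if a.size + b.size <= 20:
        p = _exact_ranksum_p(a, b)
    else:
        p = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    diff = float(np.median(a) - np.median(b))
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return u, min(p, 1.0), direction


def genome_tai_density(
    tai_a: Sequence[float],
    tai_b: Sequence[float],
    grid_size: int = 64,
) -> dict:
    """2-D kernel density of ortholog-paired tAI values plus marginals.

    Returns the density grid (integrating to ~1 over the unit square),
    per-species means and quartiles, and the fraction of pairs where
    species B exceeds species A.
    """
    a = np.asarray(tai_a, dtype=float)
    b = np.asarray(tai_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired tAI vectors must have equal length")
    data = np.vstack([a, b])
    try:
        kde = stats.gaussian_kde(data)
    except np.linalg.LinAlgError:
        # perfectly correlated pairs give a singular covariance; a tiny
        # deterministic jitter turns the ridge into a usable density
        jitter = 1e-6 * np.cos(np.arange(2 * a.size)).reshape(2, a.size)
        kde = stats.gaussian_kde(data + jitter)
    axis = np.linspace(0.0, 1.0, grid_size)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    density = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
    q = [0.25, 0.5, 0.75]
    return {
        "grid": axis,
        "density": density,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "quartiles_a": np.quantile(a, q).tolist(),
        "quartiles_b": np.quantile(b, q).tolist(),
        "fraction_b_higher": float(np.mean(b > a)),
    }


def read_trna_pool(path) -> dict[str, int]:
    """Read a tRNA pool TSV (anticodon <TAB> copy number)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["anticodon", "copies"], comment="#")
    pool = dict(zip(df["anticodon"].str.upper(), df["copies"].astype(int)))
    if not any(v > 0 for v in pool.values()):
        raise ValueError("tRNA pool has no nonzero copy numbers")
    return pool
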