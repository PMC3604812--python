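"""Assembly contiguity and quality statistics.

Scaffold-level summaries of a draft genome: contig splitting at N-gap
runs, N50/L50, cumulative size tables over length thresholds, gap
fraction, and alignment discrepancy rate.

Nomenclature: N50 here is the smallest *count* of scaffolds whose
summed length reaches half the assembly span; L50 is the *length* of
the scaffold at that point.  Usage in the literature is inconsistent;
this convention is fixed once and used everywhere in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ContiguityStats:
    """N50 count, L50 length and span totals for a scaffold set."""

    n50_count: int
    l50_length: int
    scaffold_span: int
    contig_span: int
    gap_pct: float


_NON_N = re.compile(r"[^Nn]+")


def split_contigs(sequence: str, min_gap_run: int = 10) -> list[tuple[int, int]]:
    """Split a scaffold into contig intervals at long N runs.

    Contigs are maximal runs of non-N sequence after merging across N
    runs shorter than ``min_gap_run``.  Returns 0-based half-open
    intervals, sorted and non-overlapping.
    """
    if min_gap_run < 1:
        raise ValueError("min_gap_run must be >= 1")
    if not sequence:
        return []
    raw = [(m.start(), m.end()) for m in _NON_N.finditer(sequence)]
    if not raw:
        return []
    merged: list[list[int]] = [list(raw[0])]
    for start, end in raw[1:]:
        if start - merged[-1][1] < min_gap_run:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def nl50(lengths: Sequence[int]) -> tuple[int, int]:
    """Return (n50_count, l50_length) for a set of sequence lengths.

    Lengths are sorted descending; n50_count is the smallest k whose
    cumulative sum reaches half the total; l50_length is the k-th
    length in that order.
    """
    if len(lengths) == 0:
        raise ValueError("nl50 of an empty length set is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for k, length in enumerate(ordered, start=1):
        acc += length
        if acc >= half:
            return k, length
    raise AssertionError("unreachable")


def _n_count(sequence: str) -> int:
    return sequence.count("N") + sequence.count("n")


def cumulative_size_table(
    scaffolds: Mapping[str, str],
    thresholds: Sequence[int],
    min_gap_run: int = 10,
) -> pd.DataFrame:
    """Tabulate scaffold/contig counts and spans at descending size cutoffs.

    Each row aggregates scaffolds of length >= threshold: number of
    scaffolds, number of contigs (split at N runs of ``min_gap_run``),
    total span, non-gap bp and percent non-gap (2 decimals,
    round-half-even).
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be sorted descending")
    lengths = {name: len(seq) for name, seq in scaffolds.items()}
    rows = []
    for thr in thresholds:
        names = [n for n, ln in lengths.items() if ln >= thr]
        span = sum(lengths[n] for n in names)
        n_contigs = sum(len(split_contigs(scaffolds[n], min_gap_run)) for n in names)
        nongap = sum(lengths[n] - _n_count(scaffolds[n]) for n in names)
        pct = nongap_percentage(nongap, span) if span else 0.0
        rows.append(
            {
                "threshold": thr,
                "n_scaffolds": len(names),
                "n_contigs": n_contigs,
                "span_bp": span,
                "nongap_bp": nongap,
                "pct_nongap": pct,
            }
        )
    return pd.DataFrame(rows)


def nongap_percentage(nongap_bp: int, span_bp: int) -> float:
    """Percent non-gap bases of a span, to 2 decimals (round-half-even)."""
    if span_bp <= 0:
        raise ValueError("span must be positive")
    return round(100.0 * nongap_bp / span_bp, 2)


def gap_fraction(scaffold_span: float, contig_span: float) -> float:
    """Percent of the scaffold span that is gap, to 1 decimal."""
    if scaffold_span <= 0:
        raise ValueError("scaffold span must be positive")
    if contig_span > scaffold_span:
        raise ValueError("contig span cannot exceed scaffold span")
    return round(100.0 * (scaffold_span - contig_span) / scaffold_span, 1)


def discrepancy_rate(discrepant_bp: int, total_bp: int) -> float:
    """Percent of aligned bases that disagree, to 2 decimals."""
    if total_bp <= 0:
        raise ValueError("total aligned bp must be positive")
    if discrepant_bp > total_bp:
        raise ValueError("discrepant bp cannot exceed total")
    return round(100.0 * discrepant_bp / total_bp, 2)


def contiguity_stats(
    scaffolds: Mapping[str, str], min_gap_run: int = 10
) -> ContiguityStats:
    """Full contiguity summary of a scaffold set."""
    lengths = [len(s) for s in scaffolds.values()]
    n50, l50 = nl50(lengths)
    span = sum(lengths)
    contig_span = sum(
        e - s
        for seq in scaffolds.values()
        for s, e in split_contigs(seq, min_gap_run)
    )
    return ContiguityStats(n50, l50, span, contig_span, gap_fraction(span, contig_span))


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
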