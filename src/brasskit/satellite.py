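"""Tandem satellite detection, period estimation and terminal classification.

Centromeric satellites (the CentO class, ~177 bp AT-rich units in
crucifers) occur as long tandem arrays.  In a fragmented assembly such
arrays sit at the scaffold terminus that faced the centromere, so the
side of a scaffold carrying a satellite array is orientation evidence
for chromosome construction.

Period estimation is by base-match autocorrelation: for a candidate
period p, the score is the fraction of positions i in the window with
base(i) == base(i + p) ('N' never matches).  The best period is the
argmax, with the smallest period winning among scores within a small
tolerance of the best so that harmonics (2p, 3p, ...) are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np




@dataclass(frozen=True)
class SatelliteParams:
    min_period: int = 50
    max_period: int = 500
    match_threshold: float = 0.8
    harmonic_tolerance: float = 0.01
    min_copies: float = 3.0


@dataclass(frozen=True)
class SatelliteArray:
    scaffold: str
    start: int
    end: int
    period: int
    copies: float
    consensus: str
    at_fraction: float

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_N_CODE = ord("N")


def _period_scores(window: np.ndarray, min_period: int, max_period: int) -> np.ndarray:
    scores = np.zeros(max_period - min_period + 1)
    valid = window != _N_CODE
    for k, p in enumerate(range(min_period, max_period + 1)):
        a, b = window[:-p], window[p:]
        ok = valid[:-p] & valid[p:]
        n = int(ok.sum())
        scores[k] = float(((a == b) & ok).sum()) / n if n else 0.0
    return scores


def estimate_period(
    window: str | np.ndarray,
    min_period: int,
    max_period: int,
    match_threshold: float = 0.8,
    harmonic_tolerance: float = 0.01,
) -> int | None:
    """Best tandem period of a window, or None if aperiodic.

    The window must be at least 3x the maximum candidate period so that
    every candidate is supported by at least two full repeat copies.
    """
    win = _encode(window) if isinstance(window, str) else window
    if len(win) < 3 * max_period:
        raise ValueError("window must be at least 3x max_period long")
    scores = _period_scores(win, min_period, max_period)
    best = float(scores.max())
    if best < match_threshold:
        return None
    near = np.flatnonzero(scores >= best - harmonic_tolerance)
    return int(near[0]) + min_period


def _local_score(seq: np.ndarray, start: int, end: int, period: int) -> float:
    """Match score of seq[start:end] against itself shifted by period."""
    if end - start <= period:
        return 0.0
    a, b = seq[start : end - period], seq[start + period : end]
    ok = (a != _N_CODE) & (b != _N_CODE)
    n = int(ok.sum())
    return float(((a == b) & ok).sum()) / n if n else 0.0


def _refine(seq: np.ndarray, start: int, end: int, period: int, threshold: float) -> tuple[int, int]:
    """Grow [start, end) outward while period-sized blocks keep scoring well."""
    while start - period >= 0 and _local_score(seq, start - period, start + period, period) >= threshold:
        start -= period
    while end + period <= len(seq) and _local_score(seq, end - period, end + period, period) >= threshold:
        end += period
    # trim sub-period remainders at the edges
    while start > 0 and _local_score(seq, start - 1, start - 1 + 2 * period, period) >= threshold:
        start -= 1
    while end < len(seq) and _local_score(seq, end + 1 - 2 * period, end + 1, period) >= threshold:
        end += 1
    return start, end


def _consensus(seq: np.ndarray, start: int, end: int, period: int) -> str:
    n_full = (end - start) // period
    block = seq[start : start + n_full * period].reshape(n_full, period)
    cons = np.empty(period, dtype=np.uint8)
    for j in range(period):
        col = block[:, j]
        col = col[col != _N_CODE]
        if col.size == 0:
            cons[j] = _N_CODE
            continue
        bases, counts = np.unique(col, return_counts=True)
        cons[j] = bases[np.argmax(counts)]
    return cons.tobytes().decode("ascii")


def _at_fraction(consensus: str) -> float:
    acgt = sum(consensus.count(b) for b in "ACGT")
    at = consensus.count("A") + consensus.count("T")
    return at / acgt if acgt else 0.0


def find_arrays(
    scaffold_name: str,
    sequence: str,
    params: SatelliteParams = SatelliteParams(),
) -> list[SatelliteArray]:
    """Locate tandem satellite arrays on one scaffold.

    Windows of 3x max_period with 50% overlap are scanned with
    ``estimate_period``; adjacent windows reporting the same period
    (within 2 bp) are merged, boundaries are refined to the maximal
    extent with period score >= match_threshold, and the consensus is
    the per-column majority over phase-aligned full copies.
    """
    seq = _encode(sequence)
    win_len = 3 * params.max_period
    if len(seq) < win_len:
        return []
    step = win_len // 2
    starts = list(range(0, max(len(seq) - win_len, 0) + 1, step))
    if starts[-1] + win_len < len(seq):
        starts.append(len(seq) - win_len)
    hits: list[tuple[int, int, int]] = []  # (win_start, win_end, period)
    for s in starts:
        p = estimate_period(
            seq[s : s + win_len],
            params.min_period,
            params.max_period,
            params.match_threshold,
            params.harmonic_tolerance,
        )
        if p is not None:
            hits.append((s, s + win_len, p))
    merged: list[list[int]] = []
    for s, e, p in hits:
        if merged and s <= merged[-1][1] and abs(p - merged[-1][2]) <= 2:
            merged[-1][1] = e
        else:
            merged.append([s, e, p])
    arrays = []
    for s, e, p in merged:
        s, e = _refine(seq, s, e, p, params.match_threshold)
        copies = (e - s) / p
        if copies < params.min_copies:
            continue
        cons = _consensus(seq, s, e, p)
        arrays.append(
            SatelliteArray(scaffold_name, s, e, p, copies, cons, _at_fraction(cons))
        )
    # merge refined arrays that grew into each other
    arrays.sort(key=lambda a: a.start)
    out: list[SatelliteArray] = []
    for arr in arrays:
        if out and arr.start < out[-1].end and abs(arr.period - out[-1].period) <= 2:
            prev = out[-1]
            s, e = prev.start, max(prev.end, arr.end)
            p = prev.period
            cons = _consensus(seq, s, e, p)
            out[-1] = SatelliteArray(
                prev.scaffold, s, e, p, (e - s) / p, cons, _at_fraction(cons)
            )
        else:
            out.append(arr)
    return out


def terminal_classification(
    array: SatelliteArray, scaffold_length: int, margin: float = 0.1
) -> str:
    """Classify an array as left_terminal / right_terminal / internal.

    An array within ``margin`` of a scaffold end is terminal; if both
    ends qualify the nearer terminus wins, with ties going left.
    """
    left = array.start < margin * scaffold_length
    right = array.end > (1 - margin) * scaffold_length
    if left and right:
        dist_left = array.start
        dist_right = scaffold_length - array.end
        return "left_terminal" if dist_left <= dist_right else "right_terminal"
    if left:
        return "left_terminal"
    if right:
        return "right_terminal"
    return "internal"


def genome_satellite_summary(arrays: Sequence[SatelliteArray]) -> dict:
    """Totals over a set of arrays: copies, arrays per scaffold, AT stats."""
    ordered = sorted(arrays, key=lambda a: (a.scaffold, a.start))
    per_scaffold: dict[str, int] = {}
    for a in ordered:
        per_scaffold[a.scaffold] = per_scaffold.get(a.scaffold, 0) + 1
    ats = [a.at_fraction for a in ordered]
    return {
        "n_arrays": len(ordered),
        "total_copies": float(sum(a.copies for a in ordered)),
        "arrays_per_scaffold": per_scaffold,
        "mean_at_fraction": float(np.mean(ats)) if ats else 0.0,
        "arrays": ordered,
    }


def scan_genome(
    scaffolds: Mapping[str, str], params: SatelliteParams = SatelliteParams()
) -> list[SatelliteArray]:
    """Run array detection over every scaffold of a genome."""
    out: list[SatelliteArray] = []
    for name in scaffolds:
        out.extend(find_arrays(name, scaffolds[name], params))
    return out


def write_bed(arrays: Sequence[SatelliteArray], path) -> None:
    """Write arrays as BED6+3: name SAT, score = rounded copy count."""
    with open(path, "w") as fh:
        for a in sorted(arrays, key=lambda x: (x.scaffold, x.start)):
            fh.write(
                f"{a.scaffold}\t{a.start}\t{a.end}\tSAT\t{round(a.copies)}\t.\t"
                f"{a.period}\t{a.copies:.2f}\t{a.at_fraction:.4f}\n"
            )


def read_bed(path) -> list[SatelliteArray]:
    arrays = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            arrays.append(
                SatelliteArray(
                    f[0], int(f[1]), int(f[2]), int(f[6]), float(f[7]), "", float(f[8])
                )
            )
    return arrays
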