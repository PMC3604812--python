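"""Tiled best-hit identity between proteomes and bimodal cutoff derivation.

A protein pair usually aligns as several local fragments (HSPs).  The
overall identity of the pair is computed by tiling the fragments on
the query axis: fragments are laid down greedily in descending order
of matched positions, a fragment contributes only query columns not
already covered, and its matches are pro-rated over the surviving
columns.  Overall identity = surviving matches / tiled columns.

When such identities are computed against a close relative and a
distant outgroup, their distributions are bimodal; the modes and the
crossing point of the two smoothed densities give principled low- and
high-homology cutoffs for ortholog classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GRID_SIZE = 512


@dataclass(frozen=True)
class AlignmentFragment:
    """One local alignment fragment in query coordinates (0-based half-open, aa)."""

    query: str
    subject: str
    qstart: int
    qend: int
    sstart: int
    send: int
    matched: int
    length: int

    def __post_init__(self) -> None:
        if self.qend <= self.qstart:
            raise ValueError("fragment query interval must be non-empty")
        if self.matched > self.length:
            raise ValueError("matched positions cannot exceed fragment length")


@dataclass(frozen=True)
class BestHit:
    query: str
    subject: str
    identity: float
    tiled_columns: int


@dataclass(frozen=True)
class CutoffResult:
    mode_high: float
    mode_low: float
    crossing: float
    low_cutoff: float
    high_cutoff: float


def tiled_identity(
    fragments: Sequence[AlignmentFragment], query_length: int | None = None
) -> tuple[float, int]:
    """Overall identity of one query-subject pair from its fragments.

    Fragments are tiled on the query axis in descending matched-position
    order (ties: longer fragment, then smaller qstart); overlap columns
    go to the fragment tiled first, and the later fragment's matches
    are reduced proportionally to its surviving columns.  Returns
    (identity, number of tiled columns).
    """
    if not fragments:
        raise ValueError("no fragments for pair")
    pairs = {(f.query, f.subject) for f in fragments}
    if len(pairs) > 1:
        raise ValueError(f"fragments span multiple pairs: {sorted(pairs)}")
    span = max(f.qend for f in fragments)
    if query_length is not None:
        span = max(span, query_length)
    covered = np.zeros(span, dtype=bool)
    order = sorted(fragments, key=lambda f: (-f.matched, -(f.qend - f.qstart), f.qstart))
    matches = 0.0
    for frag in order:
        cols = frag.qend - frag.qstart
        free = int((~covered[frag.qstart : frag.qend]).sum())
        if free == 0:
            continue
        matches += frag.matched * free / cols
        covered[frag.qstart : frag.qend] = True
    tiled = int(covered.sum())
    return matches / tiled, tiled


def best_hits(fragments: Iterable[AlignmentFragment]) -> list[BestHit]:
    """Per-query best subject by overall tiled identity.

    Ties are broken by larger tiled column count, then lexicographically
    smaller subject id.  Queries with no fragments are simply absent.
    """
    by_pair: dict[tuple[str, str], list[AlignmentFragment]] = {}
    for f in fragments:
        by_pair.setdefault((f.query, f.subject), []).append(f)
    by_query: dict[str, list[BestHit]] = {}
    for (q, s), frags in by_pair.items():
        ident, cols = tiled_identity(frags)
        by_query.setdefault(q, []).append(BestHit(q, s, ident, cols))
    out = []
    for q in sorted(by_query):
        cand = by_query[q]
        top = max((h.identity, h.tiled_columns) for h in cand)
        best = min(
            (h for h in cand if (h.identity, h.tiled_columns) == top),
            key=lambda h: h.subject,
        )
        out.append(best)
    return out


def _density_grid(values: np.ndarray, bandwidth: float | None) -> np.ndarray:
    kde = stats.gaussian_kde(values, bw_method=bandwidth)  # None -> Scott ~ Silverman
    if bandwidth is None:
        kde.set_bandwidth("silverman")
    return kde(np.linspace(0.0, 1.0, GRID_SIZE))


def identity_modes(
    identities: Sequence[float], bandwidth: float | None = None
) -> list[float]:
    """Modes of the smoothed identity density on [0, 1].

    Gaussian KDE (Silverman bandwidth by default) on a 512-point grid;
    modes are interior local maxima whose density is at least 10% of
    the global maximum, returned sorted by descending density.
    Requires >= 50 values for a stable density.
    """
    vals = np.asarray(identities, dtype=float)
    if vals.size < 50:
        raise ValueError("need at least 50 identities for a stable density")
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    if np.ptp(vals) == 0:  # degenerate sample: the single value is the mode
        return [float(vals[0])]
    dens = _density_grid(vals, bandwidth)
    floor = 0.10 * dens.max()
    interior = (
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:]) & (dens[1:-1] >= floor)
    )
    idx = np.flatnonzero(interior) + 1
    idx = idx[np.argsort(-dens[idx])]
    return [float(grid[i]) for i in idx]


def crossing_point(
    identities_a: Sequence[float],
    identities_b: Sequence[float],
    bandwidth: float | None = None,
) -> float:
    """Identity where the two smoothed densities cross, between their
    principal modes.

    The densities are evaluated on a common grid; among grid points
    where the density difference changes sign inside the inter-mode
    interval, the crossing nearest the midpoint of the two modes is
    returned.
    """
    modes_a = identity_modes(identities_a, bandwidth)
    modes_b = identity_modes(identities_b, bandwidth)
    m_a, m_b = modes_a[0], modes_b[0]
    if m_a == m_b:
        raise ValueError("distributions do not cross: principal modes coincide")
    lo, hi = sorted((m_a, m_b))
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    dens_a = _density_grid(np.asarray(identities_a, float), bandwidth)
    dens_b = _density_grid(np.asarray(identities_b, float), bandwidth)
    diff = dens_a - dens_b
    inside = np.flatnonzero((grid >= lo) & (grid <= hi))
    sign_change = [
        i for i in inside[:-1] if np.sign(diff[i]) != np.sign(diff[i + 1])
    ]
    if not sign_change:
        raise ValueError("distributions do not cross between their modes")
    mid = (lo + hi) / 2
    best = min(sign_change, key=lambda i: abs(grid[i] - mid))
    # linear interpolation within the bracketing grid cell
    x0, x1 = grid[best], grid[best + 1]
    y0, y1 = diff[best], diff[best + 1]
    if y1 == y0:
        return float((x0 + x1) / 2)
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def classify_orthologs(
    hits: Sequence[BestHit],
    low_cutoff: float = 0.30,
    high_cutoff: float = 0.60,
) -> dict[str, str]:
    """Bin best hits into no_homolog / low / high homology classes.

    Half-open bins: identity < low -> no_homolog; low <= identity <
    high -> low; identity >= high -> high.
    """
    if not low_cutoff < high_cutoff:
        raise ValueError("low_cutoff must be below high_cutoff")
    out = {}
    for h in hits:
        if h.identity < low_cutoff:
            out[h.query] = "no_homolog"
        elif h.identity < high_cutoff:
            out[h.query] = "low"
        else:
            out[h.query] = "high"
    return out


def derive_cutoffs(
    identities_ingroup: Sequence[float],
    identities_outgroup: Sequence[float],
    bandwidth: float | None = None,
    low_cutoff: float = 0.30,
) -> CutoffResult:
    """Derive homology cutoffs from ingroup/outgroup identity distributions.

    The high cutoff is the crossing point of the two densities; the low
    cutoff is a floor below the outgroup mode, kept as an explicit
    parameter.
    """
    mode_high = identity_modes(identities_ingroup, bandwidth)[0]
    mode_low = identity_modes(identities_outgroup, bandwidth)[0]
    if mode_high < mode_low:
        mode_high, mode_low = mode_low, mode_high
    crossing = crossing_point(identities_ingroup, identities_outgroup, bandwidth)
    return CutoffResult(mode_high, mode_low, crossing, low_cutoff, crossing)


def read_fragments(path) -> list[AlignmentFragment]:
    """Read a BLAST-tabular-like fragment TSV.

    Columns: qid, sid, qstart, qend, sstart, send, nident, length with
    0-based half-open intervals.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["qid", "sid", "qstart", "qend", "sstart", "send", "nident", "length"],
        comment="#",
    )
    return [
        AlignmentFragment(
            r.qid, r.sid, int(r.qstart), int(r.qend), int(r.sstart), int(r.send),
            int(r.nident), int(r.length),
        )
        for r in df.itertuples(index=False)
    ]
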