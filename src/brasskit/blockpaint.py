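"""Paint scaffolds with ancestral genomic blocks from reference-gene placements.

Crucifer genomes can be described as rearrangements of 24 conserved
ancestral blocks labelled A-X, each defined by a syntenic set of
reference genes.  Given where those reference genes land on the
scaffolds of a new assembly, each scaffold is segmented into maximal
runs of one block label; the orientation of a segment relative to the
ancestral gene order is the sign of Kendall's tau between scaffold
order and ancestral rank within the block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BLOCK_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWX"


@dataclass(frozen=True)
class GenePlacement:
    gene: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class BlockSegment:
    scaffold: str
    block: str
    start: int
    end: int
    genes: tuple[str, ...]
    orientation: str  # '+', '-', or '?'
    mean_index: float

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _orientation(indices: Sequence[int], tau_gate: float = 0.5) -> str:
    if len(indices) < 2:
        return "?"
    tau, _ = stats.kendalltau(range(len(indices)), indices)
    if tau is None or abs(tau) < tau_gate:
        return "?"
    return "+" if tau > 0 else "-"


@dataclass
class PaintAccounting:
    """Where every placed gene ended up during painting."""

    in_segments: list[str]
    absorbed: list[str]
    discarded: list[str]
    unknown: list[str]


def paint_scaffold(
    scaffold: str,
    placements: Sequence[GenePlacement],
    block_table: Mapping[str, tuple[str, int]],
    min_run: int = 3,
    max_interleave: int = 2,
    tau_gate: float = 0.5,
) -> list[BlockSegment]:
    """Segment one scaffold's gene track into ancestral-block runs.

    Genes are scanned in scaffold order.  A run of one block label
    tolerates up to ``max_interleave`` consecutive foreign-label genes
    (absorbed, logged) provided the run resumes afterwards; runs with
    fewer than ``min_run`` same-label genes are discarded.  Placed
    genes missing from the block table are skipped with a log message.
    """
    segments, _ = paint_scaffold_detailed(
        scaffold, placements, block_table, min_run, max_interleave, tau_gate
    )
    return segments


def paint_scaffold_detailed(
    scaffold: str,
    placements: Sequence[GenePlacement],
    block_table: Mapping[str, tuple[str, int]],
    min_run: int = 3,
    max_interleave: int = 2,
    tau_gate: float = 0.5,
) -> tuple[list[BlockSegment], PaintAccounting]:
    """As :func:`paint_scaffold`, also returning per-gene accounting."""
    acct = PaintAccounting([], [], [], [])
    ordered = sorted(placements, key=lambda p: p.start)
    track: list[tuple[GenePlacement, str, int]] = []
    for p in ordered:
        if p.gene not in block_table:
            logger.info("gene %s on %s not in block table; skipped", p.gene, scaffold)
            acct.unknown.append(p.gene)
            continue
        label, idx = block_table[p.gene]
        track.append((p, label, idx))
    if not track:
        logger.info("scaffold %s has no placed block-table genes", scaffold)
        return [], acct

    runs: list[list[tuple[GenePlacement, str, int]]] = []
    current: list[tuple[GenePlacement, str, int]] = [track[0]]
    pending: list[tuple[GenePlacement, str, int]] = []
    for item in track[1:]:
        label = item[1]
        if label == current[0][1]:
            if pending:
                for f in pending:
                    logger.info(
                        "absorbed foreign gene %s (%s) inside %s run on %s",
                        f[0].gene, f[1], current[0][1], scaffold,
                    )
                    acct.absorbed.append(f[0].gene)
                pending = []
            current.append(item)
        else:
            pending.append(item)
            if len(pending) > max_interleave:
                runs.append(current)
                # the pending genes start their own run(s)
                current = [pending[0]]
                for extra in pending[1:]:
                    if extra[1] == current[0][1]:
                        current.append(extra)
                    else:
                        runs.append(current)
                        current = [extra]
                pending = []
    runs.append(current)
    for f in pending:
        runs.append([f])

    segments = []
    for run in runs:
        if len(run) < min_run:
            for g in run:
                logger.info("discarded short run gene %s (%s) on %s", g[0].gene, g[1], scaffold)
                acct.discarded.append(g[0].gene)
            continue
        start = min(g[0].start for g in run)
        end = max(g[0].end for g in run)
        indices = [g[2] for g in run]
        acct.in_segments.extend(g[0].gene for g in run)
        segments.append(
            BlockSegment(
                scaffold=scaffold,
                block=run[0][1],
                start=start,
                end=end,
                genes=tuple(g[0].gene for g in run),
                orientation=_orientation(indices, tau_gate),
                mean_index=sum(indices) / len(indices),
            )
        )
    segments.sort(key=lambda s: s.start)
    return segments, acct


def paint_all(
    placements_by_scaffold: Mapping[str, Sequence[GenePlacement]],
    block_table: Mapping[str, tuple[str, int]],
    min_run: int = 3,
    max_interleave: int = 2,
) -> dict[str, list[BlockSegment]]:
    return {
        scaf: paint_scaffold(scaf, pls, block_table, min_run, max_interleave)
        for scaf, pls in placements_by_scaffold.items()
    }


def block_inventory(
    painted: Mapping[str, Sequence[BlockSegment]],
    chromosome_of: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """Per-block inventory of segments with split-block flags.

    A block is flagged split when its segments lie on more than one
    scaffold (or, when a scaffold -> chromosome map is supplied, more
    than one chromosome).
    """
    inv: dict[str, dict] = {}
    for scaf in sorted(painted):
        for seg in painted[scaf]:
            entry = inv.setdefault(seg.block, {"segments": [], "split": False})
            entry["segments"].append(seg)
    for block, entry in inv.items():
        if chromosome_of is not None:
            places = {
                chromosome_of.get(s.scaffold, s.scaffold) for s in entry["segments"]
            }
        else:
            places = {s.scaffold for s in entry["segments"]}
        entry["split"] = len(places) > 1
        entry["locations"] = sorted(places)
    return inv


def read_block_table(path) -> dict[str, tuple[str, int]]:
    """Read a block table TSV (gene, block letter, ancestral index)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "block", "index"], comment="#")
    return {r.gene: (r.block, int(r.index)) for r in df.itertuples(index=False)}


def read_placements(path) -> dict[str, list[GenePlacement]]:
    """Read a BED-like placements TSV (scaffold, start, end, gene, score, strand)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["scaffold", "start", "end", "gene", "score", "strand"], comment="#",
    )
    out: dict[str, list[GenePlacement]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.scaffold, []).append(
            GenePlacement(r.gene, int(r.start), int(r.end), r.strand)
        )
    return out


def write_segments(painted: Mapping[str, Sequence[BlockSegment]], path) -> None:
    rows = [
        {
            "scaffold": s.scaffold, "start": s.start, "end": s.end, "block": s.block,
            "n_genes": s.n_genes, "orientation": s.orientation,
            "mean_index": round(s.mean_index, 2),
        }
        for scaf in sorted(painted)
        for s in painted[scaf]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
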