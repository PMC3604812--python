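"""Arrange painted scaffolds into chromosomes along a karyotype template.

The karyotype (experimentally derived, e.g. by chromosome painting) is
an ordered list of signed ancestral blocks per chromosome with a
centromere position.  Scaffolds, already painted with block segments,
are matched to the template largest-first: a scaffold's block-label
sequence must occur as a contiguous run of one chromosome's block
order, either forward or reversed with signs flipped.  Orientation is
chosen to maximize agreement between segment signs and karyotype
signs; a satellite-bearing scaffold terminus overrides this and must
face the centromere.  Scaffolds are never split; every conflict is
reported rather than resolved.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from typing import Mapping, Sequence

from .blockpaint import BlockSegment
from .satellite import SatelliteArray, terminal_classification
from .simulate import Chromosome, KaryotypeDefinition
from .tai import reverse_complement


@dataclass(frozen=True)
class ScaffoldPlacement:
    scaffold: str
    orientation: str  # '+' or '-'
    blocks: tuple[str, ...]  # matched block labels, chromosome order
    position: int  # index of first matched block in the chromosome block list
    sort_index: float = 0.0  # within-block ordering key (mean ancestral index, sign-adjusted)


@dataclass
class PlacementPlan:
    chromosomes: dict[str, list[ScaffoldPlacement]]
    unplaced: list[str]


@dataclass(frozen=True)
class AssemblyDiscrepancy:
    kind: str  # missing_block | split_block | order_conflict | orientation_conflict | unplaced_scaffold
    entities: tuple[str, ...]
    description: str


def _flip(sign: str) -> str:
    return {"+": "-", "-": "+", "?": "?"}[sign]


def _match_on_chromosome(
    labels: Sequence[str], chrom: Chromosome
) -> list[int]:
    """Start positions where ``labels`` occurs contiguously in the
    chromosome's block order."""
    chrom_labels = [lab for _, lab in chrom.blocks]
    k = len(labels)
    return [
        i
        for i in range(len(chrom_labels) - k + 1)
        if chrom_labels[i : i + k] == list(labels)
    ]


def _satellite_side(
    scaffold: str,
    scaffold_length: int,
    satellites: Mapping[str, list[SatelliteArray]],
) -> str | None:
    """'left'/'right' terminus carrying a satellite array, if any."""
    for arr in satellites.get(scaffold, []):
        cls = terminal_classification(arr, scaffold_length)
        if cls == "left_terminal":
            return "left"
        if cls == "right_terminal":
            return "right"
    return None


def match_scaffolds(
    karyotype: KaryotypeDefinition,
    painted: Mapping[str, Sequence[BlockSegment]],
    satellites: Mapping[str, list[SatelliteArray]] | None = None,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> tuple[PlacementPlan, list[AssemblyDiscrepancy]]:
    """Place and orient scaffolds on the karyotype template.

    Scaffolds are processed in descending painted-gene-count order.
    Matching tries the scaffold's segment label sequence forward and
    reversed (signs flipped); among matching chromosomes/offsets the
    orientation with the higher sign agreement wins.  Satellite
    evidence overrides sign agreement: the satellite-bearing terminus
    must face the centromere; when that flips the sign-preferred
    orientation an orientation_conflict is recorded.  A scaffold whose
    labels match nowhere, or whose matched positions are already
    claimed, goes to the unplaced bin.
    """
    satellites = satellites or {}
    scaffold_lengths = scaffold_lengths or {}
    discrepancies: list[AssemblyDiscrepancy] = []
    # A block may be shared by several scaffolds (fragmentation cuts
    # inside blocks), but only at the ends of a scaffold's matched
    # range: interior block positions are claimed exclusively.
    claimed_any: dict[str, set[int]] = {c.name: set() for c in karyotype.chromosomes}
    claimed_interior: dict[str, set[int]] = {c.name: set() for c in karyotype.chromosomes}
    placements: dict[str, list[ScaffoldPlacement]] = {
        c.name: [] for c in karyotype.chromosomes
    }
    unplaced: list[str] = []

    order = sorted(
        painted,
        key=lambda s: (-sum(seg.n_genes for seg in painted[s]), s),
    )
    for scaf in order:
        segs = list(painted[scaf])
        if not segs:
            unplaced.append(scaf)
            discrepancies.append(
                AssemblyDiscrepancy(
                    "unplaced_scaffold", (scaf,), "no painted block segments"
                )
            )
            continue
        fwd_labels = [s.block for s in segs]
        fwd_signs = [s.orientation for s in segs]
        rev_labels = fwd_labels[::-1]
        rev_signs = [_flip(s) for s in fwd_signs[::-1]]

        candidates = []  # (agreement, chrom, pos, orientation)
        for chrom in karyotype.chromosomes:
            chrom_signs = [sg for sg, _ in chrom.blocks]
            for pos in _match_on_chromosome(fwd_labels, chrom):
                agree = sum(
                    1
                    for i, sg in enumerate(fwd_signs)
                    if sg == chrom_signs[pos + i]
                )
                candidates.append((agree, chrom, pos, "+", tuple(fwd_labels)))
            for pos in _match_on_chromosome(rev_labels, chrom):
                agree = sum(
                    1
                    for i, sg in enumerate(rev_signs)
                    if sg == chrom_signs[pos + i]
                )
                candidates.append((agree, chrom, pos, "-", tuple(rev_labels)))
        if not candidates:
            unplaced.append(scaf)
            discrepancies.append(
                AssemblyDiscrepancy(
                    "unplaced_scaffold",
                    (scaf,),
                    f"block labels {fwd_labels} match no chromosome",
                )
            )
            continue
        candidates.sort(key=lambda c: (-c[0], c[1].name, c[2], c[3]))
        agree, chrom, pos, orient, labels = candidates[0]

        # satellite override: the satellite terminus must face the centromere
        sat_side = _satellite_side(
            scaf, scaffold_lengths.get(scaf, 0), satellites
        ) if scaf in satellites else None
        if sat_side is not None:
            k = len(labels)
            cen = chrom.centromere_after  # centromere between blocks cen and cen+1
            if pos + k <= cen + 1:
                facing = "right"  # scaffold entirely left of centromere
            elif pos > cen:
                facing = "left"
            else:
                facing = None  # spans the centromere: no constraint
            if facing is not None:
                # current orientation puts the satellite at sat_side for '+',
                # at the mirrored side for '-'
                side_now = sat_side if orient == "+" else (
                    "left" if sat_side == "right" else "right"
                )
                if side_now != facing:
                    new_orient = "-" if orient == "+" else "+"
                    # re-find the reversed match at a compatible position
                    alt = [
                        c
                        for c in candidates
                        if c[1].name == chrom.name and c[3] == new_orient
                    ]
                    if alt:
                        _, chrom, pos, orient, labels = alt[0]
                    else:
                        orient = new_orient
                        labels = labels[::-1]
                    discrepancies.append(
                        AssemblyDiscrepancy(
                            "orientation_conflict",
                            (scaf,),
                            "satellite-terminal evidence overrode sign-based orientation",
                        )
                    )

        span = set(range(pos, pos + len(labels)))
        interior = set(range(pos + 1, pos + len(labels) - 1))
        if (interior & claimed_any[chrom.name]) or (span & claimed_interior[chrom.name]):
            unplaced.append(scaf)
            clash = sorted(
                (interior & claimed_any[chrom.name])
                | (span & claimed_interior[chrom.name])
            )
            discrepancies.append(
                AssemblyDiscrepancy(
                    "order_conflict",
                    (scaf, chrom.name),
                    f"block positions {clash} already claimed",
                )
            )
            continue
        claimed_any[chrom.name] |= span
        claimed_interior[chrom.name] |= interior
        # within-block ordering: mean ancestral index of the first
        # matched block's segment, ascending when the karyotype carries
        # that block '+', descending when '-'
        first_label = labels[0]
        seg = next((s for s in segs if s.block == first_label), None)
        mean_idx = seg.mean_index if seg is not None else 0.0
        block_sign = chrom.blocks[pos][0]
        sort_index = mean_idx if block_sign == "+" else -mean_idx
        placements[chrom.name].append(
            ScaffoldPlacement(scaf, orient, tuple(labels), pos, sort_index)
        )

    for name in placements:
        placements[name].sort(key=lambda p: (p.position, p.sort_index, p.scaffold))
    return PlacementPlan(placements, unplaced), discrepancies


def build_pseudomolecules(
    plan: PlacementPlan,
    scaffolds: Mapping[str, str],
    inter_scaffold_gap: int = 100,
) -> tuple[dict[str, str], list[list]]:
    """Join placed scaffolds into chromosome sequences plus AGP v2.0 rows.

    Scaffolds with orientation '-' are reverse complemented; scaffolds
    are joined by N runs of ``inter_scaffold_gap`` (AGP component type
    U, linkage no).  AGP coordinates are 1-based inclusive.
    """
    chrom_seqs: dict[str, str] = {}
    agp: list[list] = []
    for chrom in plan.chromosomes:
        parts: list[str] = []
        pos = 0
        part_no = 0
        for i, pl in enumerate(plan.chromosomes[chrom]):
            if pl.scaffold not in scaffolds:
                raise KeyError(f"scaffold {pl.scaffold} missing from FASTA")
            if i > 0:
                part_no += 1
                agp.append(
                    [
                        chrom, pos + 1, pos + inter_scaffold_gap, part_no,
                        "U", inter_scaffold_gap, "scaffold", "no", "na",
                    ]
                )
                parts.append("N" * inter_scaffold_gap)
                pos += inter_scaffold_gap
            seq = scaffolds[pl.scaffold]
            if pl.orientation == "-":
                seq = reverse_complement(seq)
            part_no += 1
            agp.append(
                [
                    chrom, pos + 1, pos + len(seq), part_no,
                    "W", pl.scaffold, 1, len(seq), pl.orientation,
                ]
            )
            parts.append(seq)
            pos += len(seq)
        chrom_seqs[chrom] = "".join(parts)
    return chrom_seqs, agp


def write_agp(agp: Sequence[Sequence], path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for row in agp:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_agp(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append(line.rstrip("\n").split("\t"))
    return rows


def extract_components(
    agp_rows: Sequence[Sequence[str]], chrom_seqs: Mapping[str, str]
) -> dict[str, str]:
    """Recover component (scaffold) sequences from AGP + chromosome FASTA."""
    out: dict[str, str] = {}
    for row in agp_rows:
        if row[4] != "W":
            continue
        chrom, beg, end = row[0], int(row[1]), int(row[2])
        seq = chrom_seqs[chrom][beg - 1 : end]
        if row[8] == "-":
            seq = reverse_complement(seq)
        out[row[5]] = seq
    return out


def discrepancy_report(
    plan: PlacementPlan,
    karyotype: KaryotypeDefinition,
    painted: Mapping[str, Sequence[BlockSegment]],
    match_discrepancies: Sequence[AssemblyDiscrepancy] = (),
) -> list[AssemblyDiscrepancy]:
    """Full discrepancy report for an assembly.

    Includes matching-stage conflicts plus karyotype blocks with no
    placed segment (missing_block), blocks placed on more than one
    chromosome (split_block) and residual sign disagreements after
    orientation (orientation_conflict).
    """
    report = list(match_discrepancies)
    placed_blocks: dict[str, set[str]] = {}
    placed_scaffold_chrom: dict[str, str] = {}
    for chrom, pls in plan.chromosomes.items():
        for pl in pls:
            placed_scaffold_chrom[pl.scaffold] = chrom
            for b in pl.blocks:
                placed_blocks.setdefault(b, set()).add(chrom)
    karyotype_blocks = {
        lab for c in karyotype.chromosomes for _, lab in c.blocks
    }
    for b in sorted(karyotype_blocks - set(placed_blocks)):
        report.append(
            AssemblyDiscrepancy("missing_block", (b,), "no placed segment covers this block")
        )
    # split blocks: painted segments of one block on scaffolds assigned to >1 chromosome
    seg_chroms: dict[str, set[str]] = {}
    for scaf, segs in painted.items():
        chrom = placed_scaffold_chrom.get(scaf)
        if chrom is None:
            continue
        for seg in segs:
            seg_chroms.setdefault(seg.block, set()).add(chrom)
    for b in sorted(seg_chroms):
        if len(seg_chroms[b]) > 1:
            report.append(
                AssemblyDiscrepancy(
                    "split_block",
                    (b, *sorted(seg_chroms[b])),
                    "block segments assigned to multiple chromosomes",
                )
            )
    # residual sign disagreements
    sign_of = {
        c.name: {i: sg for i, (sg, _) in enumerate(c.blocks)}
        for c in karyotype.chromosomes
    }
    seg_sign: dict[str, dict[str, str]] = {
        scaf: {s.block: s.orientation for s in segs} for scaf, segs in painted.items()
    }
    for chrom, pls in plan.chromosomes.items():
        for pl in pls:
            for i, b in enumerate(pl.blocks):
                want = sign_of[chrom][pl.position + i]
                have = seg_sign.get(pl.scaffold, {}).get(b, "?")
                if pl.orientation == "-":
                    have = _flip(have)
                if have != "?" and have != want:
                    report.append(
                        AssemblyDiscrepancy(
                            "orientation_conflict",
                            (pl.scaffold, b),
                            f"segment sign {have} disagrees with karyotype sign {want}",
                        )
                    )
    return report


def block_palette(labels: Sequence[str]) -> dict[str, str]:
    """Deterministic letter -> hex color mapping over up to 26 labels."""
    out = {}
    for lab in sorted(set(labels)):
        i = ord(lab) - ord("A")
        r, g, b = colorsys.hsv_to_rgb((i * 0.13) % 1.0, 0.55 + 0.35 * ((i % 3) / 2), 0.9)
        out[lab] = "#{:02x}{:02x}{:02x}".format(int(r * 255), int(g * 255), int(b * 255))
    return out


def render_digital_karyotype(
    plan: PlacementPlan,
    painted: Mapping[str, Sequence[BlockSegment]],
    karyotype: KaryotypeDefinition,
) -> str:
    """Render the assembly as an SVG ideogram document.

    One vertical ideogram per chromosome: stacked block rectangles in
    plan order, colored by a fixed palette keyed on block letter, with
    letter labels and a centromere marker.  Output is deterministic
    for a fixed plan.
    """
    all_labels = [lab for c in karyotype.chromosomes for _, lab in c.blocks]
    palette = block_palette(all_labels)
    col_w, block_h, pad, top = 60, 28, 40, 30
    chrom_names = [c.name for c in karyotype.chromosomes]
    height = top + block_h * max(
        (len(c.blocks) for c in karyotype.chromosomes), default=0
    ) + 60
    width = pad + len(chrom_names) * (col_w + pad)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
    ]
    for ci, chrom in enumerate(karyotype.chromosomes):
        x = pad + ci * (col_w + pad)
        lines.append(
            f'<text x="{x + col_w // 2}" y="{top - 10}" text-anchor="middle" '
            f'font-size="14">{chrom.name}</text>'
        )
        y = top
        drawn = 0
        for pl in plan.chromosomes.get(chrom.name, []):
            for b in pl.blocks:
                lines.append(
                    f'<rect x="{x}" y="{y}" width="{col_w}" height="{block_h}" '
                    f'fill="{palette[b]}" stroke="black"/>'
                )
                arrow = "&#8593;" if pl.orientation == "+" else "&#8595;"
                lines.append(
                    f'<text x="{x + col_w // 2}" y="{y + block_h - 8}" '
                    f'text-anchor="middle" font-size="12">{b}{arrow}</text>'
                )
                y += block_h
                drawn += 1
        cen_y = top + (chrom.centromere_after + 1) * block_h
        lines.append(
            f'<circle cx="{x + col_w // 2}" cy="{cen_y}" r="6" fill="black"/>'
        )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"
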