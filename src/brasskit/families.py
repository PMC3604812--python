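"""Gene-family evolution: tandem duplication, lineage-specific clusters,
copy-number enrichment.

Works on a gene catalog table with columns
``gene, species, scaffold, order_index, family, cluster`` where
``order_index`` is the gene's rank along its scaffold.  Two same-family
genes are a tandem pair when they are consecutive family members on a
scaffold and fewer than ``max_distance`` gene positions apart (the
boundary case, exactly ``max_distance``, is not tandem).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

CATALOG_COLUMNS = ["gene", "species", "scaffold", "order_index", "family", "cluster"]


@dataclass(frozen=True)
class TandemCall:
    gene_a: str
    gene_b: str
    species: str
    scaffold: str
    intervening: int
    is_tandem: bool


def tandem_pairs(
    catalog: pd.DataFrame,
    family: str,
    max_distance: int = 20,
    all_pairs: bool = False,
) -> tuple[list[TandemCall], dict[str, float]]:
    """Tandem-duplication calls for one family plus per-species tandem proportion.

    With ``all_pairs=False`` (default) only consecutive family members
    along a scaffold are compared; ``all_pairs=True`` compares every
    same-scaffold pair.  A member is "tandem" if it participates in at
    least one tandem call; the proportion is tandem members / family
    members per species.
    """
    fam = catalog[catalog["family"] == family]
    calls: list[TandemCall] = []
    tandem_genes: set[str] = set()
    for (species, scaffold), grp in fam.groupby(["species", "scaffold"], sort=True):
        grp = grp.sort_values("order_index")
        genes = list(grp["gene"])
        idx = list(grp["order_index"])
        if all_pairs:
            pairs = [
                (i, j) for i in range(len(genes)) for j in range(i + 1, len(genes))
            ]
        else:
            pairs = [(i, i + 1) for i in range(len(genes) - 1)]
        for i, j in pairs:
            dist = int(idx[j] - idx[i])
            tandem = dist < max_distance
            calls.append(
                TandemCall(genes[i], genes[j], species, scaffold, dist - 1, tandem)
            )
            if tandem:
                tandem_genes.update((genes[i], genes[j]))
    proportions = {}
    for species, grp in fam.groupby("species", sort=True):
        members = set(grp["gene"])
        proportions[species] = (
            len(members & tandem_genes) / len(members) if members else 0.0
        )
    return calls, proportions


def lineage_specific_clusters(
    catalog: pd.DataFrame, min_size: int = 2
) -> tuple[dict[str, int], pd.DataFrame]:
    """Count per species the clusters whose members all belong to it.

    Clusters smaller than ``min_size`` are ignored.  Returns the
    per-species counts and the full cluster x species membership
    matrix.
    """
    clustered = catalog.dropna(subset=["cluster"])
    matrix = (
        clustered.groupby(["cluster", "species"]).size().unstack(fill_value=0)
    )
    species = sorted(catalog["species"].unique())
    matrix = matrix.reindex(columns=species, fill_value=0)
    big = matrix[matrix.sum(axis=1) >= min_size]
    counts = {}
    for sp in species:
        others = [c for c in species if c != sp]
        mask = (big[sp] > 0) & (big[others].sum(axis=1) == 0)
        counts[sp] = int(mask.sum())
    return counts, matrix


def copy_number_compare(
    catalog: pd.DataFrame,
    families: list[str],
    species_a: str,
    species_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family copy numbers in two species with Fisher enrichment tests.

    For each family, a 2x2 table (family vs rest of genome, species A
    vs B) is tested with Fisher's exact test (two-sided); p-values are
    Benjamini-Hochberg adjusted across families.
    """
    total_a = int((catalog["species"] == species_a).sum())
    total_b = int((catalog["species"] == species_b).sum())
    if total_a == 0 or total_b == 0:
        raise ValueError("both species must have genes in the catalog")
    rows = []
    for fam in families:
        in_fam = catalog["family"] == fam
        count_a = int((in_fam & (catalog["species"] == species_a)).sum())
        count_b = int((in_fam & (catalog["species"] == species_b)).sum())
        table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "family": fam,
                "count_a": count_a,
                "count_b": count_b,
                "total_a": total_a,
                "total_b": total_b,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
        out["significant"] = out["p_adj"] < alpha
    return out


def read_catalog(path) -> pd.DataFrame:
    """Read a gene catalog TSV; missing family/cluster fields become NA."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CATALOG_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    for col in ("family", "cluster"):
        if col not in df.columns:
            df[col] = pd.NA
    dup = df.duplicated(subset=["scaffold", "species", "order_index"])
    if dup.any():
        raise ValueError("gene-order indices must be unique per scaffold")
    return df
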