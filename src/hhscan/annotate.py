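"""Per-SNP modelling table: predictor transforms, location collapse,
strata, GO singletization and hypothesis-testing groups.

Selection statistics arrive as one value per population (p-values, or MAF);
each is reduced to a single per-SNP predictor by summing natural logs across
populations. Gene-model labels are collapsed to four within-gene location
categories (plus intergenic), each SNP is assigned to exactly one stratum
(its gene, or the enclosing intergenic interval), and each gene's multiple
GO memberships are reduced to the single category closest in size to 125
genes, with small categories merged into OTHER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PVALUE_FLOOR = 1e-300
GO_SIZE_TARGET = 125
GO_SIZE_FLOOR = 50
FLANK_BP = 1000
OTHER = "OTHER"

#: raw gene-model labels -> collapsed location category, in priority order
LOCATION_MAP: dict[str, str] = {
    "exonic": "exonic",
    "ncRNA_exonic": "exonic",
    "UTR3": "UTR",
    "UTR5": "UTR",
    "ncRNA_UTR3": "UTR",
    "ncRNA_UTR5": "UTR",
    "intronic": "intronic",
    "splicing": "intronic",
    "ncRNA_intronic": "intronic",
    "ncRNA_splicing": "intronic",
    "upstream": "flanking",
    "downstream": "flanking",
    "intergenic": "intergenic",
}
LOCATION_PRIORITY = ["exonic", "UTR", "intronic", "flanking", "intergenic"]

GROUP1_GO = ["GO:0006367", "GO:0006396", "GO:0008544", "GO:0042742"]
GROUP2_GO = [
    "GO:0001501",
    "GO:0006869",
    "GO:0006936",
    "GO:0007186",
    "GO:0009653",
    "GO:0016567",
    "GO:0018108",
    "GO:0051056",
]


def transform_predictor(
    values: Sequence[float], kind: str = "pvalue", floor: float = PVALUE_FLOOR
) -> float:
    """Sum of natural logs of per-population values (the per-SNP predictor).

    p-values of zero are floored before the log; frequency-kind values of
    zero are skipped (a monomorphic population carries no information).
    Missing (NaN) entries are skipped; if nothing usable remains the result
    is NaN and the row is excluded from fits using this predictor.
    """
    if kind not in ("pvalue", "frequency"):
        raise ValueError("kind must be 'pvalue' or 'frequency'")
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if kind == "frequency":
        arr = arr[arr > 0]
    else:
        arr = np.maximum(arr, floor)
    if arr.size == 0:
        return np.nan
    return float(np.log(arr).sum())


def transform_table(
    predictors: pd.DataFrame,
    stats: Mapping[str, str],
    marker_col: str = "marker",
) -> pd.DataFrame:
    """Apply :func:`transform_predictor` column-family-wise.

    ``stats`` maps an output name to its kind ('pvalue'/'frequency'); the
    per-population inputs are columns named ``<name>.<population>``.
    """
    out = pd.DataFrame({marker_col: predictors[marker_col]})
    for name, kind in stats.items():
        cols = [c for c in predictors.columns if c.split(".")[0] == name and "." in c]
        if not cols:
            raise ValueError(f"no per-population columns found for predictor {name!r}")
        out[name] = [
            transform_predictor(row, kind=kind)
            for row in predictors[cols].to_numpy()
        ]
    return out


def collapse_location(raw_labels: str | Iterable[str]) -> str:
    """Collapse one or more raw gene-model labels to a single category.

    A SNP in multiple categories takes the highest-priority one
    (exonic > UTR > intronic > flanking > intergenic).
    """
    if isinstance(raw_labels, str):
        raw_labels = raw_labels.split(";")
    collapsed = set()
    for lab in raw_labels:
        lab = lab.strip()
        if lab not in LOCATION_MAP:
            raise ValueError(f"unknown location label: {lab!r}")
        collapsed.add(LOCATION_MAP[lab])
    if not collapsed:
        raise ValueError("no location labels given")
    for cat in LOCATION_PRIORITY:
        if cat in collapsed:
            return cat
    raise AssertionError("unreachable")


@dataclass
class StratumAssignment:
    """Result of :func:`define_strata` for a set of SNPs."""

    stratum: pd.Series  # per SNP
    is_intergenic: pd.Series  # per SNP
    flanking_genes: dict[str, tuple[str | None, str | None]]  # intergenic stratum -> genes


def define_strata(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = FLANK_BP,
) -> StratumAssignment:
    """Assign every SNP to a gene stratum or an intergenic-interval stratum.

    A SNP within a gene span or its ``flank``-bp flanks belongs to that
    gene's stratum; when spans overlap, the gene with the nearest
    transcription start wins (ties broken lexicographically). All other
    SNPs share the stratum of their enclosing intergenic interval, each
    interval being its own stratum. ``genes`` needs columns
    gene/chrom/start/end and optionally tss (defaults to start).
    """
    genes = genes.copy()
    if "tss" not in genes.columns:
        genes["tss"] = genes["start"]
    strata = np.empty(len(snps), dtype=object)
    intergenic = np.zeros(len(snps), dtype=bool)
    flanks: dict[str, tuple[str | None, str | None]] = {}

    for chrom, snp_idx in snps.groupby("chrom", sort=False).groups.items():
        g = genes[genes["chrom"] == chrom].sort_values(["start", "gene"])
        pos = snps.loc[snp_idx, "pos"].to_numpy()
        starts = g["start"].to_numpy() - flank
        ends = g["end"].to_numpy() + flank
        names = g["gene"].to_numpy()
        tss = g["tss"].to_numpy()

        # gene assignment: nearest TSS among covering spans
        assigned = np.full(len(pos), None, dtype=object)
        for j, p in enumerate(pos):
            hits = np.where((starts <= p) & (p <= ends))[0]
            if hits.size == 1:
                assigned[j] = names[hits[0]]
            elif hits.size > 1:
                d = np.abs(tss[hits] - p)
                order = sorted(zip(d, names[hits]))  # distance, then symbol
                assigned[j] = order[0][1]

        # intergenic intervals: gaps between merged gene+flank spans
        merged: list[list] = []  # [start, end, last_gene]
        for s, e, n in zip(starts, ends, names):
            if merged and s <= merged[-1][1]:
                if e > merged[-1][1]:
                    merged[-1][1], merged[-1][2] = e, n
            else:
                merged.append([s, e, n])
        bounds = np.array([m[1] for m in merged]) if merged else np.array([])

        for j, (p, a) in enumerate(zip(pos, assigned)):
            i = snp_idx[j]
            if a is not None:
                strata[snps.index.get_loc(i)] = a
                continue
            k = int(np.searchsorted(bounds, p))  # interval after merged span k-1
            sid = f"{chrom}:IGR{k}"
            strata[snps.index.get_loc(i)] = sid
            intergenic[snps.index.get_loc(i)] = True
            left = merged[k - 1][2] if k > 0 else None
            right = merged[k][2] if k < len(merged) else None
            flanks[sid] = (left, right)

    return StratumAssignment(
        stratum=pd.Series(strata, index=snps.index),
        is_intergenic=pd.Series(intergenic, index=snps.index),
        flanking_genes=flanks,
    )


def go_sizes(gene_go: pd.DataFrame) -> pd.Series:
    """Category sizes (distinct genes) on the supplied gene universe."""
    return gene_go.drop_duplicates(["gene", "go"]).groupby("go")["gene"].nunique()


def singletize_go(
    gene_go: pd.DataFrame,
    sizes: pd.Series | None = None,
    target: int = GO_SIZE_TARGET,
    floor: int = GO_SIZE_FLOOR,
) -> pd.Series:
    """Reduce each gene's GO memberships to one label; small labels -> OTHER.

    Each gene takes the membership whose universe size is closest to
    ``target`` (ties to the smaller category, then lexicographic). After
    assignment, labels retaining <= ``floor`` genes are merged into OTHER,
    as are genes with no membership at all. Depends only on the size table,
    never on gene order.
    """
    if sizes is None:
        sizes = go_sizes(gene_go)

    def pick(gos: Iterable[str]) -> str:
        return min(gos, key=lambda g: (abs(sizes[g] - target), sizes[g], g))

    chosen = (
        gene_go.drop_duplicates(["gene", "go"])
        .groupby("gene")["go"]
        .agg(pick)
    )
    counts = chosen.value_counts()
    small = counts[counts <= floor].index
    if len(small):
        logger.info("GO singletization: %d categories merged into OTHER", len(small))
    return chosen.where(~chosen.isin(small), OTHER)


def gene_groups(
    gene_go: pd.DataFrame,
    group1: Sequence[str] = GROUP1_GO,
    group2: Sequence[str] = GROUP2_GO,
) -> pd.Series:
    """Hypothesis-testing group of each gene from its full GO memberships.

    Uses all memberships (not the singletized ones): a gene in any group-1
    category and any group-2 category is 'both'; genes in neither list are
    'neither'.
    """
    g1, g2 = set(group1), set(group2)
    in1 = gene_go[gene_go["go"].isin(g1)]["gene"].unique()
    in2 = gene_go[gene_go["go"].isin(g2)]["gene"].unique()
    genes = gene_go["gene"].unique()
    out = pd.Series("neither", index=pd.Index(genes, name="gene"))
    out[out.index.isin(in1)] = "group1"
    out[out.index.isin(in2)] = "group2"
    out[out.index.isin(set(in1) & set(in2))] = "both"
    return out


def assign_groups(
    stratum_assignment: StratumAssignment,
    groups_by_gene: pd.Series,
) -> pd.Series:
    """Per-SNP group labels; intergenic strata inherit the union of the
    groups of their two flanking genes."""

    def combine(a: str, b: str) -> str:
        s = {a, b} - {"neither"}
        if "both" in s or {"group1", "group2"} <= s:
            return "both"
        if s:
            return s.pop()
        return "neither"

    lookup = groups_by_gene.to_dict()
    out = []
    for stratum, inter in zip(
        stratum_assignment.stratum, stratum_assignment.is_intergenic
    ):
        if not inter:
            out.append(lookup.get(stratum, "neither"))
        else:
            left, right = stratum_assignment.flanking_genes[stratum]
            out.append(
                combine(
                    lookup.get(left, "neither") if left else "neither",
                    lookup.get(right, "neither") if right else "neither",
                )
            )
    return pd.Series(out, index=stratum_assignment.stratum.index)


def filter_empty_strata(
    dataset: pd.DataFrame,
    stratum_col: str = "stratum",
    case_col: str = "eqtl",
) -> pd.DataFrame:
    """Drop strata that carry no information for the conditional likelihood.

    Strata with zero flagged SNPs are removed (the published filtering
    rule); strata where every SNP is flagged are removed too, since their
    conditional likelihood contribution is a constant.
    """
    grp = dataset.groupby(stratum_col)[case_col]
    n_cases = grp.transform("sum")
    n = grp.transform("size")
    all_case = dataset.loc[n_cases == n, stratum_col].nunique()
    if all_case:
        logger.warning("%d all-case strata dropped (constant likelihood)", all_case)
    return dataset[(n_cases > 0) & (n_cases < n)].copy()
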