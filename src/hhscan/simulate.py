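"""Synthetic inputs with known truth for every stage of the pipeline.

The panel generator is deliberately coalescent-free: each region draws a
small pool of founder haplotypes, every chromosome copies one founder
(population-specific founder frequencies from a Dirichlet draw), and focal
markers are inserted on top. A neutral focal marker scatters its minor
allele over chromosomes independently of the founders; a swept marker
places a fraction ``sweep_purity`` of its minor-allele carriers on a single
founder haplotype, reproducing the conserved-haplotype footprint the
conditional-entropy score is built to detect. Regions live on separate
contigs, so windows never leak across region boundaries and a purity-1.0
sweep forces the conditional entropy to exactly zero.

Study tables are sampled from the same conditional-logistic model the
fitting code implements: within each stratum the case set is drawn with
probability proportional to exp(sum of linear predictors), so parameter
recovery tests face exactly the likelihood being maximised.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, write_panel_table, write_vcf

logger = logging.getLogger(__name__)

LOCATION_LEVELS = ["exonic", "UTR", "intronic", "flanking"]
RAW_LABELS = {
    "exonic": ["exonic", "ncRNA_exonic"],
    "UTR": ["UTR3", "UTR5"],
    "intronic": ["intronic", "splicing", "ncRNA_intronic"],
    "flanking": ["upstream", "downstream"],
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults emulate a handful of 1,000-Genomes-sized population samples
    (about a hundred chromosomes each) over gene-sized regions, with an
    eQTL rate of roughly one case per ten SNPs within a stratum.
    """

    seed: int  # mandatory: no unseeded simulation
    n_populations: int = 3
    samples_per_population: int = 50
    n_regions: int = 20
    sites_per_region: int = 120
    markers_per_region: int = 8
    pool_size: int = 12
    sweep_fraction: float = 0.2
    sweep_purity: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    # planted hypothesis-generation model (on transformed predictors)
    beta_hh: float = 0.3
    beta_maf: float = 0.5
    beta_ddaf: float = 0.2
    location_effects: Mapping[str, float] = field(
        default_factory=lambda: {"exonic": 0.5, "UTR": 0.3, "intronic": 0.0,
                                 "flanking": -0.2}
    )
    go_modifiers: Mapping[str, float] = field(default_factory=dict)
    n_go: int = 12
    cases_per_stratum: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig requires an explicit seed")
        if not 0.5 <= self.sweep_purity <= 1.0:
            raise ValueError("sweep purity must lie in [0.5, 1]")
        for name in ("n_populations", "samples_per_population", "n_regions",
                     "sites_per_region", "markers_per_region", "pool_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# panel simulation


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Generate a phased multi-population panel with planted sweeps.

    Returns the panel plus a truth table (marker, chrom, pos, region,
    sweep flag, target minor-allele frequency). Deterministic per seed.
    """
    if config.sites_per_region < 6:
        raise ValueError(
            "too few sites per region to form entropy windows; increase "
            "sites_per_region"
        )
    rng = np.random.default_rng(config.seed)
    pops = [f"POP{i}" for i in range(config.n_populations)]
    n_chrom = 2 * config.samples_per_population

    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    matrices: dict[str, list[np.ndarray]] = {p: [] for p in pops}
    truth_rows = []
    rs = itertools.count(1)

    for r in range(config.n_regions):
        contig = f"region{r}"
        pool = rng.integers(0, 2, size=(config.pool_size, config.sites_per_region),
                            dtype=np.int8)
        assignment = {}
        background = {}
        for p in pops:
            freqs = rng.dirichlet(np.ones(config.pool_size))
            assignment[p] = rng.choice(config.pool_size, size=n_chrom, p=freqs)
            background[p] = pool[assignment[p]]

        # focal markers at interior background slots, one new column each
        n_m = min(config.markers_per_region, config.sites_per_region - 2)
        slots = np.linspace(1, config.sites_per_region - 1, n_m + 2)[1:-1]
        slots = np.unique(slots.astype(int))
        is_sweep = rng.random(len(slots)) < config.sweep_fraction

        cols: dict[str, list[np.ndarray]] = {p: [] for p in pops}
        pos_step = rng.integers(20, 80, size=config.sites_per_region + len(slots))
        site_pos = np.cumsum(pos_step)
        region_chrom: list[str] = []
        region_pos: list[int] = []
        region_ids: list[str] = []

        marker_iter = iter(zip(slots, is_sweep))
        next_marker = next(marker_iter, None)
        out_col = 0
        for j in range(config.sites_per_region):
            if next_marker is not None and j == next_marker[0]:
                slot, sweep = next_marker
                marker = f"rs{next(rs)}"
                maf = rng.uniform(*config.maf_range)
                for p in pops:
                    cols[p].append(_focal_column(
                        rng, assignment[p], maf, sweep, config.sweep_purity
                    ))
                region_chrom.append(contig)
                region_pos.append(int(site_pos[out_col]))
                region_ids.append(marker)
                truth_rows.append({
                    "marker": marker, "chrom": contig,
                    "pos": int(site_pos[out_col]), "region": r,
                    "gene": f"gene{r}", "sweep": bool(sweep),
                    "maf": float(maf),
                })
                out_col += 1
                next_marker = next(marker_iter, None)
            for p in pops:
                cols[p].append(background[p][:, j])
            region_chrom.append(contig)
            region_pos.append(int(site_pos[out_col]))
            region_ids.append(".")
            out_col += 1

        chroms.extend(region_chrom)
        positions.extend(region_pos)
        ids.extend(region_ids)
        for p in pops:
            matrices[p].append(np.column_stack(cols[p]))

    n_sites = len(positions)
    panel = HaplotypePanel(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ids=np.asarray(ids, dtype=object),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        haplotypes={p: np.ascontiguousarray(np.concatenate(matrices[p], axis=1))
                    for p in pops},
        samples={p: [f"{p}_S{i}" for i in range(config.samples_per_population)]
                 for p in pops},
    )
    return panel, pd.DataFrame(truth_rows)


def _focal_column(rng: np.random.Generator, founders: np.ndarray, maf: float,
                  sweep: bool, purity: float) -> np.ndarray:
    """Minor-allele (ALT) assignment for one focal marker in one population."""
    n = len(founders)
    n_minor = max(1, min(n - 1, round(maf * n)))
    col = np.zeros(n, dtype=np.int8)
    if not sweep:
        carriers = rng.choice(n, size=n_minor, replace=False)
    else:
        # the minor variant arose on one founder background, so its carriers
        # cannot outnumber that background: prefer a founder large enough to
        # host them all, else shrink the carrier count to fit
        counts = np.bincount(founders)
        n_on = round(purity * n_minor)
        roomy = np.where(counts >= n_on)[0]
        top = roomy[counts[roomy].argmax()] if roomy.size else counts.argmax()
        if counts[top] < n_on:
            n_minor = max(1, int(counts[top] / purity))
            n_on = round(purity * n_minor)
        on_hap = np.where(founders == top)[0]
        off_hap = np.where(founders != top)[0]
        n_off = min(len(off_hap), n_minor - n_on)
        carriers = np.concatenate([
            rng.choice(on_hap, size=n_on, replace=False),
            rng.choice(off_hap, size=n_off, replace=False),
        ]).astype(int)
    col[carriers] = 1
    return col


def gene_table(config: SimConfig, panel: HaplotypePanel) -> pd.DataFrame:
    """One gene per region spanning that region's sites."""
    rows = []
    for r in range(config.n_regions):
        contig = f"region{r}"
        pos = panel.pos[panel.chrom == contig]
        rows.append({"gene": f"gene{r}", "chrom": contig,
                     "start": int(pos.min()), "end": int(pos.max()),
                     "tss": int(pos.min())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study simulation


def simulate_go_assignment(config: SimConfig, rng: np.random.Generator,
                           genes: list[str] | None = None) -> pd.Series:
    """Random singletized gene -> GO assignment over ``n_go`` categories."""
    if genes is None:
        genes = [f"gene{r}" for r in range(config.n_regions)]
    labels = [f"GO:{i:07d}" for i in range(1, config.n_go + 1)]
    picks = rng.choice(len(labels), size=len(genes))
    return pd.Series([labels[k] for k in picks],
                     index=pd.Index(genes, name="gene"))


def simulate_predictor_table(
    config: SimConfig,
    rng: np.random.Generator,
    hh: pd.Series | None = None,
    n_strata: int | None = None,
    snps_per_stratum: int | None = None,
) -> pd.DataFrame:
    """Per-SNP modelling table (stratum, gene, predictors, location).

    ``hh`` may come from scoring a simulated panel; otherwise standard
    normal scores stand in, which is the fast path for regression-scale
    simulations.
    """
    n_strata = n_strata or config.n_regions
    per = snps_per_stratum or config.markers_per_region
    rows = n_strata * per
    df = pd.DataFrame({
        "marker": [f"rs{i}" for i in range(1, rows + 1)],
        "stratum": np.repeat([f"gene{r}" for r in range(n_strata)], per),
        "gene": np.repeat([f"gene{r}" for r in range(n_strata)], per),
        "maf": rng.normal(size=rows),
        "ddaf": rng.normal(size=rows),
        "location": rng.choice(LOCATION_LEVELS, size=rows,
                               p=[0.1, 0.1, 0.6, 0.2]),
    })
    df["hh"] = (np.asarray(hh, dtype=float) if hh is not None
                else rng.normal(size=rows))
    return df


def simulate_study(
    table: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    go_assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """Draw eQTL flags from the planted conditional-logistic model.

    Within each stratum, a fixed number of cases is sampled with
    probability proportional to ``exp(eta)`` over case subsets, matching
    the exact conditional likelihood. The per-GO modifiers add to the
    score slope for genes in that category.
    """
    df = table.copy()
    if go_assignment is not None:
        df["go"] = df["gene"].map(go_assignment).fillna("OTHER")
    slope = np.full(len(df), config.beta_hh)
    if config.go_modifiers and "go" in df.columns:
        slope += df["go"].map(config.go_modifiers).fillna(0.0).to_numpy()
    eta = (slope * df["hh"].to_numpy()
           + config.beta_maf * df["maf"].to_numpy()
           + config.beta_ddaf * df["ddaf"].to_numpy()
           + df["location"].map(config.location_effects).fillna(0.0).to_numpy())

    flags = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("stratum", sort=False).groups.items():
        loc = df.index.get_indexer(idx)
        k = min(config.cases_per_stratum, len(loc) - 1)
        if k < 1:
            raise ValueError("stratum too small to hold a case and a control")
        chosen = _draw_cases(eta[loc], k, rng)
        flags[loc[chosen]] = True
    df["eqtl"] = flags
    return df


def _draw_cases(eta: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    e = eta - eta.max()
    if k == 1:
        w = np.exp(e)
        return np.array([rng.choice(len(eta), p=w / w.sum())])
    subsets = list(itertools.combinations(range(len(eta)), k))
    if len(subsets) > 200_000:
        raise ValueError("stratum too large for exact multi-case sampling")
    w = np.array([np.exp(e[list(s)].sum()) for s in subsets])
    return np.array(subsets[rng.choice(len(subsets), p=w / w.sum())])


# ---------------------------------------------------------------------------
# fixture emission


def emit_fixtures(config: SimConfig, out_dir: str | Path) -> dict:
    """Write the full input file set (VCF, tables, manifest) for one seed.

    Output is loadable by every reader in the package; the manifest records
    the seed and the planted truth so downstream checks never need to
    re-derive them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)

    panel, truth = simulate_panel(config)
    write_vcf(panel, out / "panel.vcf")
    write_panel_table(panel, out / "panel_samples.tsv")
    truth[["marker"]].to_csv(out / "focal_markers.tsv", sep="\t", index=False)
    genes = gene_table(config, panel)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)

    # selection-browser-style predictor export: per-population p-values/MAF
    pred = pd.DataFrame({"marker": truth["marker"]})
    for pop in panel.populations:
        freqs = panel.alt_frequency(pop)
        sites = panel.find_sites(truth["marker"])
        maf = np.array([min(freqs[sites[m]], 1 - freqs[sites[m]])
                        for m in truth["marker"]])
        pred[f"MAF.{pop}"] = maf
        for stat in ("dDAF", "absdDAF", "diHH", "Fst", "iHS"):
            base = rng.uniform(size=len(truth))
            # swept markers get systematically smaller p-values
            pred[f"{stat}.{pop}"] = np.where(truth["sweep"], base * 0.3, base)
    pred.to_csv(out / "predictors.tsv", sep="\t", index=False)

    annot = truth[["marker", "gene"]].copy()
    annot["location"] = [
        rng.choice(RAW_LABELS[loc])
        for loc in rng.choice(LOCATION_LEVELS, size=len(truth),
                              p=[0.1, 0.1, 0.6, 0.2])
    ]
    annot.to_csv(out / "annotations.tsv", sep="\t", index=False)

    assignment = simulate_go_assignment(config, rng)
    gene_go = assignment.rename("go").reset_index()
    gene_go.to_csv(out / "gene_go.tsv", sep="\t", index=False)

    study = simulate_predictor_table(config, rng,
                                     hh=-1.5 * truth["sweep"].to_numpy()
                                     + rng.normal(scale=0.5, size=len(truth)),
                                     n_strata=config.n_regions,
                                     snps_per_stratum=config.markers_per_region)
    study["marker"] = truth["marker"].to_numpy()[: len(study)]
    study = simulate_study(study, config, rng, go_assignment=assignment)
    eqtl = study[["marker", "eqtl"]].copy()
    eqtl.insert(1, "dataset", "sim1")
    eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()
                   if not isinstance(v, dict)},
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "truth": truth.to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
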