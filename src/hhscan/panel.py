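"""Phased haplotype panels and the tabular study inputs.

A :class:`HaplotypePanel` holds the biallelic-SNP haplotypes of one or more
population samples, one 0/1 matrix of chromosomes x sites per population.
Everything downstream (per-site entropies, variation-adjusted windows, the
conditional-entropy score) is computed independently within each population,
so the panel keeps populations as separate matrices rather than one big one.

Sites are filtered on load: only biallelic SNPs are kept, and within each
population any site with a missing or unphased call is masked out for that
population (entropy over partially observed haplotypes is undefined here).
Masked calls are stored as -1 so the original site grid stays shared across
populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: required columns per tabular input kind
SCHEMAS: dict[str, list[str]] = {
    "panel": ["sample", "population"],
    "markers": ["marker"],
    "predictors": ["marker"],
    "annotations": ["marker", "gene", "location"],
    "go": ["gene", "go"],
    "eqtl": ["marker", "dataset", "eqtl"],
    "genes": ["gene", "chrom", "start", "end"],
    "calibration": ["Population", "alpha", "beta_m", "beta_M"],
}


class PanelError(ValueError):
    """Raised when panel inputs violate the loading contract."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes partitioned by population.

    Parameters
    ----------
    chrom, pos, ids, ref, alt
        Per-site arrays (1-based VCF positions, strictly increasing within
        each chromosome).
    haplotypes
        population -> int8 matrix of shape (2 * n_samples, n_sites) with
        entries 0 (REF), 1 (ALT) or -1 (masked call).
    samples
        population -> ordered sample names; row ``2*i`` and ``2*i + 1`` of
        the matrix are the two phased chromosomes of sample ``i``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: dict[str, np.ndarray]
    samples: dict[str, list[str]]
    _masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.pos)
        for arr in (self.chrom, self.ids, self.ref, self.alt):
            if len(arr) != n:
                raise PanelError("site metadata arrays have inconsistent lengths")
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise PanelError(f"positions not strictly increasing on {chrom}")
        for pop, mat in self.haplotypes.items():
            if mat.shape != (2 * len(self.samples[pop]), n):
                raise PanelError(f"haplotype matrix shape mismatch for {pop}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def populations(self) -> list[str]:
        return list(self.haplotypes)

    def n_chromosomes(self, population: str) -> int:
        return self.haplotypes[population].shape[0]

    def site_mask(self, population: str) -> np.ndarray:
        """Boolean mask of sites fully called & phased in ``population``."""
        if population not in self._masks:
            mat = self.haplotypes[population]
            self._masks[population] = ~np.any(mat < 0, axis=0)
        return self._masks[population]

    def alt_frequency(self, population: str) -> np.ndarray:
        """ALT allele frequency per site (NaN where the site is masked)."""
        mat = self.haplotypes[population]
        with np.errstate(invalid="ignore"):
            f = np.where(self.site_mask(population), mat.mean(axis=0), np.nan)
        return f

    def global_alt_frequency(self) -> np.ndarray:
        """ALT frequency pooled over populations, per site, using only
        populations where the site is unmasked."""
        num = np.zeros(self.n_sites)
        den = np.zeros(self.n_sites)
        for pop, mat in self.haplotypes.items():
            m = self.site_mask(pop)
            num[m] += mat[:, m].sum(axis=0)
            den[m] += mat.shape[0]
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    def find_sites(self, identifiers: Iterable[str]) -> dict[str, int]:
        """Resolve rs IDs or ``chrom:pos`` strings to site indices.

        Unresolvable identifiers are simply absent from the result.
        """
        by_id = {i: k for k, i in enumerate(self.ids) if i not in (".", "", None)}
        by_locus = {f"{c}:{p}": k for k, (c, p) in enumerate(zip(self.chrom, self.pos))}
        out: dict[str, int] = {}
        for ident in identifiers:
            if ident in by_id:
                out[ident] = by_id[ident]
            elif ident in by_locus:
                out[ident] = by_locus[ident]
        return out


@dataclass
class FocalMarkerSet:
    """Score targets resolved against a panel (duplicates collapsed)."""

    markers: list[str]
    sites: np.ndarray  # panel site indices, aligned with ``markers``
    unresolved: list[str]

    @classmethod
    def from_identifiers(
        cls, identifiers: Iterable[str], panel: HaplotypePanel
    ) -> "FocalMarkerSet":
        idents = list(dict.fromkeys(identifiers))  # dedup, keep order
        resolved = panel.find_sites(idents)
        unresolved = [i for i in idents if i not in resolved]
        if unresolved:
            logger.warning(
                "%d focal markers absent from panel (skipped): %s ...",
                len(unresolved),
                unresolved[:5],
            )
        # collapse identifiers resolving to the same site
        seen: dict[int, str] = {}
        for ident in idents:
            if ident in resolved and resolved[ident] not in seen:
                seen[resolved[ident]] = ident
        return cls(
            markers=list(seen.values()),
            sites=np.fromiter(seen.keys(), dtype=np.int64, count=len(seen)),
            unresolved=unresolved,
        )

    def __len__(self) -> int:
        return len(self.markers)


# ---------------------------------------------------------------------------
# loading


def load_panel(
    vcf_source: str | Path,
    panel_table: str | Path | pd.DataFrame,
) -> HaplotypePanel:
    """Read a phased VCF plus a sample->population table into a panel.

    Non-SNP and multiallelic records are dropped (and counted); missing or
    unphased calls mask the site within the affected population only. Every
    sample named in the panel table must be present in the VCF.
    """
    from cyvcf2 import VCF

    if not isinstance(panel_table, pd.DataFrame):
        panel_table = load_table(panel_table, "panel")
    panel_table = panel_table.astype({"sample": str, "population": str})

    vcf = VCF(str(vcf_source))
    vcf_samples = set(vcf.samples)
    absent = [s for s in panel_table["sample"] if s not in vcf_samples]
    if absent:
        raise PanelError(f"samples in panel but not in VCF: {absent}")

    # subset the reader to the panel samples; cyvcf2 preserves VCF order,
    # so build the population row layout from the reader's own order
    wanted = list(dict.fromkeys(panel_table["sample"]))
    vcf = VCF(str(vcf_source), samples=wanted)
    order = {s: k for k, s in enumerate(vcf.samples)}
    pop_of = dict(zip(panel_table["sample"], panel_table["population"]))

    chroms: list[str] = []
    poss: list[int] = []
    ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []  # per site: (2 * n_samples,) int8 in reader order
    n_dropped = {"non_snp": 0, "multiallelic": 0, "duplicate_pos": 0}
    n_masked_calls = 0
    last_seen: dict[str, int] = {}

    for v in vcf:
        if len(v.ALT) != 1:
            n_dropped["multiallelic"] += 1
            continue
        if not v.is_snp:
            n_dropped["non_snp"] += 1
            continue
        if last_seen.get(v.CHROM, -1) >= v.POS:
            n_dropped["duplicate_pos"] += 1
            continue
        g = v.genotype.array()  # (n_samples, ploidy + 1); last col = phased flag
        alleles = g[:, :-1]
        phased = g[:, -1].astype(bool)
        col = alleles.astype(np.int8).reshape(-1)
        bad = (alleles < 0).any(axis=1) | ~phased | (alleles.shape[1] != 2)
        if bad.any():
            n_masked_calls += int(bad.sum())
            col = col.copy()
            col.reshape(-1, 2)[bad] = MISSING
        last_seen[v.CHROM] = v.POS
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ids.append(v.ID or ".")
        refs.append(v.REF)
        alts.append(v.ALT[0])
        columns.append(col)

    if not columns:
        raise PanelError("no usable biallelic SNP records in VCF")
    full = np.stack(columns, axis=1)  # (2 * n_samples, n_sites)

    haplotypes: dict[str, np.ndarray] = {}
    samples: dict[str, list[str]] = {}
    for pop in dict.fromkeys(panel_table["population"]):
        pop_samples = [s for s in vcf.samples if pop_of[s] == pop]
        rows = np.concatenate([[2 * order[s], 2 * order[s] + 1] for s in pop_samples])
        haplotypes[pop] = np.ascontiguousarray(full[rows])
        samples[pop] = pop_samples

    if any(n_dropped.values()) or n_masked_calls:
        logger.info(
            "panel load: dropped records %s; masked %d missing/unphased calls",
            n_dropped,
            n_masked_calls,
        )
    return HaplotypePanel(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ids=np.asarray(ids, dtype=object),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        haplotypes=haplotypes,
        samples=samples,
    )


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel back out as a minimal phased VCF (text, v4.2)."""
    pops = panel.populations
    sample_names = [s for p in pops for s in panel.samples[p]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        mats = [panel.haplotypes[p] for p in pops]
        for j in range(panel.n_sites):
            gts = []
            for mat in mats:
                col = mat[:, j]
                for i in range(0, len(col), 2):
                    a, b = col[i], col[i + 1]
                    gts.append(
                        f"{a}|{b}" if a >= 0 and b >= 0 else ".|."
                    )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_panel_table(panel: HaplotypePanel, path: str | Path) -> None:
    rows = [
        {"sample": s, "population": p}
        for p in panel.populations
        for s in panel.samples[p]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic tables


def load_table(
    path: str | Path, schema: str | Sequence[str] | None = None
) -> pd.DataFrame:
    """Read a headered TSV, enforcing the required columns of ``schema``.

    ``schema`` is a key of :data:`SCHEMAS` or an explicit column list;
    unknown columns are preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "marker": str})
    if schema is not None:
        required = SCHEMAS[schema] if isinstance(schema, str) else list(schema)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PanelError(
                f"table {path} is missing required column(s): {missing}"
            )
    return df


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    """Write scores as a BED-like genome-browser track
    (chrom, pos-1, pos, marker, score)."""
    cols = ["chrom", "start", "end", "marker", "hh"]
    track[cols].to_csv(path, sep="\t", index=False, header=False)
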