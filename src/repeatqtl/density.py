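"""Window-based polymorphism density and gene-region category summaries.

Strain-difference variants (SNPs, short indels, structural variants) are
summarised in two ways: per-category counts over a named gene-region model
(5' flank, UTRs, exons, introns, 3' flank) and a genome-wide tiling of
fixed-width windows (default 64 kb) reporting variants per kb, the mean
window density and the fraction of windows at or above a density threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "RegionModel",
    "RegionSummary",
    "DensityProfile",
    "load_variants",
    "read_genome_file",
    "region_summary",
    "window_density",
]

VARIANT_CLASSES = ("SNP", "indel", "SV")


@dataclass
class VariantTable:
    """Sorted records of (chromosome, 1-based position, class, nonsyn flag)."""

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records.copy()
        required = {"chrom", "pos", "class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"variant table missing column(s) {sorted(missing)}")
        df["chrom"] = df["chrom"].astype(str)
        pos = pd.to_numeric(df["pos"], errors="coerce")
        bad = df.index[pos.isna() | (pos < 1) | (pos != np.floor(pos))].tolist()
        if bad:
            raise ValueError(f"malformed position in row(s) {bad}")
        df["pos"] = pos.astype(int)
        if "nonsyn" not in df.columns:
            df["nonsyn"] = False
        df["nonsyn"] = df["nonsyn"].fillna(False).astype(bool)
        n0 = len(df)
        # decomposed multiallelic records carry an "alt" column so distinct
        # ALT alleles at one site are not treated as duplicates
        key = ["chrom", "pos", "class"] + (["alt"] if "alt" in df.columns else [])
        df = df.drop_duplicates(subset=key)
        if len(df) < n0:
            warnings.warn(f"collapsed {n0 - len(df)} duplicate variant record(s)")
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        cols = ["chrom", "pos", "class", "nonsyn"] + (["alt"] if "alt" in df.columns else [])
        self.records = df[cols]

    def __len__(self) -> int:
        return len(self.records)


def _classify_alleles(ref: str, alt: str) -> str:
    if alt.startswith("<") or alt in ("*",):
        return "SV"
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "indel"


def load_variants(path, fmt: str | None = None) -> VariantTable:
    """Load variants from an uncompressed VCF or a ``chrom,pos,class[,nonsyn]`` TSV.

    Multiallelic VCF records are decomposed to one record per ALT allele;
    records flagged with an SVTYPE INFO key (or a symbolic ALT) are counted
    as structural variants at their POS.
    """
    fmt = fmt or ("vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv")
    if fmt == "vcf":
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                alts = rec.alts or ()
                for alt in alts:
                    if "SVTYPE" in rec.info:
                        cls = "SV"
                    else:
                        cls = _classify_alleles(rec.ref or "", str(alt))
                    rows.append({"chrom": rec.chrom, "pos": rec.pos, "class": cls,
                                 "alt": str(alt)})
        return VariantTable(pd.DataFrame(rows, columns=["chrom", "pos", "class", "alt"]))
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return VariantTable(df)


def read_genome_file(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` genome file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {str(c): int(l) for c, l in zip(df["chrom"], df["length"])}


@dataclass
class RegionModel:
    """Named, categorised intervals (1-based inclusive) covering a locus."""

    intervals: pd.DataFrame  # columns: name, category, chrom, start, end

    def __post_init__(self):
        df = self.intervals.copy()
        required = {"category", "chrom", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"region model missing column(s) {sorted(missing)}")
        if "name" not in df.columns:
            df["name"] = df["category"]
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for c, grp in df.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on chromosome {c}")
        self.intervals = df

    @classmethod
    def from_bed(cls, path) -> "RegionModel":
        """BED-like TSV: chrom, start (0-based half-open), end, category[, name]."""
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = ["chrom", "start", "end", "category", "name"][: df.shape[1]]
        df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
        df["end"] = df["end"].astype(int)
        return cls(df)

    @property
    def span(self) -> tuple[str, int, int]:
        df = self.intervals
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("region model spans multiple chromosomes")
        return str(chroms[0]), int(df["start"].min()), int(df["end"].max())

    @property
    def span_kb(self) -> float:
        _, lo, hi = self.span
        return (hi - lo + 1) / 1000.0


@dataclass
class RegionSummary:
    """Per-category variant counts over a region model."""

    counts: dict[str, int]
    unassigned: int
    total: int
    span_kb: float
    density_per_kb: float
    nonsynonymous: int


def region_summary(variants: VariantTable, model: RegionModel) -> RegionSummary:
    """Count variants per region category; density = total / span size in kb.

    Variants inside the locus span but outside every category are counted
    under ``unassigned`` with a warning (the model should cover the span).
    The nonsynonymous sub-count covers variants flagged ``nonsyn`` that fall
    in a category named exonic.
    """
    chrom, lo, hi = model.span
    rec = variants.records
    rec = rec[(rec["chrom"] == chrom) & (rec["pos"] >= lo) & (rec["pos"] <= hi)]
    counts = {str(n): 0 for n in model.intervals["name"]}
    nonsyn = 0
    assigned = np.zeros(len(rec), dtype=bool)
    pos = rec["pos"].to_numpy()
    ns = rec["nonsyn"].to_numpy()
    for _, row in model.intervals.iterrows():
        inside = (pos >= row["start"]) & (pos <= row["end"])
        counts[str(row["name"])] += int(inside.sum())
        assigned |= inside
        if "exon" in str(row["category"]).lower():
            nonsyn += int((inside & ns).sum())
    unassigned = int((~assigned).sum())
    if unassigned:
        warnings.warn(f"{unassigned} variant(s) fall outside all region categories")
    total = int(len(rec))
    return RegionSummary(
        counts=counts,
        unassigned=unassigned,
        total=total,
        span_kb=model.span_kb,
        density_per_kb=total / model.span_kb,
        nonsynonymous=nonsyn,
    )


@dataclass
class DensityProfile:
    """Fixed-width window counts/densities plus genome summary statistics."""

    windows: pd.DataFrame  # chrom, start, end (half-open bp), count, density_per_kb
    width: int
    threshold_per_kb: float
    mean_density: float
    fraction_ge: float

    def fraction_at_or_above(self, threshold_per_kb: float) -> float:
        d = self.windows["density_per_kb"].to_numpy()
        return float((d >= threshold_per_kb).mean()) if len(d) else 0.0


def window_density(
    variants: VariantTable,
    genome: Mapping[str, int],
    width: int = 64_000,
    threshold_per_kb: float = 10.0,
    drop_partial: bool = False,
) -> DensityProfile:
    """Bin variants into half-open tiling windows [0, w), [w, 2w), ... per
    chromosome and report per-window densities.

    The terminal window of each chromosome is truncated at the chromosome
    length; its density uses the true (shorter) width unless
    ``drop_partial`` removes truncated windows entirely.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rec = variants.records
    for _, row in rec.iterrows():
        length = genome.get(row["chrom"])
        if length is None or row["pos"] > length:
            raise ValueError(
                f"variant {row['chrom']}:{row['pos']} beyond declared chromosome length"
            )
    rows = []
    for chrom in genome:
        length = int(genome[chrom])
        edges = np.arange(0, length + width, width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] <= edges[-2]:
            edges = edges[:-1]
        pos0 = rec.loc[rec["chrom"] == chrom, "pos"].to_numpy() - 1  # to 0-based
        counts, _ = np.histogram(pos0, bins=edges)
        for (s, e), c in zip(zip(edges[:-1], edges[1:]), counts):
            if drop_partial and e - s < width:
                continue
            rows.append(
                {"chrom": chrom, "start": int(s), "end": int(e), "count": int(c),
                 "density_per_kb": c / ((e - s) / 1000.0)}
            )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "count", "density_per_kb"]
    )
    dens = windows["density_per_kb"].to_numpy()
    return DensityProfile(
        windows=windows,
        width=width,
        threshold_per_kb=threshold_per_kb,
        mean_density=float(dens.mean()) if len(dens) else 0.0,
        fraction_ge=float((dens >= threshold_per_kb).mean()) if len(dens) else 0.0,
    )
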