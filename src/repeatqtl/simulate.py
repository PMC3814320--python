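"""Synthetic data: somatic repeat-expansion traces and F2 intercross cohorts.

Everything the pipeline consumes can be generated here with seeded,
bit-reproducible randomness:

* a phenomenological model of somatic CAG expansion — each cell accumulates
  a Poisson number of +1 CAG steps whose mean scales with age, a tissue
  factor, a modifier-genotype factor and optionally a fast-expanding cell
  subpopulation (which produces the bimodal length distributions seen in
  older striatum and liver);
* a PCR-stutter kernel convolved over the cell-population histogram to
  render a realistic fragment-analysis trace;
* an F2 intercross simulator: gametes are Markov chains over marker loci
  with Haldane recombination fractions (no interference), a single hidden
  modifier QTL generates the phenotype, and genotypes can be masked at a
  failure rate;
* a full study bundle wiring the two together: tail and striatum traces per
  animal, striatal instability index as the mapped trait, and the cross
  files for the scan.

Seeding: a single master seed; per-animal substreams are derived by animal
counter (``default_rng([seed, animal])``) so enlarging the cohort does not
reshuffle earlier animals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fragtrace import PeakTrace, Peak, batch_index, main_allele, instability_index
from .qtl import GENOTYPES, CrossData, GeneticMap, haldane_r

__all__ = [
    "MOUSE_CHROM_CM",
    "ExpansionModel",
    "StutterKernel",
    "QTLModel",
    "StudyConfig",
    "StudyBundle",
    "default_map",
    "simulate_cell_population",
    "render_trace",
    "simulate_gametes",
    "simulate_f2",
    "simulate_study",
    "synthetic_region_variants",
]

# Approximate genetic lengths (cM) of the mouse chromosomes; the X is
# simulated as autosomal for the scan (flagged here rather than handled
# specially).
MOUSE_CHROM_CM: dict[str, float] = {
    "1": 98.0, "2": 104.0, "3": 83.0, "4": 89.0, "5": 90.0, "6": 79.0,
    "7": 89.0, "8": 76.0, "9": 75.0, "10": 78.0, "11": 88.0, "12": 64.0,
    "13": 67.0, "14": 66.0, "15": 59.0, "16": 57.0, "17": 61.0, "18": 59.0,
    "19": 57.0, "X": 80.0,
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def default_map(n_markers: int = 147, chrom_cm: Mapping[str, float] | None = None) -> GeneticMap:
    """Uniformly spaced marker map over the mouse genome.

    Markers are apportioned to chromosomes proportionally to genetic length
    (largest-remainder rounding, at least two per chromosome) and spaced
    uniformly from 0 cM to the chromosome end.
    """
    lengths = dict(chrom_cm if chrom_cm is not None else MOUSE_CHROM_CM)
    chroms = list(lengths)
    total = sum(lengths.values())
    quota = {c: n_markers * lengths[c] / total for c in chroms}
    counts = {c: max(2, int(np.floor(quota[c]))) for c in chroms}
    while sum(counts.values()) < n_markers:
        c = max(chroms, key=lambda c: quota[c] - counts[c])
        counts[c] += 1
    while sum(counts.values()) > n_markers:
        c = min((c for c in chroms if counts[c] > 2), key=lambda c: quota[c] - counts[c])
        counts[c] -= 1
    rows = []
    for c in chroms:
        pos = np.linspace(0.0, lengths[c], counts[c])
        for j, p in enumerate(pos):
            rows.append({"marker": f"c{c}m{j + 1:02d}", "chrom": c, "cm": round(float(p), 4)})
    return GeneticMap(pd.DataFrame(rows))


@dataclass
class ExpansionModel:
    """Phenomenological somatic-expansion model.

    Each cell gains ``Poisson(rate_per_week * age_weeks * tissue_factor *
    genotype_factor * (fast_multiplier if fast))`` CAG units on top of the
    constitutive length; fast membership is Bernoulli(``fast_fraction``).
    Tail is near-stable (tissue factor 0), so tail traces carry only PCR
    stutter.
    """

    constitutive_length: int = 111
    rate_per_week: float = 0.30
    tissue_factor: dict[str, float] = field(
        default_factory=lambda: {"tail": 0.0, "striatum": 1.0, "liver": 0.8}
    )
    genotype_factor: dict[str, float] = field(
        default_factory=lambda: {"BB": 1.0, "BH": 1.0, "HH": 0.15}
    )
    fast_fraction: float = 0.0
    fast_multiplier: float = 5.0
    age_weeks: float = 10.0

    def __post_init__(self):
        if self.rate_per_week < 0:
            raise ValueError("rate_per_week must be >= 0")
        if not (0.0 <= self.fast_fraction <= 1.0):
            raise ValueError("fast_fraction must be in [0, 1]")
        for name, m in (("tissue_factor", self.tissue_factor),
                        ("genotype_factor", self.genotype_factor)):
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} values must be >= 0")
        if self.age_weeks < 0:
            raise ValueError("age_weeks must be >= 0")

    def mean_steps(self, tissue: str, genotype: str, rate_multiplier: float = 1.0) -> float:
        return (self.rate_per_week * self.age_weeks * self.tissue_factor[tissue]
                * self.genotype_factor[genotype] * rate_multiplier)


def simulate_cell_population(
    model: ExpansionModel,
    n_cells: int,
    seed=0,
    tissue: str = "striatum",
    genotype: str = "BB",
    rate_multiplier: float = 1.0,
) -> dict[int, int]:
    """Repeat-length histogram of a simulated cell population.

    Returns ``{repeat_length: cell count}``; with rate 0 the distribution is
    degenerate at the constitutive length.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed)
    lam = model.mean_steps(tissue, genotype, rate_multiplier)
    fast = rng.random(n_cells) < model.fast_fraction
    lams = np.where(fast, lam * model.fast_multiplier, lam)
    steps = rng.poisson(lams)
    lengths, counts = np.unique(model.constitutive_length + steps, return_counts=True)
    return {int(l): int(c) for l, c in zip(lengths, counts)}


@dataclass(frozen=True)
class StutterKernel:
    """PCR stutter: minor peak heights relative to the parent allele.

    ``minus_ratios[k-1]`` is the height of the peak k repeats shorter than
    its parent; ``plus_ratio`` the one-repeat-longer product.  Ratios decay
    with distance from the parent.
    """

    minus_ratios: tuple[float, ...] = (0.15, 0.04, 0.01)
    plus_ratio: float = 0.03

    def __post_init__(self):
        ratios = (*self.minus_ratios, self.plus_ratio)
        if any(not (0.0 <= r < 1.0) for r in ratios):
            raise ValueError("stutter ratios must be in [0, 1)")
        if any(a < b for a, b in zip(self.minus_ratios, self.minus_ratios[1:])):
            raise ValueError("minus_ratios must decay with distance from the parent")

    def weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(offsets, weights) of the kernel, parent at offset 0 with weight 1."""
        offsets = np.arange(-len(self.minus_ratios), 2)
        w = np.array([*reversed(self.minus_ratios), 1.0, self.plus_ratio])
        return offsets, w


def render_trace(
    histogram: Mapping[int, int],
    kernel: StutterKernel | None = None,
    noise_sd: float = 0.0,
    seed=0,
    sample_id: str = "sim",
    tissue: str = "striatum",
    max_height: float = 10_000.0,
    floor_frac: float = 0.01,
) -> PeakTrace:
    """Render a cell-length histogram as a fragment-analysis trace.

    The histogram is convolved with the stutter kernel, scaled to a maximum
    height of ``max_height``, perturbed with Gaussian noise (floored at 0,
    ``noise_sd`` in scaled intensity units) and peaks under ``floor_frac``
    of the maximum are dropped to bound the trace size.
    """
    if not histogram or sum(histogram.values()) == 0 or all(v == 0 for v in histogram.values()):
        raise ValueError("histogram is empty")
    kernel = kernel if kernel is not None else StutterKernel()
    rng = _rng(seed)
    lengths = np.array(sorted(histogram), dtype=int)
    counts = np.array([histogram[int(l)] for l in lengths], dtype=float)
    offsets, w = kernel.weights()
    lo = int(lengths.min() + offsets.min())
    hi = int(lengths.max() + offsets.max())
    signal = np.zeros(hi - lo + 1)
    for off, wt in zip(offsets, w):
        signal[lengths + off - lo] += wt * counts
    signal *= max_height / signal.max()
    if noise_sd > 0:
        signal = np.maximum(signal + rng.normal(0.0, noise_sd, signal.size), 0.0)
    keep = signal >= floor_frac * signal.max()
    peaks = tuple(
        Peak(int(lo + i), float(h)) for i, h in enumerate(signal) if keep[i]
    )
    return PeakTrace(sample_id=sample_id, tissue=tissue, peaks=peaks)


@dataclass
class QTLModel:
    """Single biallelic QTL in an F2 decomposition.

    The phenotype is ``mean + add_effect*x_add + dom_effect*x_dom +
    Normal(0, residual_sd)`` with x_add = +1/0/-1 for BB/BH/HH (counting B6
    alleles) and x_dom = 1 for heterozygotes.
    """

    chromosome: str = "9"
    position_cm: float = 37.5
    add_effect: float = 1.0
    dom_effect: float = 1.0
    residual_sd: float = float(np.sqrt(0.5))
    mean: float = 0.0

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")

    @property
    def genetic_variance(self) -> float:
        return self.add_effect ** 2 / 2.0 + self.dom_effect ** 2 / 4.0

    @property
    def heritability(self) -> float:
        g = self.genetic_variance
        return g / (g + self.residual_sd ** 2)


def simulate_gametes(positions_cm: np.ndarray, n_gametes: int, rng) -> np.ndarray:
    """F1 gametes over ordered loci: 0/1 strain-of-origin per locus.

    Each gamete starts from a fair coin and switches between adjacent loci
    with the Haldane recombination fraction for their spacing (a Markov
    chain; no crossover interference).
    """
    rng = _rng(rng)
    positions_cm = np.asarray(positions_cm, dtype=float)
    L = len(positions_cm)
    r = haldane_r(np.diff(positions_cm))
    g = np.empty((n_gametes, L), dtype=np.int8)
    g[:, 0] = rng.random(n_gametes) < 0.5
    for l in range(1, L):
        switch = rng.random(n_gametes) < r[l - 1]
        g[:, l] = g[:, l - 1] ^ switch
    return g


def _simulate_genotype_counts(
    gmap: GeneticMap, n: int, rng, extra_locus: tuple[str, float] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """B6-allele counts (n x markers, values 0/1/2); optionally an extra
    untyped locus (e.g. the QTL) whose counts are returned separately."""
    rng = _rng(rng)
    counts = np.empty((n, len(gmap)), dtype=np.int8)
    extra = None
    col = 0
    for chrom in gmap.chromosomes:
        ct = gmap.chrom_table(chrom)
        pos = ct["cm"].to_numpy()
        extra_idx = None
        if extra_locus is not None and extra_locus[0] == chrom:
            pos_all = np.append(pos, extra_locus[1])
            order = np.argsort(pos_all, kind="stable")
            extra_idx = int(np.nonzero(order == len(pos))[0][0])
            pos = pos_all[order]
        maternal = simulate_gametes(pos, n, rng)
        paternal = simulate_gametes(pos, n, rng)
        allele_counts = (1 - maternal) + (1 - paternal)  # count of B (allele 0)
        if extra_idx is not None:
            extra = allele_counts[:, extra_idx].copy()
            allele_counts = np.delete(allele_counts, extra_idx, axis=1)
        counts[:, col:col + allele_counts.shape[1]] = allele_counts
        col += allele_counts.shape[1]
    return counts, gmap.markers, extra


_COUNT_TO_GENO = {2: "BB", 1: "BH", 0: "HH"}


def _counts_to_frame(counts: np.ndarray, markers: list[str], ids: list[str]) -> pd.DataFrame:
    arr = np.empty(counts.shape, dtype=object)
    for c, g in _COUNT_TO_GENO.items():
        arr[counts == c] = g
    return pd.DataFrame(arr, index=ids, columns=markers)


def simulate_f2(
    gmap: GeneticMap,
    qtl: QTLModel,
    n_individuals: int,
    missing_rate: float = 0.0,
    seed=0,
) -> CrossData:
    """Simulate an F2 intercross segregating a single QTL.

    Gametes are simulated per chromosome as Markov chains over marker loci
    (Haldane recombination, no interference); the QTL genotype is drawn at
    its map position jointly with the markers; the phenotype follows the
    :class:`QTLModel` decomposition; genotypes are masked missing at
    ``missing_rate`` ("undetermined" genotype failures).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if qtl.chromosome not in gmap.chromosomes:
        raise KeyError(f"QTL chromosome {qtl.chromosome!r} not in map")
    rng = _rng(seed)
    at_marker = (
        (gmap.table["chrom"] == qtl.chromosome)
        & (np.isclose(gmap.table["cm"], qtl.position_cm))
    )
    extra = None if at_marker.any() else (qtl.chromosome, qtl.position_cm)
    counts, markers, extra_counts = _simulate_genotype_counts(
        gmap, n_individuals, rng, extra_locus=extra
    )
    if extra_counts is None:
        qtl_counts = counts[:, int(np.nonzero(at_marker.to_numpy())[0][0])].copy()
    else:
        qtl_counts = extra_counts
    x_add = qtl_counts.astype(float) - 1.0
    x_dom = (qtl_counts == 1).astype(float)
    y = (qtl.mean + qtl.add_effect * x_add + qtl.dom_effect * x_dom
         + rng.normal(0.0, qtl.residual_sd, n_individuals))
    ids = [f"F2_{i + 1:03d}" for i in range(n_individuals)]
    geno = _counts_to_frame(counts, markers, ids)
    if missing_rate > 0:
        mask = rng.random(counts.shape) < missing_rate
        vals = geno.to_numpy(dtype=object)
        vals[mask] = np.nan
        geno = pd.DataFrame(vals, index=ids, columns=markers)
    return CrossData(geno, gmap, pd.Series(y, index=ids))


# ---------------------------------------------------------------------------
# End-to-end study bundle


@dataclass
class StudyConfig:
    """Configuration of the synthetic instability-mapping study.

    Defaults emulate the mapped design: 69 F2 animals, 147 uniformly spaced
    markers, one dominant B6 modifier locus on chromosome 9 whose genotype
    scales the striatal expansion rate, tail + striatum traces per animal,
    and a lognormal per-animal biological rate multiplier calibrated so the
    locus explains about 60% of the striatal-index variance.
    """

    n_animals: int = 69
    n_markers: int = 147
    qtl_chrom: str = "9"
    qtl_pos_cm: float | None = None  # None -> middle marker of qtl_chrom
    missing_rate: float = 0.02
    expansion: ExpansionModel = field(default_factory=ExpansionModel)
    stutter: StutterKernel = field(default_factory=StutterKernel)
    noise_sd: float = 60.0
    n_cells: int = 1000
    bio_sigma: float = 0.32  # lognormal sigma of the per-animal rate multiplier
    constitutive_mean: float = 107.7
    constitutive_sd: float = 3.2
    tissues: tuple[str, ...] = ("tail", "striatum")

    def validate(self) -> None:
        errors = []
        if self.n_animals < 1:
            errors.append("n_animals: must be >= 1")
        if self.n_markers < len(MOUSE_CHROM_CM) * 2:
            errors.append("n_markers: need at least two markers per chromosome")
        if not (0.0 <= self.missing_rate < 1.0):
            errors.append("missing_rate: must be in [0, 1)")
        if self.n_cells < 1:
            errors.append("n_cells: must be >= 1")
        if self.bio_sigma < 0:
            errors.append("bio_sigma: must be >= 0")
        if "tail" not in self.tissues:
            errors.append("tissues: must include 'tail' (main-allele anchor)")
        if self.qtl_chrom not in MOUSE_CHROM_CM:
            errors.append(f"qtl_chrom: unknown chromosome {self.qtl_chrom!r}")
        if errors:
            raise ValueError("invalid study config: " + "; ".join(errors))

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["expansion"] = dataclasses.asdict(self.expansion)
        payload["stutter"] = dataclasses.asdict(self.stutter)
        payload["tissues"] = list(self.tissues)
        payload["stutter"]["minus_ratios"] = list(self.stutter.minus_ratios)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "expansion" in payload:
            payload["expansion"] = ExpansionModel(**payload["expansion"])
        if "stutter" in payload:
            payload["stutter"]["minus_ratios"] = tuple(payload["stutter"]["minus_ratios"])
            payload["stutter"] = StutterKernel(**payload["stutter"])
        if "tissues" in payload:
            payload["tissues"] = tuple(payload["tissues"])
        return cls(**payload)


@dataclass
class StudyBundle:
    """Everything simulate_study produces: traces, indices, cross, metadata."""

    config: StudyConfig
    seed: int
    gmap: GeneticMap
    qtl_marker: str
    traces: list[PeakTrace]
    indices: pd.DataFrame
    cross: CrossData
    qtl_genotypes: pd.Series
    constitutive: pd.Series

    def peak_table(self) -> pd.DataFrame:
        rows = [
            {"sample": t.sample_id, "tissue": t.tissue, "size": p.repeat_length,
             "height": round(p.height, 6), "unit": "repeat"}
            for t in self.traces for p in t.peaks
        ]
        return pd.DataFrame(rows)


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyBundle:
    """Simulate the full study: traces per animal, indices, cross for the scan.

    The modifier locus is snapped to the nearest marker on its chromosome so
    the planted QTL is fully typed; its genotype scales the striatal
    expansion rate through ``ExpansionModel.genotype_factor`` (B6-dominant
    by default: BB and BH expand alike, HH is strongly reduced).  The
    striatal instability index, computed by the same code that analyses
    real traces, becomes the mapped phenotype.
    """
    config = config if config is not None else StudyConfig()
    config.validate()
    gmap = default_map(config.n_markers)
    ct = gmap.chrom_table(config.qtl_chrom)
    target = config.qtl_pos_cm
    if target is None:
        qrow = ct.iloc[len(ct) // 2]
    else:
        qrow = ct.iloc[int(np.argmin(np.abs(ct["cm"].to_numpy() - target)))]
    qtl_marker, qtl_pos = str(qrow["marker"]), float(qrow["cm"])

    n = config.n_animals
    ids = [f"F2_{i + 1:03d}" for i in range(n)]
    counts = np.empty((n, len(gmap)), dtype=np.int8)
    traces: list[PeakTrace] = []
    qtl_geno: list[str] = []
    constitutive: list[int] = []
    masks = np.empty((n, len(gmap)), dtype=bool)
    qcol = gmap.markers.index(qtl_marker)
    for i, ind in enumerate(ids):
        rng_i = np.random.default_rng([seed, i])
        row, _, _ = _simulate_genotype_counts(gmap, 1, rng_i)
        counts[i] = row[0]
        geno = _COUNT_TO_GENO[int(counts[i, qcol])]
        qtl_geno.append(geno)
        cag = int(np.rint(rng_i.normal(config.constitutive_mean, config.constitutive_sd)))
        constitutive.append(cag)
        bio = float(np.exp(rng_i.normal(0.0, config.bio_sigma)))
        model = dataclasses.replace(config.expansion, constitutive_length=cag)
        for tissue in config.tissues:
            hist = simulate_cell_population(
                model, config.n_cells, rng_i, tissue=tissue, genotype=geno,
                rate_multiplier=bio,
            )
            traces.append(
                render_trace(hist, config.stutter, noise_sd=config.noise_sd,
                             seed=rng_i, sample_id=ind, tissue=tissue)
            )
        masks[i] = rng_i.random(len(gmap)) < config.missing_rate

    indices = batch_index(traces, tail_tissue="tail")
    striatal = (
        indices[indices["tissue"] == "striatum"].set_index("sample")["index"]
    ).reindex(ids)

    geno = _counts_to_frame(counts, gmap.markers, ids)
    if config.missing_rate > 0:
        vals = geno.to_numpy(dtype=object)
        vals[masks] = np.nan
        geno = pd.DataFrame(vals, index=ids, columns=gmap.markers)
    cross = CrossData(geno, gmap, striatal)
    return StudyBundle(
        config=config, seed=seed, gmap=gmap, qtl_marker=qtl_marker,
        traces=traces, indices=indices, cross=cross,
        qtl_genotypes=pd.Series(qtl_geno, index=ids),
        constitutive=pd.Series(constitutive, index=ids),
    )


def synthetic_region_variants(
    intervals: Sequence[tuple[str, str, int, int, int]], seed: int = 0
) -> pd.DataFrame:
    """Synthetic variant table with a fixed count per genomic interval.

    ``intervals`` rows are ``(chrom, category, start, end, count)`` with
    1-based inclusive bounds; ``count`` distinct positions are drawn
    uniformly within each interval.  Used to build stand-in variant sets
    whose per-category totals are known by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, category, start, end, count in intervals:
        span = end - start + 1
        if count > span:
            raise ValueError(f"cannot place {count} distinct variants in {span} bp")
        pos = rng.choice(span, size=count, replace=False) + start
        for p in np.sort(pos):
            rows.append({"chrom": chrom, "pos": int(p), "class": "SNP",
                         "nonsyn": False, "category": category})
    return pd.DataFrame(rows, columns=["chrom", "pos", "class", "nonsyn", "category"])
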