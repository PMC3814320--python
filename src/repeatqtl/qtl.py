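"""Single-QTL genome scan for an F2 intercross.

An F2 intercross between two inbred strains (here labelled B = C57BL/6 and
H = 129) segregates genotypes BB : BH : HH at 1:2:1 at every autosomal
locus.  A quantitative trait measured on the F2 animals can be mapped by
fitting, at each genomic position, the single-locus model

    y = mu + a * x_add + d * x_dom + eps

with x_add = +1/0/-1 for BB/BH/HH and x_dom = 1 for heterozygotes, against
the null model y = mu + eps.  The evidence for a QTL is expressed as a LOD
score, LOD = (n/2) * log10(RSS0 / RSS1), and the variance explained at a
position relates to the LOD through R^2 = 1 - 10^(-2*LOD/n).

Between and at partially informative markers the genotype is not observed;
expected genotype indicators are computed by a forward-backward pass over a
three-state Markov chain whose transition probabilities come from the
Haldane map function (no crossover interference), and the model is fitted
on the expectations (Haley-Knott regression).  A 2-LOD drop-off from the
peak, delimited by flanking markers, serves as an approximate 95% support
interval for QTL location.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "GeneticMap",
    "CrossData",
    "GenotypeProbabilities",
    "IntercrossModel",
    "ScanResults",
    "SupportInterval",
    "DominanceReport",
    "haldane_r",
    "f2_transition_matrix",
    "genotype_probabilities",
    "scan",
    "support_interval",
    "permutation_threshold",
    "dominance_assessment",
    "lod_from_r2",
    "r2_from_lod",
]

GENOTYPES = ("BB", "BH", "HH")
_GENO_INDEX = {g: i for i, g in enumerate(GENOTYPES)}
F2_PRIOR = np.array([0.25, 0.5, 0.25])

# R/qtl-style single-letter codes used in cross CSV files.
_CSV_CODE = {"BB": "B", "BH": "H", "HH": "A"}
_CSV_DECODE = {v: k for k, v in _CSV_CODE.items()}


def _encode(arr: np.ndarray) -> np.ndarray:
    """Genotype strings -> state indices (BB=0, BH=1, HH=2); NaN for missing."""
    codes = np.full(arr.shape, np.nan)
    for g, i in _GENO_INDEX.items():
        codes[arr == g] = float(i)
    return codes


def haldane_r(d_cm):
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def f2_transition_matrix(r: float) -> np.ndarray:
    """Transition matrix of F2 genotypes (BB, BH, HH) between linked loci.

    The two gametes recombine independently with probability ``r``, so the
    genotype chain is the lumped product of two two-state chains.
    """
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def lod_from_r2(r2: float, n: int) -> float:
    """LOD score implied by a least-squares R^2 at sample size n."""
    return -(n / 2.0) * np.log10(1.0 - r2)


def r2_from_lod(lod: float, n: int) -> float:
    """Variance explained implied by a LOD score at sample size n."""
    return 1.0 - 10.0 ** (-2.0 * lod / n)


class GeneticMap:
    """Ordered marker map: names, chromosome, position in cM, optional bp.

    Chromosome order follows first appearance in the input table; positions
    must be non-decreasing within a chromosome and marker names unique.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "cm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"marker table missing column(s) {sorted(missing)}")
        table = table.copy()
        table["marker"] = table["marker"].astype(str)
        table["chrom"] = table["chrom"].astype(str)
        table["cm"] = table["cm"].astype(float)
        if "bp" not in table.columns:
            table["bp"] = np.nan
        if table["marker"].duplicated().any():
            dups = table.loc[table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker name(s) {dups}")
        order = list(dict.fromkeys(table["chrom"]))
        for c in order:
            pos = table.loc[table["chrom"] == c, "cm"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"marker positions not sorted on chromosome {c}")
        self.table = table.reset_index(drop=True)
        self._order = order

    @property
    def chromosomes(self) -> list[str]:
        return list(self._order)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == str(chrom)]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub

    def position(self, marker: str) -> tuple[str, float]:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return str(row["chrom"].iloc[0]), float(row["cm"].iloc[0])

    def bp(self, marker: str) -> float:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return float(row["bp"].iloc[0])

    @classmethod
    def read_marker_table(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower().replace("cm", "cm") for c in df.columns]
        df = df.rename(columns={"cM".lower(): "cm"})
        return cls(df)

    def write_marker_table(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)


class CrossData:
    """F2 genotype matrix, genetic map and phenotype vector.

    ``genotypes`` is individuals x markers with entries in {"BB", "BH",
    "HH"} or NaN for a failed ("undetermined") genotype.  ``phenotype``
    aligns with the genotype rows; NaN phenotypes are dropped at fit time.
    """

    def __init__(self, genotypes: pd.DataFrame, gmap: GeneticMap, phenotype: pd.Series):
        if list(genotypes.columns) != gmap.markers:
            genotypes = genotypes.reindex(columns=gmap.markers)
            if genotypes.isna().all().any():
                raise ValueError("genotype matrix columns do not match the genetic map")
        phenotype = pd.Series(phenotype, index=genotypes.index, dtype=float)
        vals = pd.unique(genotypes.values.ravel())
        bad = [v for v in vals if isinstance(v, str) and v not in GENOTYPES]
        if bad:
            raise ValueError(f"unknown genotype code(s) {bad}")
        finite = phenotype.dropna()
        if len(finite) and not np.isfinite(finite.to_numpy()).all():
            raise ValueError("phenotype contains non-finite values")
        self.genotypes = genotypes
        self.map = gmap
        self.phenotype = phenotype

    @property
    def individuals(self) -> list:
        return list(self.genotypes.index)

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def geno_codes(self) -> np.ndarray:
        """Genotype codes as floats: BB=0, BH=1, HH=2 (state index), NaN missing."""
        return _encode(self.genotypes.to_numpy(dtype=object))

    def to_rqtl_csv(self, path, phenotype_name: str = "instability_index") -> None:
        """Write an R/qtl-style cross CSV (id + phenotype, then markers)."""
        gmap = self.map.table
        header1 = ["id", phenotype_name] + gmap["marker"].tolist()
        header2 = ["", ""] + gmap["chrom"].tolist()
        header3 = ["", ""] + [f"{x:g}" for x in gmap["cm"]]
        lines = [",".join(header1), ",".join(header2), ",".join(header3)]
        for ind, row in self.genotypes.iterrows():
            codes = [
                _CSV_CODE[v] if isinstance(v, str) else "-" for v in row.to_numpy()
            ]
            ph = self.phenotype.loc[ind]
            lines.append(",".join([str(ind), "" if pd.isna(ph) else f"{ph:.6g}"] + codes))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read_rqtl_csv(cls, path) -> "CrossData":
        raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
        header = raw.iloc[0].tolist()
        chroms = raw.iloc[1].tolist()
        cms = raw.iloc[2].tolist()
        # phenotype/id columns have blank chromosome rows
        marker_cols = [j for j in range(len(header)) if chroms[j] != ""]
        meta_cols = [j for j in range(len(header)) if chroms[j] == ""]
        if not meta_cols:
            raise ValueError(f"{path}: no id/phenotype column found")
        id_col = meta_cols[0]
        pheno_col = meta_cols[1] if len(meta_cols) > 1 else None
        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "marker": [header[j] for j in marker_cols],
                    "chrom": [chroms[j] for j in marker_cols],
                    "cm": [float(cms[j]) for j in marker_cols],
                }
            )
        )
        body = raw.iloc[3:]
        ids = body.iloc[:, id_col].tolist()
        geno_arr = body.iloc[:, marker_cols].to_numpy(dtype=object)
        decoded = np.vectorize(
            lambda v: _CSV_DECODE.get(str(v).strip(), np.nan), otypes=[object]
        )(geno_arr)
        geno = pd.DataFrame(decoded, columns=gmap.markers, index=ids)
        if pheno_col is not None:
            ph = pd.Series(
                [float(v) if v.strip() not in ("", "-", "NA") else np.nan
                 for v in body.iloc[:, pheno_col]],
                index=ids,
            )
        else:
            ph = pd.Series(np.nan, index=ids)
        return cls(geno, gmap, ph)


@dataclass
class GenotypeProbabilities:
    """Per-chromosome grids of P(genotype) for every individual.

    ``positions[c]`` is the cM grid (markers plus pseudomarkers),
    ``probs[c]`` has shape (n_individuals, n_positions, 3) over (BB, BH,
    HH), and ``marker_at[c]`` names the marker at grid points that coincide
    with markers ("" elsewhere).
    """

    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    probs: dict[str, np.ndarray]
    marker_at: dict[str, list[str]]
    individuals: list


def _chrom_grid(marker_pos: np.ndarray, step_cm: float) -> np.ndarray:
    lo, hi = marker_pos[0], marker_pos[-1]
    grid = np.arange(lo, hi + 1e-9, step_cm) if hi > lo else np.array([lo])
    merged = np.union1d(np.round(grid, 9), np.round(marker_pos, 9))
    return merged


def genotype_probabilities(
    cross: CrossData, step_cm: float = 1.0, individuals: Sequence | None = None
) -> GenotypeProbabilities:
    """Conditional F2 genotype probabilities on a cM grid.

    At an observed marker the probability mass sits on the observed class;
    elsewhere probabilities are conditioned on all informative markers of
    the chromosome through a forward-backward pass over the three-state
    genotype chain with Haldane transitions (equivalent to conditioning on
    the nearest informative flanking markers, the chain being Markov).
    Individuals with no data on a chromosome get the 1/4:1/2:1/4 prior.
    """
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    inds = list(individuals) if individuals is not None else cross.individuals
    sub = cross.genotypes.loc[inds]
    out_pos: dict[str, np.ndarray] = {}
    out_probs: dict[str, np.ndarray] = {}
    out_marker: dict[str, list[str]] = {}
    chroms: list[str] = []
    for chrom in cross.map.chromosomes:
        ct = cross.map.chrom_table(chrom)
        if ct.empty:  # pragma: no cover - map constructor forbids this
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        mpos = ct["cm"].to_numpy()
        mnames = ct["marker"].tolist()
        grid = _chrom_grid(mpos, step_cm)
        P = len(grid)
        n = len(inds)
        # map each marker to its grid index
        gidx = {round(p, 9): i for i, p in enumerate(grid)}
        marker_at = [""] * P
        obs = np.full((n, P), np.nan)
        codes = _encode(sub[mnames].to_numpy(dtype=object))
        for j, p in enumerate(np.round(mpos, 9)):
            marker_at[gidx[p]] = mnames[j]
            obs[:, gidx[p]] = codes[:, j]

        emis = np.ones((n, P, 3))
        seen = ~np.isnan(obs)
        if seen.any():
            ii, pp = np.nonzero(seen)
            emis[ii, pp, :] = 0.0
            emis[ii, pp, obs[ii, pp].astype(int)] = 1.0

        T = [f2_transition_matrix(float(haldane_r(grid[t + 1] - grid[t]))) for t in range(P - 1)]

        alpha = np.empty((n, P, 3))
        a = F2_PRIOR[None, :] * emis[:, 0, :]
        norm = a.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        alpha[:, 0, :] = a / norm
        for t in range(1, P):
            a = (alpha[:, t - 1, :] @ T[t - 1]) * emis[:, t, :]
            norm = a.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            alpha[:, t, :] = a / norm
        beta = np.empty((n, P, 3))
        beta[:, P - 1, :] = 1.0
        for t in range(P - 2, -1, -1):
            b = (emis[:, t + 1, :] * beta[:, t + 1, :]) @ T[t].T
            norm = b.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            beta[:, t, :] = b / norm
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)

        chroms.append(chrom)
        out_pos[chrom] = grid
        out_probs[chrom] = post
        out_marker[chrom] = marker_at
    return GenotypeProbabilities(chroms, out_pos, out_probs, out_marker, inds)


@dataclass(frozen=True)
class SupportInterval:
    """Marker-delimited LOD support interval around a scan peak."""

    chrom: str
    left_marker: str
    right_marker: str
    cm_lo: float
    cm_hi: float
    bp_lo: float | None
    bp_hi: float | None
    peak_lod: float
    r2: float
    drop: float = 2.0

    @property
    def width_cm(self) -> float:
        return self.cm_hi - self.cm_lo

    @property
    def physical_width_mb(self) -> float | None:
        """Width of the physical interval in Mb (1-based inclusive bounds)."""
        if self.bp_lo is None or self.bp_hi is None:
            return None
        return (self.bp_hi - self.bp_lo + 1) / 1e6

    def to_json(self, path=None) -> str:
        payload = {
            "chrom": self.chrom,
            "left_marker": self.left_marker,
            "right_marker": self.right_marker,
            "cM_lo": self.cm_lo,
            "cM_hi": self.cm_hi,
            "bp_lo": self.bp_lo,
            "bp_hi": self.bp_hi,
            "peak_lod": self.peak_lod,
            "r2": self.r2,
            "drop": self.drop,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class DominanceReport:
    """Genotype-class means at a marker and the implied mode of inheritance."""

    marker: str
    class_n: dict[str, int]
    class_means: dict[str, float]
    class_sd: dict[str, float]
    a_hat: float | None
    d_hat: float | None
    classification: str


class ScanResults:
    """Results of a single-QTL genome scan.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per grid position: ``chrom, pos_cm, marker, lod, mu_hat,
        a_hat, d_hat, n``.
    n_used : int
        Individuals with a phenotype that entered the scan.
    """

    def __init__(self, table: pd.DataFrame, n_used: int, method: str, cross: CrossData):
        self.table = table.reset_index(drop=True)
        self.n_used = n_used
        self.method = method
        self._cross = cross

    # -- peak ----------------------------------------------------------------
    @property
    def peak(self) -> pd.Series:
        t = self.table
        best = t["lod"].max()
        hits = t[t["lod"] == best]
        if len(hits) > 1:
            warnings.warn("LOD peak tied across positions; using the first (lowest cM)")
        return hits.iloc[0]

    @property
    def peak_lod(self) -> float:
        return float(self.peak["lod"])

    @property
    def r2_peak(self) -> float:
        """Least-squares variance explained at the peak (== LOD-implied R^2)."""
        return r2_from_lod(self.peak_lod, int(self.peak["n"]))

    def r2_from_lod_at_peak(self) -> float:
        return r2_from_lod(self.peak_lod, int(self.peak["n"]))

    # -- reporting -----------------------------------------------------------
    def support_interval(self, drop: float = 2.0) -> SupportInterval:
        return support_interval(self, drop=drop)

    def summary(self) -> str:
        pk = self.peak
        si = self.support_interval()
        lines = [
            "Single-QTL genome scan (F2 intercross)",
            "=" * 54,
            f"Method:               {self.method}",
            f"Individuals used:     {self.n_used}",
            f"Positions scanned:    {len(self.table)}",
            f"Peak LOD:             {self.peak_lod:.2f}",
            f"Peak position:        chr{pk['chrom']} @ {pk['pos_cm']:.1f} cM"
            + (f" ({pk['marker']})" if pk["marker"] else ""),
            f"Variance explained:   {100 * self.r2_peak:.1f}%  (R^2 = 1 - 10^(-2 LOD/n))",
            f"Effects at peak:      mu = {pk['mu_hat']:.3f}, a = {pk['a_hat']:.3f}, d = {pk['d_hat']:.3f}",
            f"{si.drop:.0f}-LOD support:        chr{si.chrom} {si.left_marker} .. {si.right_marker} "
            f"({si.cm_lo:.1f}-{si.cm_hi:.1f} cM)",
        ]
        if si.physical_width_mb is not None and np.isfinite(si.physical_width_mb):
            lines.append(
                f"Physical interval:    {si.bp_lo:,.0f}-{si.bp_hi:,.0f} bp "
                f"({si.physical_width_mb:.2f} Mb)"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["chrom", "pos_cm", "marker", "lod", "mu_hat", "a_hat", "d_hat", "n"]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot(self, ax=None, threshold: float | None = 4.3):
        """LOD profile against cumulative map position, one panel genome-wide."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        ticks, labels = [], []
        for chrom in self._cross.map.chromosomes:
            sub = self.table[self.table["chrom"] == chrom]
            if sub.empty:
                continue
            x = sub["pos_cm"].to_numpy() + offset
            ax.plot(x, sub["lod"].to_numpy(), lw=1.2)
            ticks.append(offset + sub["pos_cm"].mean())
            labels.append(chrom)
            offset = x.max() + 5.0
        if threshold is not None:
            ax.axhline(threshold, color="red", ls="--", lw=0.8)
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("LOD")
        return ax


def _fit_positions(y: np.ndarray, xa: np.ndarray, xd: np.ndarray):
    """Least-squares fit of y ~ 1 + xa + xd at each column of xa/xd.

    Returns (lod_numerator ratio pieces) as arrays: mu, a, d, rss1.
    ``xa``/``xd`` have shape (n, P).
    """
    n, P = xa.shape
    ones = np.ones(n)
    mu = np.empty(P)
    a = np.empty(P)
    d = np.empty(P)
    rss1 = np.empty(P)
    for j in range(P):
        X = np.column_stack([ones, xa[:, j], xd[:, j]])
        coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        rss1[j] = float(np.sum((y - fitted) ** 2))
        mu[j], a[j], d[j] = coef
    return mu, a, d, rss1


def scan(cross: CrossData, method: str = "hk", step_cm: float = 1.0) -> ScanResults:
    """Genome scan; see :class:`IntercrossModel` for the model definition.

    ``method="hk"`` fits on expected genotype indicators from
    :func:`genotype_probabilities` over a grid of markers plus pseudomarkers;
    ``method="marker"`` fits genotype-class regression at typed markers only,
    dropping individuals untyped at each marker.
    """
    return IntercrossModel(cross).fit(method=method, step_cm=step_cm)


class IntercrossModel:
    """Single-QTL model for an F2 intercross phenotype.

    The full model at a position is ``y = mu + a*x_add + d*x_dom + eps``
    (2 df: additive plus dominance, the free model of classical interval
    mapping); the null is ``y = mu + eps``.  ``fit`` performs the genome
    scan and returns :class:`ScanResults`.
    """

    def __init__(self, cross: CrossData):
        self.cross = cross
        keep = cross.phenotype.notna()
        self._inds = [i for i, k in zip(cross.individuals, keep) if k]
        # >= 10 phenotyped individuals recommended for any real scan; tiny
        # crosses down to 8 are permitted for exact-arithmetic checks.
        if len(self._inds) < 8:
            raise ValueError(
                f"need >= 8 phenotyped individuals, have {len(self._inds)}"
            )
        self._y = cross.phenotype.loc[self._inds].to_numpy(dtype=float)

    @property
    def n_used(self) -> int:
        return len(self._inds)

    def fit(self, method: str = "hk", step_cm: float = 1.0) -> ScanResults:
        if method not in ("hk", "marker"):
            raise ValueError(f"method must be 'hk' or 'marker', got {method!r}")
        y = self._y
        n = len(y)
        rss0_full = float(np.sum((y - y.mean()) ** 2))
        constant = rss0_full <= 0.0
        if constant:
            warnings.warn("phenotype is constant; LOD defined as 0 everywhere")

        rows = []
        if method == "hk":
            gp = genotype_probabilities(self.cross, step_cm=step_cm, individuals=self._inds)
            for chrom in gp.chromosomes:
                probs = gp.probs[chrom]
                xa = probs[:, :, 0] - probs[:, :, 2]
                xd = probs[:, :, 1]
                if constant:
                    P = xa.shape[1]
                    mu = np.full(P, y.mean())
                    a = np.zeros(P)
                    d = np.zeros(P)
                    lod = np.zeros(P)
                else:
                    mu, a, d, rss1 = _fit_positions(y, xa, xd)
                    rss1 = np.maximum(rss1, np.finfo(float).tiny)
                    lod = (n / 2.0) * np.log10(rss0_full / rss1)
                    lod = np.maximum(lod, 0.0)
                for j, pos in enumerate(gp.positions[chrom]):
                    rows.append(
                        (chrom, float(pos), gp.marker_at[chrom][j], float(lod[j]),
                         float(mu[j]), float(a[j]), float(d[j]), n)
                    )
        else:
            geno = self.cross.genotypes.loc[self._inds]
            for chrom in self.cross.map.chromosomes:
                ct = self.cross.map.chrom_table(chrom)
                for marker, pos in zip(ct["marker"], ct["cm"]):
                    g = geno[marker]
                    typed = g.notna().to_numpy()
                    yt = y[typed]
                    nt = int(typed.sum())
                    if nt < 3 or constant or np.ptp(yt) == 0:
                        rows.append((chrom, float(pos), marker, 0.0,
                                     float(yt.mean()) if nt else np.nan, 0.0, 0.0, nt))
                        continue
                    codes = g[typed].map(_GENO_INDEX).to_numpy(dtype=float)
                    xa = (1.0 - codes)[:, None]  # BB=+1, BH=0, HH=-1
                    xd = (codes == 1).astype(float)[:, None]
                    mu, a, d, rss1 = _fit_positions(yt, xa, xd)
                    rss0 = float(np.sum((yt - yt.mean()) ** 2))
                    rss1 = max(float(rss1[0]), np.finfo(float).tiny)
                    lod = max((nt / 2.0) * np.log10(rss0 / rss1), 0.0)
                    rows.append((chrom, float(pos), marker, float(lod),
                                 float(mu[0]), float(a[0]), float(d[0]), nt))

        table = pd.DataFrame(
            rows, columns=["chrom", "pos_cm", "marker", "lod", "mu_hat", "a_hat", "d_hat", "n"]
        )
        return ScanResults(table, n, method, self.cross)

    def permutation_threshold(
        self, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0
    ) -> float:
        """Genome-wide LOD threshold from phenotype permutations.

        The phenotype vector is shuffled against the genotypes ``n_perm``
        times and the (1 - alpha) quantile of the permuted genome-wide
        maximum marker-regression LOD is returned.  At a typed marker the
        2-df genotype model's fitted values are the genotype-class means,
        so each permutation reduces to a one-way analysis of variance per
        marker, which is what makes thousands of shuffles cheap.
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 for a stable quantile")
        rng = np.random.default_rng(seed)
        codes = CrossData(
            self.cross.genotypes.loc[self._inds], self.cross.map,
            self.cross.phenotype.loc[self._inds],
        ).geno_codes()
        maxima = np.empty(n_perm)
        y = self._y.copy()
        for b in range(n_perm):
            rng.shuffle(y)
            maxima[b] = _marker_lod_profile(codes, y).max()
        return float(np.quantile(maxima, 1.0 - alpha))


def _marker_lod_profile(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Marker-regression LOD at each marker from genotype-state codes.

    ``codes`` is (n, M) with state indices 0/1/2 and NaN for missing.  The
    full model's fitted values at a typed marker are the genotype-class
    means, so RSS comparisons reduce to class sums.
    """
    n, M = codes.shape
    typed = ~np.isnan(codes)
    lod = np.zeros(M)
    y2 = y ** 2
    for j in range(M):
        t = typed[:, j]
        nt = int(t.sum())
        if nt < 3:
            continue
        yt = y[t]
        cj = codes[t, j].astype(int)
        sums = np.bincount(cj, weights=yt, minlength=3)
        cnts = np.bincount(cj, minlength=3)
        tot = yt.sum()
        rss0 = float(y2[t].sum() - tot ** 2 / nt)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = float(y2[t].sum() - np.sum(
                np.where(cnts > 0, sums ** 2 / np.where(cnts > 0, cnts, 1), 0.0)
            ))
        if rss0 <= 0:
            continue
        rss1 = max(rss1, np.finfo(float).tiny)
        lod[j] = max((nt / 2.0) * np.log10(rss0 / rss1), 0.0)
    return lod


def support_interval(result: ScanResults, drop: float = 2.0) -> SupportInterval:
    """Marker-delimited LOD drop-off interval around the scan peak.

    Walking outward from the peak, positions with ``lod >= peak - drop``
    stay inside (a dip exactly to the line does not terminate the walk);
    the bound is the first *marker* at or beyond the first position whose
    LOD falls strictly below the line, or the chromosome end if the drop is
    never reached.
    """
    if result.table.empty:
        raise ValueError("empty scan result")
    pk = result.peak
    chrom = pk["chrom"]
    sub = result.table[result.table["chrom"] == chrom].reset_index(drop=True)
    lod = sub["lod"].to_numpy()
    pos = sub["pos_cm"].to_numpy()
    markers = sub["marker"].tolist()
    peak_idx = int(sub.index[(sub["pos_cm"] == pk["pos_cm"])][0])
    cut = pk["lod"] - drop

    def bound(direction: int) -> int:
        # Grid endpoints coincide with the outermost markers, so both exit
        # paths below land on a marker index.
        j = peak_idx
        while True:
            k = j + direction
            if k < 0 or k >= len(sub):
                return j  # chromosome end (a marker by construction)
            if lod[k] < cut:
                m = k  # first marker at or beyond the crossing position
                while markers[m] == "":
                    m += direction
                return m
            j = k

    li = bound(-1)
    ri = bound(+1)
    gmap = result._cross.map
    lm, rm = markers[li], markers[ri]
    bp_lo = gmap.bp(lm) if lm else None
    bp_hi = gmap.bp(rm) if rm else None
    if bp_lo is not None and np.isnan(bp_lo):
        bp_lo = None
    if bp_hi is not None and np.isnan(bp_hi):
        bp_hi = None
    return SupportInterval(
        chrom=str(chrom),
        left_marker=lm,
        right_marker=rm,
        cm_lo=float(pos[li]),
        cm_hi=float(pos[ri]),
        bp_lo=bp_lo,
        bp_hi=bp_hi,
        peak_lod=float(pk["lod"]),
        r2=r2_from_lod(float(pk["lod"]), int(pk["n"])),
        drop=float(drop),
    )


def permutation_threshold(
    cross: CrossData, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    return IntercrossModel(cross).permutation_threshold(n_perm=n_perm, alpha=alpha, seed=seed)


def dominance_assessment(cross: CrossData, marker: str) -> DominanceReport:
    """Genotype-class means at a marker and a dominance classification.

    With a = (mean_BB - mean_HH)/2 and d = mean_BH - (mean_BB + mean_HH)/2,
    |d/a| < 0.25 is called additive; d/a >= 0.25 pulls the heterozygote
    toward the BB class (B6-dominant) and d/a <= -0.25 toward HH
    (129-dominant).  An empty genotype class yields "indeterminate".
    """
    if marker not in cross.genotypes.columns:
        raise KeyError(f"marker {marker!r} not in cross")
    g = cross.genotypes[marker]
    y = cross.phenotype
    stats_n, stats_m, stats_s = {}, {}, {}
    for cls in GENOTYPES:
        vals = y[(g == cls) & y.notna()].to_numpy(dtype=float)
        stats_n[cls] = int(len(vals))
        stats_m[cls] = float(vals.mean()) if len(vals) else np.nan
        stats_s[cls] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    if any(stats_n[c] == 0 for c in GENOTYPES):
        return DominanceReport(marker, stats_n, stats_m, stats_s, None, None, "indeterminate")
    a = (stats_m["BB"] - stats_m["HH"]) / 2.0
    d = stats_m["BH"] - (stats_m["BB"] + stats_m["HH"]) / 2.0
    if a == 0:
        cls = "indeterminate"
    else:
        ratio = d / a
        if abs(ratio) < 0.25:
            cls = "additive"
        elif ratio >= 0.25:
            cls = "B6-dominant"
        else:
            cls = "129-dominant"
    return DominanceReport(marker, stats_n, stats_m, stats_s, a, d, cls)
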