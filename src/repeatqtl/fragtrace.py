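"""Fragment-analysis peak traces and the somatic CAG instability index.

Capillary-electrophoresis fragment analysis of a PCR product spanning a CAG
tract yields a trace in which each peak corresponds to a discrete repeat
length and the peak height is proportional to the abundance of molecules of
that length in the template pool.  In a tissue undergoing somatic expansion
the trace broadens and shifts to longer repeats relative to the constitutive
("main") allele called from a stable tissue such as tail.

The *instability index* summarises a trace as the signed mean change in
repeat length across the cell population: peaks below a relative height
threshold (default 20% of the tallest peak in the trace) are excluded, the
surviving peak heights are normalised to weights summing to one, and each
weight is multiplied by the peak's repeat-length change relative to the main
allele.  Contractions contribute negative terms, so a purely contracted
trace yields a negative index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakTrace",
    "InstabilityResult",
    "PeakTableFormatError",
    "PeakCollisionError",
    "MissingTailError",
    "read_peak_table",
    "write_peak_table",
    "main_allele",
    "instability_index",
    "batch_index",
    "write_index_table",
]

REQUIRED_COLUMNS = ("sample", "tissue", "size", "height")


class PeakTableFormatError(ValueError):
    """The peak table is missing required columns or is malformed."""


class PeakCollisionError(ValueError):
    """Two base-pair sizes mapped onto the same repeat length within a trace."""


class MissingTailError(KeyError):
    """Samples lack the tail trace needed to anchor the main allele."""

    def __init__(self, samples: Sequence[str]):
        self.samples = list(samples)
        super().__init__(
            "no tail trace for sample(s): " + ", ".join(map(str, self.samples))
        )


@dataclass(frozen=True)
class Peak:
    """One fragment peak: an integer repeat length and a fluorescence height."""

    repeat_length: int
    height: float

    def __post_init__(self):
        if float(self.repeat_length) != int(self.repeat_length):
            raise ValueError(f"repeat_length must be an integer, got {self.repeat_length!r}")
        object.__setattr__(self, "repeat_length", int(self.repeat_length))
        if not math.isfinite(self.height) or self.height < 0:
            raise ValueError(f"peak height must be finite and >= 0, got {self.height!r}")
        object.__setattr__(self, "height", float(self.height))


@dataclass(frozen=True)
class PeakTrace:
    """Ordered peaks for one (sample, tissue) trace.

    Peaks are stored sorted by strictly increasing repeat length; at least
    one peak must have positive height for the trace to be interpretable.
    """

    sample_id: str
    tissue: str
    peaks: tuple[Peak, ...]

    def __post_init__(self):
        peaks = tuple(
            p if isinstance(p, Peak) else Peak(*p)
            for p in sorted(self.peaks, key=lambda p: p[0] if not isinstance(p, Peak) else p.repeat_length)
        )
        if not peaks:
            raise ValueError(f"trace {self.sample_id}/{self.tissue}: no peaks")
        lengths = [p.repeat_length for p in peaks]
        if len(set(lengths)) != len(lengths):
            dups = sorted({l for l in lengths if lengths.count(l) > 1})
            raise PeakCollisionError(
                f"trace {self.sample_id}/{self.tissue}: duplicate repeat lengths {dups}"
            )
        if not any(p.height > 0 for p in peaks):
            raise ValueError(f"trace {self.sample_id}/{self.tissue}: all peak heights are zero")
        object.__setattr__(self, "peaks", peaks)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([p.repeat_length for p in self.peaks], dtype=int)

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class InstabilityResult:
    """Instability index of one trace relative to a main allele."""

    main_allele: int
    threshold_height: float
    included_peaks: tuple[Peak, ...]
    index: float

    @property
    def n_peaks_included(self) -> int:
        return len(self.included_peaks)


def _bp_to_repeats(size_bp: np.ndarray, flank_bp: float) -> np.ndarray:
    return np.rint((size_bp - flank_bp) / 3.0).astype(int)


def read_peak_table(
    path,
    unit: str | None = None,
    flank_bp: float = 115.0,
    sep: str | None = None,
) -> list[PeakTrace]:
    """Read a delimited peak table into one :class:`PeakTrace` per (sample, tissue).

    Parameters
    ----------
    path
        Delimited text file with header columns ``sample, tissue, size,
        height`` and optionally ``unit`` (``bp`` or ``repeat``) per row.
    unit
        Force the size unit for the whole file; overrides any ``unit``
        column.  ``bp`` sizes are converted to repeat units with
        ``round((size_bp - flank_bp) / 3)``.
    flank_bp
        Length of the non-repeat flanking amplicon used for the bp->repeat
        conversion.
    sep
        Field separator; sniffed when ``None``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"{path}: missing column(s) {missing}")
    if (df["height"] < 0).any():
        bad = df.index[df["height"] < 0].tolist()
        raise ValueError(f"{path}: negative height in row(s) {bad}")

    if unit is not None:
        units = pd.Series([unit] * len(df), index=df.index)
    elif "unit" in df.columns:
        units = df["unit"].astype(str).str.lower()
    else:
        units = pd.Series(["repeat"] * len(df), index=df.index)
    bad_units = sorted(set(units) - {"bp", "repeat"})
    if bad_units:
        raise PeakTableFormatError(f"{path}: unknown size unit(s) {bad_units}")

    size = df["size"].to_numpy(dtype=float)
    repeats = np.where(
        units.to_numpy() == "bp", _bp_to_repeats(size, flank_bp), np.rint(size)
    ).astype(int)
    df = df.assign(repeat_length=repeats)

    traces: list[PeakTrace] = []
    for (sample, tissue), grp in df.groupby(["sample", "tissue"], sort=True):
        lengths = grp["repeat_length"].to_numpy()
        if len(np.unique(lengths)) != len(lengths):
            raise PeakCollisionError(
                f"sample {sample!r} tissue {tissue!r}: distinct sizes map to the "
                "same repeat length (check flank_bp / unit settings)"
            )
        traces.append(
            PeakTrace(
                sample_id=str(sample),
                tissue=str(tissue),
                peaks=tuple(Peak(int(l), float(h)) for l, h in zip(lengths, grp["height"])),
            )
        )
    return traces


def write_peak_table(traces: Iterable[PeakTrace], path) -> None:
    """Write traces back to the TSV dialect read by :func:`read_peak_table`."""
    rows = [
        {"sample": t.sample_id, "tissue": t.tissue, "size": p.repeat_length,
         "height": p.height, "unit": "repeat"}
        for t in traces
        for p in t.peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def main_allele(tail_trace: PeakTrace) -> int:
    """Constitutive repeat length: the tallest peak of the tail trace.

    On an exact height tie the smallest tied repeat length is returned.
    """
    heights = tail_trace.heights
    lengths = tail_trace.lengths
    top = heights.max()
    return int(lengths[heights == top].min())


def instability_index(
    trace: PeakTrace,
    main_allele: int,
    threshold_frac: float = 0.20,
    denominator: str = "included",
) -> InstabilityResult:
    """Signed mean CAG-length change of a trace relative to ``main_allele``.

    Peaks strictly below ``threshold_frac`` of the tallest peak in *this*
    trace are excluded ("falling below" is read strictly, so a peak exactly
    at the threshold is retained).  The remaining heights are normalised and
    each weight multiplied by the repeat-length change relative to the main
    allele; the weighted changes are summed.

    ``denominator`` selects the normalisation sum: ``"included"`` (default)
    uses post-exclusion heights so weights sum to one; ``"all"`` uses the
    pre-exclusion height sum, for sensitivity checks.
    """
    if float(main_allele) != int(main_allele):
        raise ValueError(f"main_allele must be an integer repeat count, got {main_allele!r}")
    main_allele = int(main_allele)
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    if denominator not in ("included", "all"):
        raise ValueError(f"denominator must be 'included' or 'all', got {denominator!r}")

    heights = trace.heights
    lengths = trace.lengths
    threshold = threshold_frac * heights.max()
    keep = heights >= threshold
    kept_h = heights[keep]
    denom = kept_h.sum() if denominator == "included" else heights.sum()
    deltas = lengths[keep] - main_allele
    index = float(np.sum((kept_h / denom) * deltas))
    return InstabilityResult(
        main_allele=main_allele,
        threshold_height=float(threshold),
        included_peaks=tuple(p for p, k in zip(trace.peaks, keep) if k),
        index=index,
    )


def batch_index(
    traces: Sequence[PeakTrace],
    tail_map: Mapping[str, PeakTrace] | None = None,
    tail_tissue: str = "tail",
    threshold_frac: float = 0.20,
    include_tail: bool = True,
) -> pd.DataFrame:
    """Apply the instability index to a cohort of traces.

    Every non-tail trace is scored against the main allele called from the
    same animal's tail trace (supplied in ``tail_map`` or located among
    ``traces`` by ``tail_tissue``).  Tail traces are scored against their own
    main allele, which lands near zero by construction, and are included
    unless ``include_tail`` is false.  Rows are ordered by (sample, tissue).
    """
    tails = dict(tail_map) if tail_map is not None else {}
    if tail_map is None:
        for t in traces:
            if t.tissue == tail_tissue:
                tails[t.sample_id] = t

    missing = sorted(
        {t.sample_id for t in traces if t.tissue != tail_tissue and t.sample_id not in tails}
    )
    if missing:
        raise MissingTailError(missing)

    rows = []
    for t in sorted(traces, key=lambda t: (t.sample_id, t.tissue)):
        if t.tissue == tail_tissue and not include_tail:
            continue
        allele = main_allele(tails[t.sample_id] if t.tissue != tail_tissue else t)
        res = instability_index(t, allele, threshold_frac=threshold_frac)
        rows.append(
            {"sample": t.sample_id, "tissue": t.tissue, "main_allele": res.main_allele,
             "n_peaks_included": res.n_peaks_included, "index": res.index}
        )
    return pd.DataFrame(
        rows, columns=["sample", "tissue", "main_allele", "n_peaks_included", "index"]
    )


def write_index_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")
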