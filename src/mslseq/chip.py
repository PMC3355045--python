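"""Tiling-array signal analytics.

Gene binding values average the top 50% of exon probe log2 ratios (robust
to alternative splicing).  Binding regions are called where probes exceed
the genomic average by at least three standard deviations, chained while
consecutive qualifying probes are within 360 bp, requiring a span of at
least 360 bp and at least five probes; a region's value is the mean of its
highest six consecutive probe values and its center the mid-position of
those six.  Regions found with both antibodies of a protein are intersected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError


@dataclass
class ProbeTrack:
    """Per-probe log2 enrichment signal on one chromosome."""

    chrom: str
    positions: np.ndarray  # probe midpoints, 0-based, strictly increasing
    values: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise InputError("positions and values differ in length")
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise InputError("probe positions must be strictly increasing")


@dataclass
class PeakRegion:
    chrom: str
    start: int  # first qualifying probe position
    end: int  # last qualifying probe position
    value: float  # mean of the highest six consecutive probe values
    center: float  # mid-position of those six probes
    n_probes: int


def read_bedgraph(path) -> list[ProbeTrack]:
    """Read a bedGraph (0-based half-open) into per-chromosome tracks.

    The interval start is taken as the probe midpoint coordinate.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    if df.empty:
        raise InputError(f"{path}: empty bedGraph")
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        tracks.append(
            ProbeTrack(
                chrom=str(chrom),
                positions=sub["start"].to_numpy(),
                values=sub["value"].to_numpy(),
            )
        )
    return tracks


def genomic_stats(tracks: Sequence[ProbeTrack]) -> tuple[float, float]:
    """Mean and SD of probe values over all probes of all chromosomes."""
    vals = np.concatenate([t.values for t in tracks])
    if vals.size == 0:
        raise InputError("no probes")
    return float(vals.mean()), float(vals.std(ddof=0))


def gene_binding_value(exon_probe_values) -> float:
    """Mean of the top 50% (ceil(n/2)) probe values; NaN when empty."""
    vals = np.asarray(list(exon_probe_values), dtype=float)
    if vals.size == 0:
        return float("nan")
    keep = math.ceil(vals.size / 2)
    top = np.sort(vals)[::-1][:keep]
    return float(top.mean())


def gene_binding_table(
    tracks_by_protein: dict[str, Sequence[ProbeTrack]],
    genes,
) -> pd.DataFrame:
    """Per-gene, per-protein binding values from exon probes.

    ``genes`` is a list of :class:`~mslseq.features.GeneModel`.
    """
    out = {}
    for protein, tracks in tracks_by_protein.items():
        by_chrom = {t.chrom: t for t in tracks}
        col = {}
        for g in genes:
            track = by_chrom.get(g.chrom)
            if track is None:
                col[g.gene_id] = float("nan")
                continue
            vals = []
            for es, ee in g.exons:
                i0, i1 = np.searchsorted(track.positions, [es, ee])
                vals.append(track.values[i0:i1])
            vals = np.concatenate(vals) if vals else np.empty(0)
            col[g.gene_id] = gene_binding_value(vals)
        out[protein] = col
    return pd.DataFrame(out)


def _best_six_window(positions: np.ndarray, values: np.ndarray, width: int = 6):
    """Leftmost maximal-mean window of ``width`` consecutive probes."""
    n = values.size
    w = min(width, n)
    sums = np.convolve(values, np.ones(w), mode="valid")
    i = int(np.argmax(sums))  # argmax returns the leftmost tie
    value = float(sums[i] / w)
    center = (positions[i] + positions[i + w - 1]) / 2.0
    return value, center


def call_regions(
    tracks: Sequence[ProbeTrack] | ProbeTrack,
    sd_mult: float = 3.0,
    min_span: int = 360,
    max_gap: int = 360,
    min_probes: int = 5,
    stats: tuple[float, float] | None = None,
) -> list[PeakRegion]:
    """Call binding regions from probes exceeding mean + sd_mult * SD.

    The genomic mean/SD default to statistics over all probes of all the
    tracks passed in; precomputed statistics can be supplied when calling
    one chromosome of a larger track set.
    """
    if isinstance(tracks, ProbeTrack):
        tracks = [tracks]
    if not tracks or all(t.positions.size == 0 for t in tracks):
        raise InputError("empty track set")
    mean, sd = stats if stats is not None else genomic_stats(tracks)
    threshold = mean + sd_mult * sd
    regions: list[PeakRegion] = []
    for track in tracks:
        qual = track.values >= threshold
        pos = track.positions[qual]
        val = track.values[qual]
        if pos.size == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
        for chunk_pos, chunk_val in zip(
            np.split(pos, breaks), np.split(val, breaks)
        ):
            span = int(chunk_pos[-1] - chunk_pos[0])
            if span < min_span or chunk_pos.size < min_probes:
                continue
            value, center = _best_six_window(chunk_pos, chunk_val)
            regions.append(
                PeakRegion(
                    chrom=track.chrom,
                    start=int(chunk_pos[0]),
                    end=int(chunk_pos[-1]),
                    value=value,
                    center=center,
                    n_probes=int(chunk_pos.size),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def intersect_regions(
    regions_a: Sequence[PeakRegion], regions_b: Sequence[PeakRegion]
) -> list[PeakRegion]:
    """Keep regions detected in both datasets (>= 1 bp overlap).

    The emitted region is the union span, the larger of the two values, and
    the mean of the two centers.
    """
    out: list[PeakRegion] = []
    by_chrom: dict[str, list[PeakRegion]] = {}
    for r in regions_b:
        by_chrom.setdefault(r.chrom, []).append(r)
    for ra in regions_a:
        for rb in by_chrom.get(ra.chrom, ()):
            if ra.start <= rb.end and rb.start <= ra.end:
                out.append(
                    PeakRegion(
                        chrom=ra.chrom,
                        start=min(ra.start, rb.start),
                        end=max(ra.end, rb.end),
                        value=max(ra.value, rb.value),
                        center=(ra.center + rb.center) / 2.0,
                        n_probes=max(ra.n_probes, rb.n_probes),
                    )
                )
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def tss_peak_distance(genes, peaks: Sequence[PeakRegion]) -> pd.Series:
    """Distance from each gene's TSS to the nearest peak center (NaN when
    the gene's chromosome has no peak)."""
    centers: dict[str, np.ndarray] = {}
    for r in peaks:
        centers.setdefault(r.chrom, [])
    for r in peaks:
        centers[r.chrom].append(r.center)
    centers = {c: np.sort(np.asarray(v)) for c, v in centers.items()}
    out = {}
    for g in genes:
        cs = centers.get(g.chrom)
        if cs is None or cs.size == 0:
            out[g.gene_id] = float("nan")
        else:
            out[g.gene_id] = float(np.min(np.abs(cs - g.tss)))
    return pd.Series(out, name="tss_peak_distance")


def binned_colocalization(
    tracks: Sequence[ProbeTrack],
    anchors: Iterable[tuple[str, float, bool]],
    bin_bp: int = 100,
    span: int = 2000,
) -> pd.Series:
    """Mean signal in ``bin_bp`` bins of signed distance from anchor centers.

    Each anchor is (chrom, center, tss_rightward); anchors whose gene lies
    leftward are mirrored so the TSS is always to the right.  Bins with no
    probes near any anchor are NaN.  The index holds bin left edges.
    """
    if span % bin_bp != 0:
        raise ParameterError("span must be a multiple of bin_bp")
    n_bins = 2 * span // bin_bp
    edges = np.arange(-span, span + bin_bp, bin_bp)
    by_chrom = {t.chrom: t for t in tracks}
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    any_probe = False
    for chrom, center, tss_rightward in anchors:
        track = by_chrom.get(chrom)
        if track is None:
            continue
        i0, i1 = np.searchsorted(track.positions, [center - span, center + span + 1])
        if i1 <= i0:
            continue
        d = track.positions[i0:i1].astype(float) - center
        if not tss_rightward:
            d = -d
        idx = np.floor((d + span) / bin_bp).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(sums, idx[ok], track.values[i0:i1][ok])
        np.add.at(counts, idx[ok], 1)
        any_probe = any_probe or ok.any()
    if not any_probe:
        raise InputError("no probes within span of any anchor")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=edges[:-1], name="mean_signal")


def coverage_fraction(
    regions: Sequence[PeakRegion], chrom_lengths: dict[str, int]
) -> pd.Series:
    """Fraction of each chromosome covered by (disjoint, sorted) regions."""
    cov = {c: 0 for c in chrom_lengths}
    for r in regions:
        if r.chrom not in chrom_lengths:
            raise InputError(f"region on unknown chromosome {r.chrom}")
        if r.end > chrom_lengths[r.chrom]:
            raise InputError(f"region beyond {r.chrom} length")
        cov[r.chrom] += r.end - r.start
    return pd.Series(
        {c: cov[c] / length for c, length in chrom_lengths.items()},
        name="coverage_fraction",
    )


def write_peaks_bed(regions: Sequence[PeakRegion], path) -> None:
    """Write peaks as BED6; score is value*100 rounded."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tpeak{i}\t{round(r.value * 100)}\t.\n"
            )
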