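"""Synthetic genomes, annotations, signal tracks, and expression tables.

The generator emulates the statistical structure of the study system: three
gene classes (strongly MSL-bound + expressed, weakly bound + expressed,
unexpressed) laid out on five chromosome arms, a promoter PWM planted in a
class-dependent fraction of genes (defaults 0.44 strong / 0.18 weak), CDS
word enrichment with a 5'->3' gradient in strong genes, per-probe tiling
tracks for three MSL proteins with exon enrichment plus a dual-antibody
insulator track with discrete promoter-proximal peaks, and expression
values concentrated in the (6, 10) window for expressed classes.

All randomness flows through one seed; named sub-streams are derived per
component so stages are individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import BASES, revcomp
from .chip import ProbeTrack
from .errors import ConfigError, InputError

_K_MAX = 6

#: Default planted promoter motif: 10 columns, one dominant base per column
#: (p = 0.95), consensus TATCGATAGC (a sharp insulator-like CGATA core).
DEFAULT_PWM_CONSENSUS = "TATCGATAGC"
DEFAULT_PWM_DOMINANT = 0.95

DEFAULT_CDS_WORDS = (
    "AGGTAC", "CCGTTA", "GTACCA", "TTGCGA", "CATGGC",
    "ACCGAT", "TGGATC", "GCTAAC", "AGCCTG", "TCGTGG",
)

DEFAULT_PROMOTER_WORDS = (
    "GCAGTT", "TACGGA", "CGGTAT", "ATGCCG", "GGTCAA",
    "CTAGGC", "TGCAGA", "ACGTCC", "GATCGT", "CCATAG",
)


def consensus_pwm(consensus: str, dominant: float = DEFAULT_PWM_DOMINANT) -> np.ndarray:
    """PWM with probability ``dominant`` on the consensus base per column."""
    low = (1.0 - dominant) / 3.0
    pwm = np.full((len(consensus), 4), low)
    for i, b in enumerate(consensus):
        pwm[i, BASES.index(b)] = dominant
    return pwm


def _default_pwm() -> np.ndarray:
    return consensus_pwm(DEFAULT_PWM_CONSENSUS)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_genes_per_class: int = 150
    class_names: tuple[str, ...] = ("strong", "weak", "unexpressed")
    chromosomes: tuple[str, ...] = ("chr2L", "chr2R", "chr3L", "chr3R", "chrX")
    feature_length_means: Mapping[str, int] = field(
        default_factory=lambda: {"utr5": 200, "cds": 1500, "intron": 300, "utr3": 300}
    )
    promoter_bp: int = 500
    background_base_probs: tuple[float, ...] = (0.29, 0.21, 0.21, 0.29)
    planted_pwm: np.ndarray = field(default_factory=_default_pwm)
    motif_insert_prob: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 0.44, "weak": 0.18, "unexpressed": 0.0}
    )
    promoter_enriched_words: tuple[str, ...] = DEFAULT_PROMOTER_WORDS
    promoter_word_rate: float = 0.25  # expected insertions / word / promoter, baseline
    promoter_word_multiplier: float = 3.0  # strong-class multiplier
    cds_enriched_words: tuple[str, ...] = DEFAULT_CDS_WORDS
    cds_word_rate: float = 0.8  # expected insertions / word / third, baseline
    cds_third_multipliers: tuple[float, float, float] = (1.0, 2.0, 3.0)
    probe_spacing: int = 100
    msl_proteins: tuple[str, ...] = ("MSL1", "MSL3", "MOF")
    signal_gene_enrichment: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 1.2, "weak": 0.2, "unexpressed": 0.0}
    )
    signal_gene_sd: float = 0.05
    signal_noise_sd: float = 0.1
    insulator_peak_prob: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 0.49, "weak": 0.13, "unexpressed": 0.05}
    )
    insulator_peak_height: float = 2.0
    insulator_peak_probes: int = 7
    insulator_antibodies: tuple[str, ...] = ("BEAF32_ab1", "BEAF32_ab2")
    peak_positions: Sequence[tuple[str, int]] | None = None
    expression_window: tuple[float, float] = (6.0, 10.0)
    expression_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.background_base_probs, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ConfigError("background_base_probs must be a 4-vector summing to 1")
        pwm = np.asarray(self.planted_pwm, dtype=float)
        if pwm.size and (
            pwm.ndim != 2
            or pwm.shape[1] != 4
            or (pwm < 0).any()
            or np.abs(pwm.sum(axis=1) - 1.0).max() > 1e-9
        ):
            raise ConfigError("planted_pwm columns must be probabilities summing to 1")
        for mapping in (self.motif_insert_prob, self.insulator_peak_prob):
            for name, p in dict(mapping).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"probability for class {name!r} outside [0, 1]")
        for feat, ln in dict(self.feature_length_means).items():
            if ln < _K_MAX:
                raise ConfigError(f"feature length for {feat!r} must be >= {_K_MAX}")
        if self.n_genes_per_class < 1:
            raise ConfigError("need at least one gene per class")
        if self.promoter_word_rate < 0 or self.cds_word_rate < 0:
            raise ConfigError("word insertion rates must be non-negative")
        lo, hi = self.expression_window
        if not lo < hi:
            raise ConfigError("expression_window must be increasing")


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset (one row per gene)."""

    genes: pd.DataFrame
    planted_pwm: np.ndarray
    extra_peaks: list[tuple[str, int]]

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="list"),
            "planted_pwm": np.asarray(self.planted_pwm).tolist(),
            "extra_peaks": [[c, int(p)] for c, p in self.extra_peaks],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            planted_pwm=np.asarray(payload["planted_pwm"]),
            extra_peaks=[(c, int(p)) for c, p in payload["extra_peaks"]],
        )


@dataclass
class SynthDataset:
    genome: dict[str, str]
    gff3: str
    probe_tracks: dict[str, list[ProbeTrack]]
    expression: pd.DataFrame
    truth: SynthTruth


def random_sequence(length: int, base_probs, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(base_probs, dtype=float))
    return "".join(BASES[c] for c in codes)


#: AT-balanced words carrying the group signal of the AT-gradient benchmark
AT_NEUTRAL_WORDS = ("GATC", "CTAG", "AGCT", "TCGA")


def at_gradient_observations(
    n_per_group: int = 36,
    length: int = 50_000,
    at_low: float = 0.40,
    at_high: float = 0.70,
    word_rate: float = 40.0,
    seed: int = 0,
) -> tuple[dict[str, str], pd.Series]:
    """Two sequence groups spanning the same AT gradient.

    Group "b" carries extra copies of AT-balanced words, so composition
    differs between groups while AT content does not: before AT
    normalization the leading variation is the AT gradient, afterwards the
    group signal.  The default group size and sequence length keep the
    residual post-normalization PC1-AT correlation (sampling noise plus
    variance heterogeneity across the gradient) well below 0.2.
    Returns (observations, group labels).
    """
    rng = np.random.default_rng(seed)
    obs: dict[str, str] = {}
    labels = {}
    ats = np.linspace(at_low, at_high, n_per_group)
    for group in ("a", "b"):
        for i, at in enumerate(ats):
            p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
            seq = random_sequence(length, p, rng)
            if group == "b":
                seq = _scatter_words(seq, AT_NEUTRAL_WORDS, word_rate, rng)
            name = f"{group}{i}"
            obs[name] = seq
            labels[name] = group
    return obs, pd.Series(labels)


def plant_motif(
    sequence: str, pwm: np.ndarray, position: int, rng: np.random.Generator
) -> str:
    """Replace bases at ``position`` with a sample drawn column-wise from
    ``pwm`` (no indels)."""
    pwm = np.asarray(pwm, dtype=float)
    L = pwm.shape[0] if pwm.size else 0
    if L == 0:
        return sequence
    if position < 0 or position + L > len(sequence):
        raise InputError(
            f"motif of length {L} at position {position} exceeds sequence "
            f"length {len(sequence)}"
        )
    insert = "".join(BASES[rng.choice(4, p=pwm[i] / pwm[i].sum())] for i in range(L))
    return sequence[:position] + insert + sequence[position + L :]


def _insert_word(sequence: str, word: str, position: int) -> str:
    return sequence[:position] + word + sequence[position + len(word) :]


def _scatter_words(
    sequence: str,
    words: Sequence[str],
    rate_per_word: float,
    rng: np.random.Generator,
) -> str:
    """Overwrite Poisson-distributed word copies at uniform positions."""
    for word in words:
        n = rng.poisson(rate_per_word)
        for _ in range(n):
            if len(sequence) <= len(word):
                break
            pos = int(rng.integers(0, len(sequence) - len(word) + 1))
            sequence = _insert_word(sequence, word, pos)
    return sequence


def _draw_length(mean: int, rng: np.random.Generator, multiple: int = 1) -> int:
    ln = int(round(rng.normal(mean, 0.1 * mean)))
    ln = max(multiple * max(2, _K_MAX // multiple + 1), ln)
    if multiple > 1:
        ln -= ln % multiple
    return ln


class _GffBuilder:
    def __init__(self):
        self.lines = ["##gff-version 3"]

    def add_gene(self, gene_id, chrom, strand, span, exons, cds, utr5, utr3):
        s, e = span
        attrs = f"ID={gene_id}"
        self.lines.append(
            f"{chrom}\tmslseq\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
        )
        mrna_id = f"{gene_id}.t1"
        self.lines.append(
            f"{chrom}\tmslseq\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
            f"ID={mrna_id};Parent={gene_id}"
        )
        for ftype, ivs in (
            ("exon", exons),
            ("five_prime_UTR", utr5),
            ("CDS", cds),
            ("three_prime_UTR", utr3),
        ):
            for i, (fs, fe) in enumerate(ivs, start=1):
                phase = "0" if ftype == "CDS" else "."
                self.lines.append(
                    f"{chrom}\tmslseq\t{ftype}\t{fs + 1}\t{fe}\t.\t{strand}\t{phase}\t"
                    f"ID={mrna_id}.{ftype}.{i};Parent={mrna_id}"
                )

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate a full dataset with known ground truth.

    Deterministic for a fixed config and seed; genes never overlap and every
    promoter has its full upstream window free of neighbouring genes.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(7)
    rng_layout, rng_seq, rng_motif, rng_words, rng_signal, rng_expr, rng_peaks = (
        np.random.default_rng(s) for s in streams
    )

    base_probs = np.asarray(config.background_base_probs, dtype=float)
    pwm = np.asarray(config.planted_pwm, dtype=float)
    n_classes = len(config.class_names)
    n_genes = config.n_genes_per_class * n_classes

    # class labels, shuffled, assigned round-robin to chromosomes
    labels = np.repeat(config.class_names, config.n_genes_per_class)
    rng_layout.shuffle(labels)
    gene_chroms = [config.chromosomes[i % len(config.chromosomes)] for i in range(n_genes)]
    strands = rng_layout.choice(["+", "-"], size=n_genes)
    flm = dict(config.feature_length_means)

    gff = _GffBuilder()
    genome: dict[str, str] = {}
    rows = []
    exon_map: dict[str, list[tuple[int, int, str]]] = {c: [] for c in config.chromosomes}
    peak_centers: dict[str, list[int]] = {c: [] for c in config.chromosomes}

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    order = np.arange(n_genes)

    for chrom in config.chromosomes:
        idx = [i for i in order if gene_chroms[i] == chrom]
        cursor = 0
        segments: list[str] = []
        for i in idx:
            cls = labels[i]
            strand = strands[i]
            gid = gene_ids[i]
            gap = int(rng_layout.integers(config.promoter_bp + 100, config.promoter_bp + 500))
            segments.append(random_sequence(gap, base_probs, rng_seq))
            cursor += gap

            # transcript-oriented feature strings
            len_u5 = _draw_length(flm["utr5"], rng_layout)
            len_cds = _draw_length(flm["cds"], rng_layout, multiple=3)
            len_int = _draw_length(flm["intron"], rng_layout)
            len_u3 = _draw_length(flm["utr3"], rng_layout)
            utr5 = random_sequence(len_u5, base_probs, rng_seq)
            cds = random_sequence(len_cds, base_probs, rng_seq)
            intron = random_sequence(len_int, base_probs, rng_seq)
            utr3 = random_sequence(len_u3, base_probs, rng_seq)
            promoter = random_sequence(config.promoter_bp, base_probs, rng_seq)

            # promoter composition bias + planted motif
            if config.promoter_word_rate > 0 and config.promoter_enriched_words:
                mult = (
                    config.promoter_word_multiplier if cls == "strong" else 1.0
                )
                promoter = _scatter_words(
                    promoter,
                    config.promoter_enriched_words,
                    config.promoter_word_rate * mult,
                    rng_words,
                )
            motif_inserted = False
            motif_offset = -1
            p_ins = dict(config.motif_insert_prob).get(cls, 0.0)
            if pwm.size and rng_motif.random() < p_ins:
                motif_offset = int(
                    rng_motif.integers(0, config.promoter_bp - pwm.shape[0] + 1)
                )
                promoter = plant_motif(promoter, pwm, motif_offset, rng_motif)
                motif_inserted = True

            # CDS composition bias, graded 5'->3' in strong genes
            if config.cds_word_rate > 0 and config.cds_enriched_words:
                third = len_cds // 3
                bounds = [0, third, 2 * third, len_cds]
                parts = []
                for t in range(3):
                    part = cds[bounds[t] : bounds[t + 1]]
                    mult = config.cds_third_multipliers[t] if cls == "strong" else 1.0
                    parts.append(
                        _scatter_words(
                            part,
                            config.cds_enriched_words,
                            config.cds_word_rate * mult,
                            rng_words,
                        )
                    )
                cds = "".join(parts)

            # assemble the gene block on the genome strand
            cds_split = len_cds // 2
            transcribed = utr5 + cds[:cds_split] + intron + cds[cds_split:] + utr3
            if strand == "+":
                block = promoter + transcribed
                gene_start = cursor + config.promoter_bp
                gene_end = gene_start + len(transcribed)
                tss = gene_start
            else:
                block = revcomp(transcribed) + revcomp(promoter)
                gene_start = cursor
                gene_end = gene_start + len(transcribed)
                tss = gene_end - 1
            segments.append(block)
            cursor += len(block)

            # transcript-frame offsets -> genome intervals
            t_ivs = {
                "utr5": [(0, len_u5)],
                "cds": [
                    (len_u5, len_u5 + cds_split),
                    (len_u5 + cds_split + len_int, len_u5 + len_cds + len_int),
                ],
                "exon": [
                    (0, len_u5 + cds_split),
                    (len_u5 + cds_split + len_int, len(transcribed)),
                ],
                "utr3": [(len(transcribed) - len_u3, len(transcribed))],
            }
            g_ivs = {}
            T = len(transcribed)
            for key, ivs in t_ivs.items():
                if strand == "+":
                    g_ivs[key] = [(gene_start + s, gene_start + e) for s, e in ivs]
                else:
                    g_ivs[key] = sorted(
                        (gene_start + T - e, gene_start + T - s) for s, e in ivs
                    )
            gff.add_gene(
                gid, chrom, strand, (gene_start, gene_end),
                g_ivs["exon"], g_ivs["cds"], g_ivs["utr5"], g_ivs["utr3"],
            )
            for es, ee in g_ivs["exon"]:
                exon_map[chrom].append((es, ee, gid))

            # genome coordinate of the planted motif
            motif_genome_pos = -1
            if motif_inserted:
                if strand == "+":
                    motif_genome_pos = cursor - len(block) + motif_offset
                else:
                    motif_genome_pos = (
                        gene_end + (config.promoter_bp - motif_offset - pwm.shape[0])
                    )

            # insulator peak near the TSS
            peak_center = -1
            if rng_peaks.random() < dict(config.insulator_peak_prob).get(cls, 0.0):
                d = int(rng_peaks.integers(100, 401))  # bp upstream of TSS
                peak_center = tss - d if strand == "+" else tss + d
                peak_centers[chrom].append(peak_center)

            rows.append(
                dict(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=gene_start,
                    end=gene_end,
                    tss=tss,
                    gene_class=cls,
                    motif_inserted=motif_inserted,
                    motif_promoter_offset=motif_offset,
                    motif_genome_pos=motif_genome_pos,
                    peak_center=peak_center,
                )
            )
        segments.append(random_sequence(1000, base_probs, rng_seq))
        genome[chrom] = "".join(segments)

    truth_genes = pd.DataFrame(rows).set_index("gene_id", drop=False)

    # --- expression table
    lo, hi = config.expression_window
    margin = 0.05 * (hi - lo)
    n_rep = config.expression_replicates
    expr_base = np.where(
        truth_genes["gene_class"] == "unexpressed",
        rng_expr.uniform(lo - 3.0, lo - 0.5, size=n_genes),
        rng_expr.uniform(lo + margin, hi - margin, size=n_genes),
    )
    reps = expr_base[:, None] + rng_expr.normal(0.0, 0.05, size=(n_genes, n_rep))
    expression = pd.DataFrame(
        reps,
        index=truth_genes.index,
        columns=[f"rep{j + 1}" for j in range(n_rep)],
    )
    truth_genes["expression_base"] = expr_base

    # --- probe tracks
    enrich = dict(config.signal_gene_enrichment)
    gene_means: dict[str, np.ndarray] = {}
    for protein in config.msl_proteins:
        means = np.array(
            [enrich.get(c, 0.0) for c in truth_genes["gene_class"]], dtype=float
        )
        gene_means[protein] = means + rng_signal.normal(
            0.0, config.signal_gene_sd, size=n_genes
        )
    for protein in config.msl_proteins:
        truth_genes[f"true_enrichment_{protein}"] = gene_means[protein]

    extra_peaks = [
        (c, int(p)) for c, p in (config.peak_positions or [])
    ]
    for chrom, pos in extra_peaks:
        peak_centers[chrom].append(pos)

    gene_index = {gid: i for i, gid in enumerate(truth_genes.index)}
    tracks: dict[str, list[ProbeTrack]] = {
        p: [] for p in (*config.msl_proteins, *config.insulator_antibodies)
    }
    half_width = (config.insulator_peak_probes // 2) * config.probe_spacing
    for chrom in config.chromosomes:
        clen = len(genome[chrom])
        positions = np.arange(config.probe_spacing // 2, clen, config.probe_spacing)
        exon_add = {p: np.zeros(positions.size) for p in config.msl_proteins}
        for es, ee, gid in exon_map[chrom]:
            sel = (positions >= es) & (positions < ee)
            for protein in config.msl_proteins:
                exon_add[protein][sel] += gene_means[protein][gene_index[gid]]
        peak_add = np.zeros(positions.size)
        for center in peak_centers[chrom]:
            sel = np.abs(positions - center) <= half_width
            peak_add[sel] += config.insulator_peak_height
        for protein in config.msl_proteins:
            noise = rng_signal.normal(0.0, config.signal_noise_sd, size=positions.size)
            tracks[protein].append(
                ProbeTrack(chrom=chrom, positions=positions.copy(),
                           values=exon_add[protein] + noise)
            )
        for ab in config.insulator_antibodies:
            noise = rng_signal.normal(0.0, config.signal_noise_sd, size=positions.size)
            tracks[ab].append(
                ProbeTrack(chrom=chrom, positions=positions.copy(),
                           values=peak_add + noise)
            )

    truth = SynthTruth(genes=truth_genes, planted_pwm=pwm, extra_peaks=extra_peaks)
    return SynthDataset(
        genome=genome,
        gff3=gff.text(),
        probe_tracks=tracks,
        expression=expression,
        truth=truth,
    )


def write_dataset(dataset: SynthDataset, outdir) -> None:
    """Write FASTA / GFF3 / bedGraph / TSV / truth-JSON files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in dataset.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
        fh.write(dataset.gff3)
    trackdir = os.path.join(outdir, "tracks")
    os.makedirs(trackdir, exist_ok=True)
    for protein, tracks in dataset.probe_tracks.items():
        with open(os.path.join(trackdir, f"{protein}.bedGraph"), "w") as fh:
            for tr in tracks:
                for pos, val in zip(tr.positions, tr.values):
                    fh.write(f"{tr.chrom}\t{pos}\t{pos + 1}\t{val:.5f}\n")
    dataset.expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
    dataset.truth.to_json(os.path.join(outdir, "truth.json"))
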