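"""Gene models and the six gene-feature sequence classes.

The genome is partitioned into promoter (up to 500 bp upstream of the TSS),
5' UTR, CDS, intron, 3' UTR and intergenic sequence.  Promoters overlapping
another gene or promoter are truncated toward the TSS; a promoter whose
entire upstream window lies inside a neighbouring gene is kept but flagged
excluded-for-modeling.  Within a gene, annotation conflicts resolve with
precedence CDS > UTR > intron.

Coordinates are 0-based half-open internally; GFF3 I/O converts from/to
1-based inclusive at the boundary.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gffutils

from ._dna import revcomp
from .errors import InputError

PROMOTER_BP = 500

FEATURE_CLASSES = ("promoter", "utr5", "cds", "intron", "utr3", "intergenic")

Interval = tuple[int, int]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based position of the 5'-most transcribed base
    exons: list[Interval]
    cds_intervals: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]
    introns: list[Interval]

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class FeatureSequence:
    """One gene-feature interval, optionally carrying its bases."""

    owner_gene: str
    feature_class: str
    chrom: str
    start: int
    end: int
    strand: str
    bases: str = ""
    excluded: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise InputError(
                f"{self.feature_class} of {self.owner_gene}: empty interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise InputError(f"GFF3 line {lineno}: expected 9 fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise InputError(f"GFF3 line {lineno}: non-integer coordinates") from None
        if start < 1 or end < start:
            raise InputError(f"GFF3 line {lineno}: bad interval {start}..{end}")


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(ivs: list[Interval], cuts: list[Interval]) -> list[Interval]:
    """Set-difference of sorted interval lists."""
    out: list[Interval] = []
    for s, e in ivs:
        pieces = [(s, e)]
        for cs, ce in cuts:
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    nxt.append((ps, pe))
                    continue
                if cs > ps:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        out.extend(pieces)
    return [iv for iv in out if iv[1] > iv[0]]


def parse_annotation(gff_text: str) -> list[GeneModel]:
    """Parse GFF3 (text, file path, or stream) into gene models.

    Multiple transcripts per gene are collapsed by keeping the longest
    transcript; coordinates are converted to 0-based half-open.
    """
    if hasattr(gff_text, "read"):
        gff_text = gff_text.read()
    elif "\n" not in gff_text and os.path.exists(gff_text):
        with open(gff_text) as fh:
            gff_text = fh.read()
    _validate_gff_lines(gff_text)
    db = gffutils.create_db(
        gff_text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if transcripts:
            tx = max(transcripts, key=lambda t: t.end - t.start)
            parent = tx
        else:
            parent = gene
        exons = [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
        if not exons:
            exons = [(parent.start - 1, parent.end)]
        exons = _merge_intervals(exons)
        cds = _merge_intervals(
            [(f.start - 1, f.end) for f in db.children(parent, featuretype="CDS")]
        )
        utr5 = _merge_intervals(
            [(f.start - 1, f.end) for f in db.children(parent, featuretype="five_prime_UTR")]
        )
        utr3 = _merge_intervals(
            [(f.start - 1, f.end) for f in db.children(parent, featuretype="three_prime_UTR")]
        )
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise InputError(
                    f"gene {gene.id}: CDS [{cs},{ce}) not contained in any exon"
                )
        introns = [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]
        strand = gene.strand
        span = (exons[0][0], exons[-1][1])
        tss = span[0] if strand == "+" else span[1] - 1
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                tss=tss,
                exons=exons,
                cds_intervals=cds,
                utr5=utr5,
                utr3=utr3,
                introns=introns,
            )
        )
    return genes


def _promoter_interval(gene: GeneModel, chrom_len: int, promoter_bp: int) -> Interval:
    if gene.strand == "+":
        return max(0, gene.tss - promoter_bp), gene.tss
    return gene.tss + 1, min(chrom_len, gene.tss + 1 + promoter_bp)


def derive_features(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    promoter_bp: int = PROMOTER_BP,
) -> list[FeatureSequence]:
    """Derive non-overlapping coordinates of the six feature classes.

    Returns coordinate records (``bases`` empty); pass the result to
    :func:`extract_sequences` to attach sequence.
    """
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise InputError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if g.span[1] > chrom_lengths[g.chrom]:
            raise InputError(
                f"gene {g.gene_id} extends beyond {g.chrom} length "
                f"{chrom_lengths[g.chrom]}"
            )

    out: list[FeatureSequence] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        clen = chrom_lengths[chrom]
        spans = {g.gene_id: g.span for g in chrom_genes}

        # --- promoters: truncate at other genes, then at other promoters
        promoters: dict[str, Interval | None] = {}
        excluded: set[str] = set()
        for g in chrom_genes:
            raw = _promoter_interval(g, clen, promoter_bp)
            if raw[1] <= raw[0]:  # TSS at chromosome edge
                promoters[g.gene_id] = None
                excluded.add(g.gene_id)
                continue
            cuts = [sp for gid, sp in spans.items() if gid != g.gene_id]
            pieces = _subtract([raw], _merge_intervals(cuts))
            # keep the piece adjacent to the TSS
            anchor = raw[1] if g.strand == "+" else raw[0]
            keep = None
            for ps, pe in pieces:
                if (g.strand == "+" and pe == anchor) or (
                    g.strand == "-" and ps == anchor
                ):
                    keep = (ps, pe)
            if keep is None:
                promoters[g.gene_id] = raw  # fully inside a neighbour
                excluded.add(g.gene_id)
            else:
                promoters[g.gene_id] = keep

        # promoter-promoter overlaps: split at the midpoint of the overlap
        active = [
            (gid, iv)
            for gid, iv in promoters.items()
            if iv is not None and gid not in excluded
        ]
        active.sort(key=lambda kv: kv[1])
        for i in range(len(active) - 1):
            (gid_a, (sa, ea)), (gid_b, (sb, eb)) = active[i], active[i + 1]
            if sb < ea:  # overlap
                mid = (sb + ea) // 2
                active[i] = (gid_a, (sa, mid))
                active[i + 1] = (gid_b, (mid, eb))
        for gid, iv in active:
            promoters[gid] = iv

        gene_strand = {g.gene_id: g.strand for g in chrom_genes}
        for gid, iv in promoters.items():
            if iv is None or iv[1] <= iv[0]:
                continue
            out.append(
                FeatureSequence(
                    owner_gene=gid,
                    feature_class="promoter",
                    chrom=chrom,
                    start=iv[0],
                    end=iv[1],
                    strand=gene_strand[gid],
                    excluded=gid in excluded,
                )
            )

        # --- internal features with precedence CDS > UTR > intron
        for g in chrom_genes:
            for s, e in g.cds_intervals:
                out.append(FeatureSequence(g.gene_id, "cds", chrom, s, e, g.strand))
            for cls, ivs in (("utr5", g.utr5), ("utr3", g.utr3)):
                for s, e in _subtract(ivs, g.cds_intervals):
                    out.append(FeatureSequence(g.gene_id, cls, chrom, s, e, g.strand))
            cuts = _merge_intervals(g.cds_intervals + g.utr5 + g.utr3)
            for s, e in _subtract(g.introns, cuts):
                out.append(FeatureSequence(g.gene_id, "intron", chrom, s, e, g.strand))

        # --- intergenic: complement of gene spans and promoters
        occupied = _merge_intervals(
            list(spans.values())
            + [iv for iv in promoters.values() if iv is not None and iv[1] > iv[0]]
        )
        for s, e in _subtract([(0, clen)], occupied):
            out.append(FeatureSequence("intergenic", "intergenic", chrom, s, e, "."))

    return out


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    try:
        seq = genome[chrom]
    except KeyError:
        raise InputError(f"chromosome {chrom} missing from genome") from None
    return str(seq[start:end]).upper()


def extract_sequences(coords: list[FeatureSequence], genome) -> list[FeatureSequence]:
    """Attach bases to feature coordinates.

    ``genome`` is a mapping chrom -> sequence (dict of str, or a
    ``pyfaidx.Fasta``).  CDS/UTR/intron sequences are reported on the coding
    strand; promoters 5'->3' toward the TSS; intergenic on the forward
    strand.
    """
    out = []
    for fc in coords:
        bases = _fetch(genome, fc.chrom, fc.start, fc.end)
        if fc.strand == "-" and fc.feature_class != "intergenic":
            bases = revcomp(bases)
        out.append(
            FeatureSequence(
                fc.owner_gene,
                fc.feature_class,
                fc.chrom,
                fc.start,
                fc.end,
                fc.strand,
                bases=bases,
                excluded=fc.excluded,
            )
        )
    return out


def write_bed6(features: list[FeatureSequence], path) -> None:
    """Write feature coordinates as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for fc in sorted(features, key=lambda f: (f.chrom, f.start)):
            name = f"{fc.owner_gene}:{fc.feature_class}"
            strand = fc.strand if fc.strand in "+-" else "."
            fh.write(
                f"{fc.chrom}\t{fc.start}\t{fc.end}\t{name}\t0\t{strand}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a plain dict (small genomes only)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise InputError(f"no sequences in {path}")
    return seqs
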