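"""Reference sequences, transcript models and coordinate projection.

Coordinates are 0-based half-open everywhere in memory; the 1-based
conventions of GTF/FASTA-adjacent text formats are applied only at the
file boundary.  Transcript coordinates run 5'->3' in the orientation of
the RNA, i.e. position 0 of a minus-strand transcript is the *rightmost*
genomic base of its rightmost exon.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

GENOME_CLASSES = ("nuclear", "mitochondrial", "spikein", "rRNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRef:
    """Reference sequences plus a genome-class label per contig.

    The class label drives downstream behaviour: spike-in contigs are
    exempt from the gene-overlap filter of the site caller and
    mitochondrial contigs use the UGA->Trp reading in codon statistics.
    """

    contigs: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
        for name in self.contigs:
            self.classes.setdefault(name, "nuclear")
        for name, cls in self.classes.items():
            if cls not in GENOME_CLASSES:
                raise ValueError(f"unknown genome class {cls!r} for {name!r}")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def base(self, contig: str, strand: str, pos: int) -> str:
        """Strand-aware base at a 0-based genomic position."""
        b = self.contigs[contig][pos]
        return b.translate(_COMPLEMENT) if strand == "-" else b


def read_reference(
    fasta_path: str | os.PathLike,
    class_map: Mapping[str, str] | None = None,
    default_class: str = "nuclear",
) -> GenomeRef:
    """Load a FASTA reference; unknown alphabet characters become N."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    classes = {
        name: (class_map or {}).get(name, default_class) for name in contigs
    }
    return GenomeRef(contigs=contigs, classes=classes)


def write_reference(genome: GenomeRef, fasta_path: str | os.PathLike, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exon blocks plus an optional CDS span.

    ``exons`` are genomic 0-based half-open intervals sorted by start;
    ``cds`` is a transcript-coordinate 0-based half-open span.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError("empty exon interval")
            if start < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= self.length):
                raise ValueError("CDS outside transcript")
            if (e - s) % 3:
                raise ValueError("CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def gene_span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Project a genomic position into transcript coordinates.

        Returns None for non-exonic positions.  The projection is a
        bijection between exon-covered genomic positions and
        0..length-1, reversed on the minus strand.
        """
        offset = 0
        for start, end in self.exons:
            if start <= gpos < end:
                tpos = offset + (gpos - start)
                return self.length - 1 - tpos if self.strand == "-" else tpos
            offset += end - start
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.length:
            raise IndexError(f"transcript position {tpos} out of range")
        if self.strand == "-":
            tpos = self.length - 1 - tpos
        offset = 0
        for start, end in self.exons:
            if tpos < offset + (end - start):
                return start + (tpos - offset)
            offset += end - start
        raise AssertionError("unreachable")

    def sequence(self, genome: GenomeRef) -> str:
        """Transcript sequence 5'->3' (DNA alphabet)."""
        parts = [genome.contigs[self.contig][s:e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_sequence(self, genome: GenomeRef) -> str:
        if self.cds is None:
            raise ValueError(f"{self.transcript_id} has no CDS")
        return self.sequence(genome)[self.cds[0] : self.cds[1]]

    def contains_genomic(self, gpos: int) -> bool:
        """True if the position falls inside the transcript's genomic span."""
        s, e = self.gene_span
        return s <= gpos < e


def read_annotation(gtf_path: str | os.PathLike) -> dict[str, TranscriptModel]:
    """Parse a GTF into TranscriptModel objects keyed by transcript_id.

    Biotype comes from transcript_biotype/gene_biotype attributes when
    present, else defaults to mRNA if the transcript carries a CDS and
    ncRNA otherwise.  CDS genomic intervals are converted to a
    transcript-coordinate span.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ValueError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} lacks transcript_id"
            )
        tid = tids[0]
        info = meta.setdefault(tid, {})
        info["contig"] = feat.seqid
        info["strand"] = feat.strand
        info["gene_id"] = feat.attributes.get("gene_id", [tid])[0]
        bt = feat.attributes.get("transcript_biotype") or feat.attributes.get(
            "gene_biotype"
        )
        if bt:
            info["biotype"] = bt[0]
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        (exons if feat.featuretype == "exon" else cds)[tid] = (
            (exons if feat.featuretype == "exon" else cds).get(tid, []) + [iv]
        )

    out: dict[str, TranscriptModel] = {}
    for tid, ex in exons.items():
        info = meta[tid]
        ex = tuple(sorted(ex))
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            biotype="mRNA",  # provisional; fixed below
            contig=info["contig"],
            strand=info["strand"],
            exons=ex,
        )
        cds_span = None
        if tid in cds:
            tpositions = []
            for s, e in cds[tid]:
                for g in (s, e - 1):
                    t = model.genomic_to_transcript(g)
                    if t is None:
                        raise ValueError(f"CDS of {tid} outside its exons")
                    tpositions.append(t)
            lo, hi = min(tpositions), max(tpositions) + 1
            if (hi - lo) % 3:
                raise ValueError(f"CDS length of {tid} not divisible by 3")
            cds_span = (lo, hi)
        biotype = info.get("biotype") or ("mRNA" if cds_span else "ncRNA")
        out[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            biotype=biotype,
            contig=info["contig"],
            strand=info["strand"],
            exons=ex,
            cds=cds_span,
        )
    return out


def write_annotation(
    transcripts: Iterable[TranscriptModel], gtf_path: str | os.PathLike
) -> None:
    """Emit gene/transcript/exon/CDS GTF lines (1-based inclusive)."""
    with open(gtf_path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            gs, ge = t.gene_span
            rows = [("gene", gs, ge), ("transcript", gs, ge)]
            rows += [("exon", s, e) for s, e in t.exons]
            if t.cds is not None:
                # contiguous CDS in transcript space; split over exons
                gpos = sorted(
                    t.transcript_to_genomic(tp) for tp in range(t.cds[0], t.cds[1])
                )
                start = prev = gpos[0]
                for g in gpos[1:]:
                    if g != prev + 1:
                        rows.append(("CDS", start, prev + 1))
                        start = g
                    prev = g
                rows.append(("CDS", start, prev + 1))
            for ftype, s, e in rows:
                fh.write(
                    "\t".join(
                        [
                            t.contig,
                            "psiseq",
                            ftype,
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def transcripts_by_gene(
    transcripts: Mapping[str, TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        genes.setdefault(t.gene_id, []).append(t)
    return genes


def longest_transcript_per_gene(
    transcripts: Mapping[str, TranscriptModel], require_cds: bool = False
) -> dict[str, TranscriptModel]:
    """Representative (longest) transcript for each gene.

    Ties break on transcript_id for determinism.
    """
    out: dict[str, TranscriptModel] = {}
    for gene, ts in transcripts_by_gene(transcripts).items():
        if require_cds:
            ts = [t for t in ts if t.cds is not None]
        if not ts:
            continue
        out[gene] = max(ts, key=lambda t: (t.length, t.transcript_id))
    return out
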