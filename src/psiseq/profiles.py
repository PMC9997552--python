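"""Strand-aware RT-termination profiles.

A profile stores, per (contig, strand), two dense integer arrays over the
contig length: ``n_term`` (inserts whose cDNA 5' end falls at the
position, i.e. RT stops) and ``coverage`` (inserts whose observed span
contains the position).  Termination sites are read out of paired-end
alignments as the 5' end of read R2 of a concordant pair; full-length
cDNAs contribute to coverage only.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

CONDITIONS = ("CMC", "mock")


@dataclass
class TerminationProfile:
    library_id: str
    condition: str  # "CMC" | "mock"
    genotype: str
    experiment: str
    contig_lengths: dict[str, int]
    n_term: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    coverage: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    insert_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def _ensure(self, contig: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        key = (contig, strand)
        if key not in self.n_term:
            L = self.contig_lengths[contig]
            self.n_term[key] = np.zeros(L, dtype=np.int64)
            self.coverage[key] = np.zeros(L, dtype=np.int64)
        return self.n_term[key], self.coverage[key]

    def add_insert(
        self, contig: str, strand: str, span: tuple[int, int], term: int | None
    ) -> None:
        """Record one insert: coverage over 0-based half-open ``span`` and,
        unless full-length (term is None), a termination at ``term``."""
        nt, cov = self._ensure(contig, strand)
        s, e = span
        if not (0 <= s < e <= len(cov)):
            raise ValueError(f"span {span} outside contig {contig}")
        cov[s:e] += 1
        if term is not None:
            if not s <= term < e:
                raise ValueError("termination site outside insert span")
            nt[term] += 1
        self.insert_counts[contig] = self.insert_counts.get(contig, 0) + 1

    def keys(self):
        return sorted(self.n_term)

    def total_inserts(self) -> int:
        return sum(self.insert_counts.values())

    def validate(self) -> None:
        for key in self.n_term:
            if np.any(self.n_term[key] > self.coverage[key]):
                raise ValueError(f"n_term exceeds coverage on {key}")

    def equals(self, other: "TerminationProfile") -> bool:
        if (
            self.library_id != other.library_id
            or self.condition != other.condition
            or self.genotype != other.genotype
            or self.experiment != other.experiment
            or self.contig_lengths != other.contig_lengths
            or self.insert_counts != other.insert_counts
        ):
            return False

        def arr(p: "TerminationProfile", d: dict, key) -> np.ndarray:
            if key in d:
                return d[key]
            return np.zeros(p.contig_lengths[key[0]], dtype=np.int64)

        keys = set(self.n_term) | set(other.n_term)
        return all(
            np.array_equal(arr(self, self.n_term, k), arr(other, other.n_term, k))
            and np.array_equal(
                arr(self, self.coverage, k), arr(other, other.coverage, k)
            )
            for k in keys
        )


_SKIP_FLAGS = (
    pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FDUP | pysam.FQCFAIL
)


def profile_from_alignments(
    bam_path: str | os.PathLike,
    library_id: str,
    condition: str,
    genotype: str = "",
    experiment: str = "",
) -> TerminationProfile:
    """Build a termination profile from a coordinate-sorted, indexed BAM.

    Only concordant proper pairs contribute; each pair is processed once
    via its R2.  The termination site is R2's 5' end (reference_start on
    forward alignments, last aligned base on reverse alignments); the
    insert spans the outer coordinates of the pair.  The profile strand
    is the strand R2 maps to, which in this library layout is the strand
    of the original RNA.
    """
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} is not indexed (run samtools index)")
        lengths = dict(zip(bam.references, bam.lengths))
        prof = TerminationProfile(
            library_id=library_id,
            condition=condition,
            genotype=genotype,
            experiment=experiment,
            contig_lengths=lengths,
        )
        n_pairs = 0
        for read in bam.fetch():
            if (
                not read.is_read2
                or not read.is_proper_pair
                or read.is_unmapped
                or read.mate_is_unmapped
                or read.flag & _SKIP_FLAGS
            ):
                continue
            tlen = abs(read.template_length)
            if tlen == 0:
                continue
            left = min(read.reference_start, read.next_reference_start)
            span = (left, left + tlen)
            strand = "-" if read.is_reverse else "+"
            term = read.reference_end - 1 if read.is_reverse else read.reference_start
            prof.add_insert(read.reference_name, strand, span, term)
            n_pairs += 1
        if n_pairs == 0:
            warnings.warn(f"no proper pairs found in {bam_path}; empty profile")
    return prof


def write_profile_tsv(profile: TerminationProfile, path: str | os.PathLike) -> None:
    """Serialize a profile; positions are written 1-based."""
    profile.validate()
    with open(path, "w") as fh:
        fh.write("#psiseq_profile\tv1\n")
        fh.write(f"#library_id\t{profile.library_id}\n")
        fh.write(f"#condition\t{profile.condition}\n")
        fh.write(f"#genotype\t{profile.genotype}\n")
        fh.write(f"#experiment\t{profile.experiment}\n")
        for contig, L in sorted(profile.contig_lengths.items()):
            fh.write(f"#contig\t{contig}\t{L}\n")
        for contig, n in sorted(profile.insert_counts.items()):
            fh.write(f"#inserts\t{contig}\t{n}\n")
        fh.write("contig\tstrand\tposition\tn_term\tcoverage\n")
        for contig, strand in profile.keys():
            cov = profile.coverage[(contig, strand)]
            nt = profile.n_term[(contig, strand)]
            for pos in np.nonzero(cov)[0]:
                fh.write(
                    f"{contig}\t{strand}\t{pos + 1}\t{nt[pos]}\t{cov[pos]}\n"
                )


def read_profile_tsv(path: str | os.PathLike) -> TerminationProfile:
    meta: dict[str, str] = {}
    lengths: dict[str, int] = {}
    inserts: dict[str, int] = {}
    rows: list[tuple[str, str, int, int, int]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "contig":
                    lengths[parts[1]] = int(parts[2])
                elif parts[0] == "inserts":
                    inserts[parts[1]] = int(parts[2])
                elif parts[0] in ("library_id", "condition", "genotype", "experiment"):
                    meta[parts[0]] = parts[1] if len(parts) > 1 else ""
                continue
            if not header_seen:
                if line.split("\t") != ["contig", "strand", "position", "n_term", "coverage"]:
                    raise ValueError(f"{path}: malformed column header at line {lineno}")
                header_seen = True
                continue
            contig, strand, pos, nt, cov = line.split("\t")
            nt, cov = int(nt), int(cov)
            if nt > cov:
                raise ValueError(
                    f"{path}: n_term {nt} > coverage {cov} at line {lineno}"
                )
            rows.append((contig, strand, int(pos) - 1, nt, cov))
    for key in ("library_id", "condition"):
        if key not in meta:
            raise ValueError(f"{path}: missing #{key} header line")
    prof = TerminationProfile(
        library_id=meta["library_id"],
        condition=meta["condition"],
        genotype=meta.get("genotype", ""),
        experiment=meta.get("experiment", ""),
        contig_lengths=lengths,
        insert_counts=inserts,
    )
    for contig, strand, pos, nt, cov in rows:
        n_arr, c_arr = prof._ensure(contig, strand)
        n_arr[pos] = nt
        c_arr[pos] = cov
    return prof
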