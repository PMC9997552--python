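"""Codon-level Psi enrichment statistics and site annotation.

For each Psi-codon (a codon with one uridine replaced by Psi, e.g. CΨG)
the expected site count under a uniform-across-uridines null is

    E = T * q,    q = (A_c / N) / u_c

where A_c is the abundance of the base codon in qualifying coding
regions, u_c its uridine count, N the total abundance of uridine-
containing codons (each distinct codon counted once), and T the total
number of Psi sites on coding regions of that genome class.  Observed
counts are tested against Binomial(T, q) — strict upper tail when
observed exceeds E, inclusive lower tail otherwise — and Bonferroni-
corrected by the 48 Psi-codon rows of the class.  Mitochondrial codons
translate UGA as tryptophan (invertebrate mitochondrial reading).
"""
from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom, fisher_exact

from .profiles import TerminationProfile
from .reference import GenomeRef, TranscriptModel, longest_transcript_per_gene

PSI = "Ψ"  # Ψ

#: published totals of Psi sites on coding regions, per genome class
T_NUCLEAR = 907
T_MITO = 99

#: Bonferroni family size: Psi-codon rows per genome class
N_PSI_CODON_ROWS = 48

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon_dna: str, genome_class: str = "nuclear") -> str:
    """One-letter amino acid; UGA reads W on mitochondrial transcripts."""
    if genome_class == "mitochondrial" and codon_dna == "TGA":
        return "W"
    return _STANDARD_CODE[codon_dna]


def psi_codon_label(base_codon_dna: str, psi_index: int) -> str:
    """Display form, RNA alphabet with Ψ at the modified position (1-based)."""
    rna = base_codon_dna.replace("T", "U")
    i = psi_index - 1
    return rna[:i] + PSI + rna[i + 1 :]


def parse_psi_codon(label: str) -> tuple[str, int]:
    """Inverse of :func:`psi_codon_label` -> (DNA base codon, 1-based index)."""
    i = label.index(PSI)
    rna = label.replace(PSI, "U")
    return rna.replace("U", "T"), i + 1


def all_psi_codon_rows() -> list[tuple[str, int]]:
    """The 48 (DNA base codon, 1-based Psi index) combinations."""
    bases = "TCAG"
    rows = []
    for c1 in bases:
        for c2 in bases:
            for c3 in bases:
                codon = c1 + c2 + c3
                for i, b in enumerate(codon, start=1):
                    if b == "T":
                        rows.append((codon, i))
    return rows


# ---------------------------------------------------------------------------
# site annotation on transcripts


def classify_region(
    contig: str, strand: str, pos0: int, transcript: TranscriptModel
) -> str | None:
    """5UTR / coding / 3UTR / intron label of a site on one transcript.

    Returns None when the site misses the transcript entirely or the
    transcript has no CDS.
    """
    if contig != transcript.contig or strand != transcript.strand:
        return None
    tpos = transcript.genomic_to_transcript(pos0)
    if tpos is None:
        return "intron" if transcript.contains_genomic(pos0) else None
    if transcript.cds is None:
        return None
    s, e = transcript.cds
    if tpos < s:
        return "5UTR"
    if tpos < e:
        return "coding"
    return "3UTR"


def classify_site_regions(
    contig: str,
    strand: str,
    pos0: int,
    transcripts: Iterable[TranscriptModel],
) -> set[str]:
    """All region labels a site receives across isoforms (each counted
    once per site in tallies, so the labels may sum past 100%)."""
    labels = set()
    for t in transcripts:
        lab = classify_region(contig, strand, pos0, t)
        if lab is not None:
            labels.add(lab)
    return labels


def codon_context(
    contig: str,
    strand: str,
    pos0: int,
    transcript: TranscriptModel,
    genome: GenomeRef,
) -> tuple[str, str, int, str]:
    """(Ψ-codon label, base codon, Psi index 1..3, amino acid) of a
    coding site, read in the frame of the supplied transcript."""
    tpos = transcript.genomic_to_transcript(pos0)
    if tpos is None or transcript.cds is None:
        raise ValueError("site is not exonic on a coding transcript")
    s, e = transcript.cds
    if not s <= tpos < e:
        raise ValueError("site outside the CDS span")
    seq = transcript.sequence(genome)
    if seq[tpos] != "T":
        raise ValueError(f"reference base at site is {seq[tpos]}, not T")
    off = tpos - s
    codon_start = s + off // 3 * 3
    codon = seq[codon_start : codon_start + 3]
    psi_index = off % 3 + 1
    genome_class = genome.classes.get(contig, "nuclear")
    return (
        psi_codon_label(codon, psi_index),
        codon,
        psi_index,
        translate_codon(codon, genome_class),
    )


# ---------------------------------------------------------------------------
# abundance, expectation, tests


def mean_cds_coverage(
    profiles: Iterable[TerminationProfile], transcript: TranscriptModel
) -> float:
    """Mean CMC insert coverage over the CDS, averaged across libraries."""
    if transcript.cds is None:
        return 0.0
    gpos = np.array(
        [
            transcript.transcript_to_genomic(tp)
            for tp in range(transcript.cds[0], transcript.cds[1])
        ]
    )
    vals = []
    for prof in profiles:
        cov = prof.coverage.get((transcript.contig, transcript.strand))
        vals.append(0.0 if cov is None else float(cov[gpos].mean()))
    return float(np.mean(vals)) if vals else 0.0


def codon_abundance(
    transcripts: Mapping[str, TranscriptModel],
    genome: GenomeRef,
    gene_coverage: Mapping[str, float] | None = None,
    min_coverage: float = 10.0,
    genome_class: str = "nuclear",
) -> tuple[dict[str, int], int]:
    """Per-codon abundance A_c over qualifying genes, and normalizer N.

    One (longest) coding transcript per gene; a gene qualifies when its
    mean CMC coverage over the CDS is >= min_coverage (no filter when
    gene_coverage is None).  N sums the abundances of the distinct
    uridine-containing base codons.
    """
    reps = longest_transcript_per_gene(transcripts, require_cds=True)
    counts: dict[str, int] = {}
    any_gene = False
    for gene, t in sorted(reps.items()):
        if genome.classes.get(t.contig, "nuclear") != genome_class:
            continue
        if gene_coverage is not None and gene_coverage.get(gene, 0.0) < min_coverage:
            continue
        any_gene = True
        cds = t.cds_sequence(genome)
        for i in range(0, len(cds) - 2, 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    if not any_gene:
        raise ValueError(f"no qualifying {genome_class} genes")
    N = sum(c for codon, c in counts.items() if "T" in codon)
    return counts, N


def codon_binomial_test(
    q: float, T: int, observed: int, n_rows: int = N_PSI_CODON_ROWS
) -> tuple[float, float]:
    """Raw and Bonferroni-adjusted binomial p for one Ψ-codon row.

    With X ~ Binomial(T, q) and E = T*q: enrichment (observed > E) is
    tested with the strict upper tail P(X > observed); otherwise the
    inclusive lower tail P(X <= observed).
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q={q} outside [0, 1]")
    E = T * q
    if observed > E:
        p = float(binom.sf(observed, T, q))
    else:
        p = float(binom.cdf(observed, T, q))
    return p, min(1.0, n_rows * p)


def codon_rows(
    abundances: Mapping[str, int],
    observed: Mapping[tuple[str, int], int],
    T: int,
    genome_class: str = "nuclear",
) -> pd.DataFrame:
    """Build the full 48-row Ψ-codon table for one genome class.

    ``observed`` maps (DNA base codon, 1-based Psi index) to called-site
    counts; codons absent from ``abundances`` get A_c = 0.
    """
    rows = []
    N = sum(c for codon, c in abundances.items() if "T" in codon)
    for codon, idx in all_psi_codon_rows():
        A = int(abundances.get(codon, 0))
        u = codon.count("T")
        q = (A / N) / u if N else 0.0
        E = T * q
        obs = int(observed.get((codon, idx), 0))
        p_raw, p_adj = codon_binomial_test(q, T, obs)
        rows.append(
            {
                "psi_codon": psi_codon_label(codon, idx),
                "base_codon": codon,
                "psi_index": idx,
                "genome_class": genome_class,
                "amino_acid": translate_codon(codon, genome_class),
                "abundance": A,
                "u_count": u,
                "q": q,
                "expected": E,
                "expected_rounded": int(np.floor(E + 0.5)),
                "observed": obs,
                "p_raw": p_raw,
                "p_adj": p_adj,
            }
        )
    return pd.DataFrame(rows)


def psi_ga_fisher(table: Iterable[Iterable[int]]) -> float:
    """One-sided (greater) Fisher exact p that ΨGA is more frequent in
    the first row's class; rows are (ΨGA count, unmodified UGA count)."""
    arr = np.asarray(list(table), dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    return float(fisher_exact(arr, alternative="greater")[1])


# ---------------------------------------------------------------------------
# published census


def load_published_census() -> pd.DataFrame:
    """The packaged Psi-codon census (abundances, observed counts, and
    the published expectations / adjusted p-values for cross-checks)."""
    path = resources.files("psiseq.data") / "psi_codon_counts_dmel.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", encoding="utf-8")
    parsed = df["codon"].map(parse_psi_codon)
    df["base_codon"] = [c for c, _ in parsed]
    df["psi_index"] = [i for _, i in parsed]
    return df


def recompute_published_table(genome_class: str = "nuclear") -> pd.DataFrame:
    """Recompute the Ψ-codon table of one genome class from the census's
    printed abundance and observed columns alone."""
    census = load_published_census()
    prefix = "nuclear" if genome_class == "nuclear" else "mito"
    T = T_NUCLEAR if genome_class == "nuclear" else T_MITO
    abundances = {}
    for row in census.itertuples():
        abundances[row.base_codon] = int(getattr(row, f"{prefix}_abundance"))
    observed = {
        (row.base_codon, row.psi_index): int(getattr(row, f"{prefix}_observed"))
        for row in census.itertuples()
    }
    out = codon_rows(abundances, observed, T, genome_class=genome_class)
    printed = census.set_index(["base_codon", "psi_index"])
    out["expected_printed"] = [
        int(printed.loc[(r.base_codon, r.psi_index), f"{prefix}_expected_printed"])
        for r in out.itertuples()
    ]
    out["adjp_printed"] = [
        float(printed.loc[(r.base_codon, r.psi_index), f"{prefix}_adjp_printed"])
        for r in out.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# per-gene summaries and motif flanks


def gene_summaries(
    siteset: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    genome: GenomeRef,
    cmc_profiles: Iterable[TerminationProfile],
) -> pd.DataFrame:
    """Per-gene Psi burden and expression table.

    RPKM = assigned inserts * 1e9 / (transcript length * total assigned
    inserts), averaged over the CMC libraries; insert assignment is
    estimated from exonic coverage mass divided by the library's mean
    insert length (exact when each gene owns its contig).  Genes with
    zero called sites stay in the table.
    """
    cmc_profiles = list(cmc_profiles)
    reps = longest_transcript_per_gene(transcripts)
    site_count: dict[str, int] = {g: 0 for g in reps}
    for row in siteset.itertuples():
        for gene, t in reps.items():
            if (
                t.contig == row.contig
                and t.strand == row.strand
                and t.contains_genomic(row.psi_pos0)
            ):
                site_count[gene] += 1
    rows = []
    rpkm_per_lib: dict[str, list[float]] = {g: [] for g in reps}
    for prof in cmc_profiles:
        total = prof.total_inserts()
        if total == 0:
            raise ValueError(f"library {prof.library_id} has no inserts")
        cov_mass = sum(float(c.sum()) for c in prof.coverage.values())
        mean_len = cov_mass / total
        for gene, t in reps.items():
            cov = prof.coverage.get((t.contig, t.strand))
            gene_mass = 0.0
            if cov is not None:
                for s, e in t.exons:
                    gene_mass += float(cov[s:e].sum())
            assigned = gene_mass / mean_len
            rpkm_per_lib[gene].append(assigned * 1e9 / (t.length * total))
    for gene, t in sorted(reps.items()):
        useq = t.sequence(genome)
        n_u = useq.count("T")
        n_psi = site_count[gene]
        rows.append(
            {
                "gene_id": gene,
                "transcript_id": t.transcript_id,
                "biotype": t.biotype,
                "length": t.length,
                "n_uridines": n_u,
                "n_psi": n_psi,
                "pct_u_modified": 100.0 * n_psi / n_u if n_u else 0.0,
                "rpkm": float(np.mean(rpkm_per_lib[gene])),
            }
        )
    return pd.DataFrame(rows)


def motif_flanks(
    siteset: pd.DataFrame,
    genome: GenomeRef,
    transcripts: Mapping[str, TranscriptModel] | None = None,
    flank: int = 10,
) -> pd.DataFrame:
    """Position frequency matrix of the 21-nt windows centred on Psi.

    Windows are taken in transcript orientation (host transcript when
    available, strand-aware genomic sequence otherwise); positions
    truncated by sequence ends pad with N, which is excluded from
    column normalisation.  The centre column is all-U by construction.
    """
    if siteset.empty:
        raise ValueError("empty site set")
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=float)  # rows A, C, G, U
    row_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    reps = longest_transcript_per_gene(transcripts) if transcripts else {}
    for site in siteset.itertuples():
        window = None
        for t in reps.values():
            if t.contig == site.contig and t.strand == site.strand:
                tpos = t.genomic_to_transcript(site.psi_pos0)
                if tpos is not None:
                    seq = t.sequence(genome)
                    lo, hi = tpos - flank, tpos + flank + 1
                    window = (
                        "N" * max(0, -lo)
                        + seq[max(0, lo) : min(len(seq), hi)]
                        + "N" * max(0, hi - len(seq))
                    )
                    break
        if window is None:
            seq = genome.contigs[site.contig]
            p = site.psi_pos0
            lo, hi = p - flank, p + flank + 1
            window = (
                "N" * max(0, -lo)
                + seq[max(0, lo) : min(len(seq), hi)]
                + "N" * max(0, hi - len(seq))
            )
            if site.strand == "-":
                from .reference import revcomp

                window = revcomp(window)
        for j, b in enumerate(window):
            if b in row_of:
                counts[row_of[b], j] += 1
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(col_tot > 0, counts / col_tot, 0.0)
    return pd.DataFrame(
        freqs,
        index=["A", "C", "G", "U"],
        columns=[str(i - flank) for i in range(width)],
    )
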