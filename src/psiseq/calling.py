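"""The statistical Psi site caller.

Per testable site the caller runs a one-sided two-proportion z-test of

    H0: TR_CMC <= TR_Mock     vs     Ha: TR_CMC > TR_Mock

with the pooled-proportion variance

    z = (TR_CMC - TR_Mock) / sqrt( p(1-p) (1/Cvg_CMC + 1/Cvg_Mock) ),
    p = (n_term_CMC + n_term_Mock) / (Cvg_CMC + Cvg_Mock).

P-values are BH-adjusted within the family of *relevant* sites of one
CMC/mock library pair.  A site is called in a library when it is
relevant, padj < alpha, the base immediately 5' (transcript
orientation) of the termination site is a uridine, and the position
falls inside an annotated gene on the matching strand (spike-in contigs
are exempt from the gene rule).  The reported coordinate is the Psi
(upstream) base, not the termination site.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .reference import GenomeRef, TranscriptModel
from .profiles import TerminationProfile
from .termination import pair_stats

#: support-count thresholds for (high, intermediate, low) reproducibility
DEFAULT_CLASS_BOUNDS = (6, 4, 2)


def z_statistic(
    n_term_cmc: int, cvg_cmc: int, n_term_mock: int, cvg_mock: int
) -> tuple[float, float]:
    """Pooled two-proportion z and its one-sided (upper-tail) p-value.

    When the pooled proportion is 0 or 1 the variance degenerates and
    the site is untestable: returns (nan, 1.0).
    """
    if cvg_cmc <= 0 or cvg_mock <= 0:
        raise ValueError("z-test requires positive coverage on both sides")
    p = (n_term_cmc + n_term_mock) / (cvg_cmc + cvg_mock)
    if p <= 0 or p >= 1:
        return float("nan"), 1.0
    tr_c = n_term_cmc / cvg_cmc
    tr_m = n_term_mock / cvg_mock
    z = (tr_c - tr_m) / np.sqrt(p * (1 - p) * (1 / cvg_cmc + 1 / cvg_mock))
    return float(z), float(norm.sf(z))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def annotate_significance(stats: pd.DataFrame) -> pd.DataFrame:
    """Fill z/pval/padj on the relevant rows of a pair_stats table.

    The BH family is the set of relevant sites of this one library pair.
    Untestable sites (pooled proportion 0 or 1) get pval = 1.
    """
    out = stats.copy()
    rel = out["relevant"].to_numpy()
    if not rel.any():
        return out
    cc = out.loc[rel, "cvg_cmc"].to_numpy(float)
    cm = out.loc[rel, "cvg_mock"].to_numpy(float)
    nc = out.loc[rel, "n_term_cmc"].to_numpy(float)
    nm = out.loc[rel, "n_term_mock"].to_numpy(float)
    p = (nc + nm) / (cc + cm)
    testable = (p > 0) & (p < 1)
    z = np.full(p.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z[testable] = (
            (nc / cc - nm / cm)[testable]
            / np.sqrt((p * (1 - p) * (1 / cc + 1 / cm))[testable])
        )
    pval = np.where(testable, norm.sf(z), 1.0)
    out.loc[rel, "z"] = z
    out.loc[rel, "pval"] = pval
    out.loc[rel, "padj"] = bh_adjust(pval)
    return out


@dataclass(frozen=True)
class LibraryCall:
    """Called Psi positions of one CMC/mock pair.

    Sites are (contig, strand, 0-based Psi position); the Psi base is
    the transcript-orientation upstream neighbour of the termination
    site.
    """

    library_id: str
    genotype: str
    experiment: str
    sites: frozenset[tuple[str, str, int]]
    table: pd.DataFrame | None = None


def _gene_index(
    transcripts: Mapping[str, TranscriptModel],
) -> dict[tuple[str, str], list[tuple[int, int, str]]]:
    idx: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for t in transcripts.values():
        s, e = t.gene_span
        idx.setdefault((t.contig, t.strand), []).append((s, e, t.gene_id))
    return idx


def psi_position(strand: str, term_pos: int) -> int:
    """Genomic position of the base 5' (transcript orientation) of a
    termination site: term-1 on '+', term+1 on '-'."""
    return term_pos - 1 if strand == "+" else term_pos + 1


def call_library(
    stats: pd.DataFrame,
    genome: GenomeRef,
    transcripts: Mapping[str, TranscriptModel],
    library_id: str,
    genotype: str = "",
    experiment: str = "",
    alpha: float = 0.05,
) -> LibraryCall:
    """Apply the per-library calling filters to an annotated stats table."""
    if stats["padj"].isna().all() and stats["relevant"].any():
        raise ValueError("stats table lacks padj; run annotate_significance first")
    genes = _gene_index(transcripts)
    sig = stats[(stats["relevant"]) & (stats["padj"] < alpha)]
    rows = []
    for row in sig.itertuples():
        contig = row.contig
        if contig not in genome.contigs:
            raise KeyError(f"no reference sequence for contig {contig!r}")
        psi = psi_position(row.strand, int(row.pos0))
        if not 0 <= psi < len(genome.contigs[contig]):
            continue
        if genome.base(contig, row.strand, psi) != "T":
            continue
        if genome.classes.get(contig) != "spikein":
            spans = genes.get((contig, row.strand), [])
            if not any(s <= psi < e for s, e, _ in spans):
                continue
        rows.append(
            {
                "contig": contig,
                "strand": row.strand,
                "psi_pos0": psi,
                "term_pos0": int(row.pos0),
                "tr_cmc": row.tr_cmc,
                "tr_mock": row.tr_mock,
                "z": row.z,
                "padj": row.padj,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "strand",
            "psi_pos0",
            "term_pos0",
            "tr_cmc",
            "tr_mock",
            "z",
            "padj",
        ],
    )
    sites = frozenset(
        (r["contig"], r["strand"], r["psi_pos0"]) for r in rows
    )
    return LibraryCall(
        library_id=library_id,
        genotype=genotype,
        experiment=experiment,
        sites=sites,
        table=table,
    )


def call_pair(
    cmc: TerminationProfile,
    mock: TerminationProfile,
    genome: GenomeRef,
    transcripts: Mapping[str, TranscriptModel],
    alpha: float = 0.05,
    min_term: int = 5,
    min_readthrough: int = 5,
) -> tuple[pd.DataFrame, LibraryCall]:
    """pair_stats -> z-test -> BH -> per-library call, in one step."""
    stats = annotate_significance(
        pair_stats(cmc, mock, min_term=min_term, min_readthrough=min_readthrough)
    )
    call = call_library(
        stats,
        genome,
        transcripts,
        library_id=cmc.library_id,
        genotype=cmc.genotype,
        experiment=cmc.experiment,
        alpha=alpha,
    )
    return stats, call


def reproducibility_class(
    support: int, bounds: tuple[int, int, int] = DEFAULT_CLASS_BOUNDS
) -> str:
    high, mid, low = bounds
    if support >= high:
        return "high"
    if support >= mid:
        return "intermediate"
    if support >= low:
        return "low"
    return "none"


def aggregate_replicates(
    calls: Iterable[LibraryCall],
    min_libraries: int = 2,
    min_experiments: int = 2,
    class_bounds: tuple[int, int, int] = DEFAULT_CLASS_BOUNDS,
    allow_single_experiment: bool = False,
) -> pd.DataFrame:
    """Aggregate per-library calls into a reproducibility-classed site set.

    A site qualifies when supported by >= min_libraries calls spanning
    >= min_experiments distinct experiment labels; the class is assigned
    from the total support count.
    """
    calls = list(calls)
    experiments = {c.experiment for c in calls}
    if len(experiments) < min_experiments:
        if not allow_single_experiment:
            raise ValueError(
                f"calls span {len(experiments)} experiment label(s); "
                f">= {min_experiments} required (allow_single_experiment to override)"
            )
        warnings.warn("aggregating calls from a single experiment")
        min_experiments = len(experiments)
    support: dict[tuple[str, str, int], list[LibraryCall]] = {}
    for call in calls:
        for site in call.sites:
            support.setdefault(site, []).append(call)
    rows = []
    for site in sorted(support):
        sup = support[site]
        exps = sorted({c.experiment for c in sup})
        if len(sup) < min_libraries or len(exps) < min_experiments:
            continue
        contig, strand, pos = site
        rows.append(
            {
                "contig": contig,
                "strand": strand,
                "psi_pos0": pos,
                "support": len(sup),
                "libraries": ";".join(sorted(c.library_id for c in sup)),
                "experiments": ";".join(exps),
                "repro_class": reproducibility_class(len(sup), class_bounds),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "strand",
            "psi_pos0",
            "support",
            "libraries",
            "experiments",
            "repro_class",
        ],
    )


def annotate_sites(
    siteset: pd.DataFrame, transcripts: Mapping[str, TranscriptModel]
) -> pd.DataFrame:
    """Attach host gene id(s) and biotype(s) to an aggregated site set."""
    idx: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts.values():
        idx.setdefault((t.contig, t.strand), []).append(t)
    genes, biotypes = [], []
    for row in siteset.itertuples():
        hits = {
            (t.gene_id, t.biotype)
            for t in idx.get((row.contig, row.strand), [])
            if t.contains_genomic(row.psi_pos0)
        }
        genes.append(";".join(sorted({g for g, _ in hits})))
        biotypes.append(";".join(sorted({b for _, b in hits})))
    out = siteset.copy()
    out["genes"] = genes
    out["biotypes"] = biotypes
    return out


def differential_sites(
    control: pd.DataFrame,
    mutant_calls: Sequence[LibraryCall],
    mutant_profiles: Sequence[TerminationProfile] | None = None,
) -> pd.DataFrame:
    """Control sites not detected in *any* mutant library.

    "Detected" means present in that library's full call set (relevance,
    FDR and sequence/annotation filters included).  When mutant profiles
    are supplied, per-library coverage at each site is attached so that
    absence of signal can be told apart from absence of data.
    """
    if not mutant_calls:
        raise ValueError("no mutant calls supplied")
    detected: set[tuple[str, str, int]] = set()
    for call in mutant_calls:
        detected |= call.sites
    mask = [
        (row.contig, row.strand, row.psi_pos0) not in detected
        for row in control.itertuples()
    ]
    out = control[pd.Series(mask, index=control.index)].reset_index(drop=True)
    if mutant_profiles is not None:
        for prof in mutant_profiles:
            col = []
            for row in out.itertuples():
                key = (row.contig, row.strand)
                cov = prof.coverage.get(key)
                col.append(int(cov[row.psi_pos0]) if cov is not None else 0)
            out[f"cvg_{prof.library_id}"] = col
    return out


def write_calls_tsv(call: LibraryCall, path) -> None:
    """Serialize one library's call table (positions 1-based on disk)."""
    with open(path, "w") as fh:
        fh.write("#psiseq_calls\tv1\n")
        fh.write(f"#library_id\t{call.library_id}\n")
        fh.write(f"#genotype\t{call.genotype}\n")
        fh.write(f"#experiment\t{call.experiment}\n")
        table = call.table if call.table is not None else pd.DataFrame()
        out = table.copy()
        if not out.empty:
            out["psi_position"] = out.pop("psi_pos0") + 1
            out["term_position"] = out.pop("term_pos0") + 1
            out = out[
                [
                    "contig",
                    "strand",
                    "psi_position",
                    "term_position",
                    "tr_cmc",
                    "tr_mock",
                    "z",
                    "padj",
                ]
            ]
        else:
            out = pd.DataFrame(
                columns=[
                    "contig",
                    "strand",
                    "psi_position",
                    "term_position",
                    "tr_cmc",
                    "tr_mock",
                    "z",
                    "padj",
                ]
            )
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path) -> LibraryCall:
    meta = {"library_id": "", "genotype": "", "experiment": ""}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            parts = line[1:].rstrip("\n").split("\t")
            if parts[0] in meta:
                meta[parts[0]] = parts[1] if len(parts) > 1 else ""
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    table["psi_pos0"] = table.pop("psi_position").astype(int) - 1
    table["term_pos0"] = table.pop("term_position").astype(int) - 1
    sites = frozenset(
        (r.contig, r.strand, r.psi_pos0) for r in table.itertuples()
    )
    return LibraryCall(sites=sites, table=table, **meta)


def write_siteset_tsv(siteset: pd.DataFrame, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("#psiseq_siteset\tv1\n")
        for k, v in (header or {}).items():
            fh.write(f"#{k}\t{v}\n")
        out = siteset.copy()
        cols = list(out.columns)
        cols[cols.index("psi_pos0")] = "psi_position"
        out["psi_pos0"] += 1
        out.columns = cols
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_siteset_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["psi_pos0"] = df.pop("psi_position").astype(int) - 1
    cols = ["contig", "strand", "psi_pos0"] + [
        c for c in df.columns if c not in ("contig", "strand", "psi_pos0")
    ]
    return df[cols]


def write_calls_bed(call_table: pd.DataFrame, path) -> None:
    """Called Psi sites as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in call_table.itertuples():
            name = f"psi_padj={row.padj:.3g}" if hasattr(row, "padj") else "psi"
            score = getattr(row, "support", 0)
            fh.write(
                f"{row.contig}\t{row.psi_pos0}\t{row.psi_pos0 + 1}\t{name}\t{score}\t{row.strand}\n"
            )
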