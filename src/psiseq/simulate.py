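"""Synthetic CMC/mock termination data with planted Psi truth sets.

The generator emulates the chemistry the caller assumes: in CMC-treated
libraries a Psi carries a bulky adduct with probability rho (adduct
occupancy) and an adducted Psi blocks reverse transcription with
probability pi, so the cDNA 5' end lands on the base immediately 3' of
the Psi — the Psi is the *upstream* base of the recorded termination
site.  Background stops occur at every nucleotide with probability b in
both conditions; mock libraries see background only.  cDNAs that run
through to the fragment's 5' boundary are full-length: they count in
coverage but never in n_term.

Replicate structure mirrors a two-experiment design: by default 3
control pairs in Exp1 plus 4 control and 4 mutant pairs in Exp2, with a
150-nt spike-in carrying a single Psi at position 43 added to every
library.  All randomness flows from one master seed through per-library
spawned streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .reference import GenomeRef, TranscriptModel
from .profiles import TerminationProfile

SPIKE_CONTIG = "spikein"


@dataclass(frozen=True)
class PairSpec:
    """One CMC/mock library pair."""

    pair_id: str
    genotype: str
    experiment: str
    is_mutant: bool = False


def default_layout() -> tuple[PairSpec, ...]:
    """3 control pairs in Exp1; 4 control + 4 mutant pairs in Exp2."""
    pairs = [PairSpec(f"ctrl{i}", "control", "Exp1") for i in range(1, 4)]
    pairs += [PairSpec(f"ctrl{i}", "control", "Exp2") for i in range(4, 8)]
    pairs += [
        PairSpec(f"mut{i}", "mutant", "Exp2", is_mutant=True) for i in range(1, 5)
    ]
    return tuple(pairs)


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.

    Probabilities: ``adduct_occupancy`` (rho) is the fraction of
    molecules carrying a CMC adduct at a Psi in treated libraries;
    ``stop_given_adduct`` (pi) the chance an adduct halts RT;
    ``background_stop`` (b) the per-nucleotide spontaneous stop rate.
    Depth: ``inserts_per_transcript`` is a Poisson mean per transcript
    per library, sized so planted sites average >= 50x coverage.
    """

    n_transcripts: int = 30
    length_range: tuple[int, int] = (300, 600)
    gc_fraction: float = 0.42
    psi_per_transcript: int = 3
    adduct_occupancy: float = 0.9
    stop_given_adduct: float = 0.85
    background_stop: float = 0.002
    inserts_per_transcript: float = 400.0
    fragment_length_mean: float = 80.0
    fragment_length_sd: float = 20.0
    fragment_length_min: int = 40
    layout: tuple[PairSpec, ...] = field(default_factory=default_layout)
    mutant_missing_fraction: float = 0.3
    include_spikein: bool = True
    spikein_length: int = 150
    spikein_psi_position: int = 43  # 1-based
    spikein_inserts: float = 2000.0
    psi_end_margin: int = 50
    psi_min_spacing: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "adduct_occupancy",
            "stop_given_adduct",
            "background_stop",
            "gc_fraction",
            "mutant_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.length_range[0] < 60:
            raise ValueError("transcripts must be at least 60 nt")
        if not self.layout:
            raise ValueError("replicate layout needs at least one pair")


TRUTH_COLUMNS = ["contig", "strand", "pos0", "writable_in_mutant"]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _plant_psis(
    rng: np.random.Generator, seq: str, cfg: SyntheticConfig
) -> list[int]:
    m = cfg.psi_end_margin
    candidates = [
        i for i in range(m, len(seq) - m) if seq[i] == "T"
    ]
    if cfg.psi_per_transcript > len(candidates):
        raise ValueError(
            f"psi_per_transcript={cfg.psi_per_transcript} exceeds "
            f"{len(candidates)} available uridine positions"
        )
    rng.shuffle(candidates)
    chosen: list[int] = []
    for pos in candidates:
        if len(chosen) == cfg.psi_per_transcript:
            break
        if all(abs(pos - c) >= cfg.psi_min_spacing for c in chosen):
            chosen.append(pos)
    return sorted(chosen)


def generate_reference(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeRef, dict[str, TranscriptModel], pd.DataFrame]:
    """Random transcript contigs, annotation, and a planted Psi truth set.

    Each transcript occupies its own plus-strand contig with a central
    CDS; Psi sites are planted only at uridines, away from transcript
    ends.  With ``include_spikein`` a 150-nt spike-in contig carries
    exactly one Psi at (1-based) position 43.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    contigs: dict[str, str] = {}
    classes: dict[str, str] = {}
    transcripts: dict[str, TranscriptModel] = {}
    truth_rows: list[dict] = []
    lo, hi = config.length_range
    for i in range(config.n_transcripts):
        name = f"tx{i + 1:03d}"
        L = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, L, config.gc_fraction)
        for pos in _plant_psis(rng, seq, config):
            truth_rows.append(
                {
                    "contig": name,
                    "strand": "+",
                    "pos0": pos,
                    "writable_in_mutant": bool(
                        rng.random() >= config.mutant_missing_fraction
                    ),
                }
            )
        contigs[name] = seq
        classes[name] = "nuclear"
        cds_start = L // 10
        cds_len = (L * 8 // 10) // 3 * 3
        transcripts[f"{name}.t1"] = TranscriptModel(
            transcript_id=f"{name}.t1",
            gene_id=f"{name}.g",
            biotype="mRNA",
            contig=name,
            strand="+",
            exons=((0, L),),
            cds=(cds_start, cds_start + cds_len),
        )
    if config.include_spikein:
        seq = list(_random_sequence(rng, config.spikein_length, config.gc_fraction))
        psi0 = config.spikein_psi_position - 1
        seq[psi0] = "T"
        contigs[SPIKE_CONTIG] = "".join(seq)
        classes[SPIKE_CONTIG] = "spikein"
        truth_rows.append(
            {
                "contig": SPIKE_CONTIG,
                "strand": "+",
                "pos0": psi0,
                "writable_in_mutant": True,
            }
        )
    genome = GenomeRef(contigs=contigs, classes=classes)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genome, transcripts, truth


def simulate_library(
    genome: GenomeRef,
    truth: pd.DataFrame,
    config: SyntheticConfig,
    library_id: str,
    condition: str,
    genotype: str = "control",
    experiment: str = "",
    is_mutant: bool = False,
    rng: np.random.Generator | None = None,
) -> TerminationProfile:
    """Simulate the termination profile of one library.

    RT walks 3'->5' along each fragment.  Before copying base k
    (counting from 1 at the fragment 3' end) it halts with the
    background probability, and additionally with rho*pi when that base
    is an adduct-bearing Psi (CMC condition, site writable for this
    genotype).  A halt before base k leaves a cDNA whose 5' end is the
    (k-1)-th copied base; a halt before the very first base yields no
    cDNA and the fragment is lost.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if condition not in ("CMC", "mock"):
        raise ValueError("condition must be CMC or mock")
    prof = TerminationProfile(
        library_id=library_id,
        condition=condition,
        genotype=genotype,
        experiment=experiment,
        contig_lengths={c: len(s) for c, s in genome.contigs.items()},
    )
    rho_pi = config.adduct_occupancy * config.stop_given_adduct
    b = config.background_stop
    psis_by_contig: dict[str, list[int]] = {}
    for row in truth.itertuples():
        if is_mutant and not row.writable_in_mutant:
            continue
        psis_by_contig.setdefault(row.contig, []).append(int(row.pos0))

    for contig in sorted(genome.contigs):
        L = len(genome.contigs[contig])
        mean_inserts = (
            config.spikein_inserts
            if genome.classes.get(contig) == "spikein"
            else config.inserts_per_transcript
        )
        n = int(rng.poisson(mean_inserts))
        if n == 0:
            prof._ensure(contig, "+")
            continue
        flen = np.clip(
            np.rint(
                rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
            ).astype(np.int64),
            config.fragment_length_min,
            L,
        )
        start = rng.integers(0, L - flen + 1)
        end = start + flen - 1  # 0-based inclusive 3' end
        if b > 0:
            k_eff = rng.geometric(b, n).astype(float)
        else:
            k_eff = np.full(n, np.inf)
        if condition == "CMC" and rho_pi > 0:
            for p in psis_by_contig.get(contig, []):
                covered = (start <= p) & (p <= end)
                trig = covered & (rng.random(n) < rho_pi)
                k_p = np.where(trig, (end - p + 1).astype(float), np.inf)
                k_eff = np.minimum(k_eff, k_p)
        full = k_eff > flen
        lost = k_eff == 1  # stopped before copying any base
        term = np.where(full | lost, -1, end - k_eff + 2).astype(np.int64)
        keep = ~lost
        obs_start = np.where(full, start, term)
        nt, cov = prof._ensure(contig, "+")
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, obs_start[keep], 1)
        np.add.at(diff, end[keep] + 1, -1)
        cov += np.cumsum(diff)[:L]
        term_sites = term[keep & ~full]
        np.add.at(nt, term_sites, 1)
        prof.insert_counts[contig] = int(keep.sum())
    return prof


@dataclass
class SimulatedPair:
    spec: PairSpec
    cmc: TerminationProfile
    mock: TerminationProfile


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeRef
    transcripts: dict[str, TranscriptModel]
    truth: pd.DataFrame
    pairs: list[SimulatedPair]

    def control_pairs(self) -> list[SimulatedPair]:
        return [p for p in self.pairs if not p.spec.is_mutant]

    def mutant_pairs(self) -> list[SimulatedPair]:
        return [p for p in self.pairs if p.spec.is_mutant]

    def truth_sites(self, writable_in_mutant: bool | None = None) -> set:
        t = self.truth
        if writable_in_mutant is not None:
            t = t[t["writable_in_mutant"] == writable_in_mutant]
        return {(r.contig, r.strand, r.pos0) for r in t.itertuples()}


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate reference, truth and all library profiles of the layout."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + 2 * len(config.layout))
    genome, transcripts, truth = generate_reference(
        config, np.random.default_rng(children[0])
    )
    pairs = []
    for i, spec in enumerate(config.layout):
        profs = {}
        for j, condition in enumerate(("CMC", "mock")):
            profs[condition] = simulate_library(
                genome,
                truth,
                config,
                library_id=f"{spec.pair_id}_{condition}",
                condition=condition,
                genotype=spec.genotype,
                experiment=spec.experiment,
                is_mutant=spec.is_mutant,
                rng=np.random.default_rng(children[1 + 2 * i + j]),
            )
        pairs.append(SimulatedPair(spec=spec, cmc=profs["CMC"], mock=profs["mock"]))
    return SyntheticDataset(
        config=config,
        genome=genome,
        transcripts=transcripts,
        truth=truth,
        pairs=pairs,
    )


def null_config(config: SyntheticConfig, seed: int | None = None) -> SyntheticConfig:
    """Same generative process with the Psi-specific stop switched off
    (rho*pi = 0): CMC and mock become exchangeable draws."""
    kwargs = {"adduct_occupancy": 0.0, "stop_given_adduct": 0.0}
    if seed is not None:
        kwargs["seed"] = seed
    return replace(config, **kwargs)


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    """Truth sites as BED; the name field carries the mutant-writable flag."""
    with open(path, "w") as fh:
        for r in truth.itertuples():
            name = "writable" if r.writable_in_mutant else "unwritable"
            fh.write(
                f"{r.contig}\t{r.pos0}\t{r.pos0 + 1}\t{name}\t0\t{r.strand}\n"
            )


def read_truth_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, s, _e, name, _score, strand = line.split("\t")[:6]
            rows.append(
                {
                    "contig": contig,
                    "strand": strand.strip(),
                    "pos0": int(s),
                    "writable_in_mutant": name == "writable",
                }
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)
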