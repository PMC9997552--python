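import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import fisher_exact

from psiseq.codons import (
    classify_region,
    classify_site_regions,
    codon_context,
    codon_abundance,
    codon_rows,
    codon_binomial_test,
    psi_ga_fisher,
    psi_codon_label,
    parse_psi_codon,
    all_psi_codon_rows,
    load_published_census,
    recompute_published_table,
    motif_flanks,
    gene_summaries,
    T_NUCLEAR,
    T_MITO,
)
from psiseq.profiles import TerminationProfile
from psiseq.reference import GenomeRef, TranscriptModel


def _tx(seq_len=60, cds=(9, 39), strand="+", exons=None, tid="t", gene="g"):
    exons = exons or ((0, seq_len),)
    return TranscriptModel(tid, gene, "mRNA", "c", strand, exons, cds)


def test_classify_region_utr_cds_intron():
    t = _tx()
    assert classify_region("c", "+", 5, t) == "5UTR"
    assert classify_region("c", "+", 15, t) == "coding"
    assert classify_region("c", "+", 45, t) == "3UTR"
    spliced = _tx(exons=((0, 20), (30, 70)), cds=(9, 39))
    assert classify_region("c", "+", 25, spliced) == "intron"
    noncoding = TranscriptModel("n", "g", "ncRNA", "c", "+", ((0, 60),))
    assert classify_region("c", "+", 15, noncoding) is None


def test_site_can_carry_multiple_region_labels():
    a = _tx(cds=(9, 39), tid="a")
    b = _tx(cds=(21, 51), tid="b")
    # position 15 is coding on a but 5'UTR on b
    assert classify_site_regions("c", "+", 15, [a, b]) == {"coding", "5UTR"}


def test_codon_context_frame_arithmetic():
    #         CDS: ATG CTG TAA  starting at genomic 3
    genome = GenomeRef(contigs={"c": "AAAATGCTGTAACCCAAATTTGGGAAACCC"})
    t = _tx(seq_len=30, cds=(3, 12))
    # Psi at CDS position 5 (1-based) = genomic 7: codon CTG, index 2
    label, codon, idx, aa = codon_context("c", "+", 7, t, genome)
    assert (label, codon, idx, aa) == ("CΨG", "CTG", 2, "L")


def test_codon_context_first_position():
    genome = GenomeRef(contigs={"c": "TTGAAATAAGGGCCCAAATTTGGGAAACCC"})
    t = _tx(seq_len=30, cds=(0, 9))
    label, codon, idx, aa = codon_context("c", "+", 0, t, genome)
    assert label == "ΨUG"
    assert aa == "L"


def test_codon_context_rejects_non_uridine():
    genome = GenomeRef(contigs={"c": "AAAATGCTGTAACCCAAATTTGGGAAACCC"})
    t = _tx(seq_len=30, cds=(3, 12))
    with pytest.raises(ValueError, match="not T"):
        codon_context("c", "+", 3, t, genome)  # the 'A' of ATG


def test_mitochondrial_uga_reads_tryptophan():
    genome = GenomeRef(
        contigs={"m": "TGACCCAAATTTGGGAAACCCAAATTTGGG"},
        classes={"m": "mitochondrial"},
    )
    t = TranscriptModel("t", "g", "mRNA", "m", "+", ((0, 30),), (0, 9))
    label, codon, idx, aa = codon_context("m", "+", 0, t, genome)
    assert (label, aa) == ("ΨGA", "W")


def test_psi_codon_label_round_trip():
    for codon, idx in all_psi_codon_rows():
        assert parse_psi_codon(psi_codon_label(codon, idx)) == (codon, idx)
    assert len(all_psi_codon_rows()) == 48


def test_codon_abundance_counts_and_normalizer():
    genome = GenomeRef(contigs={"c": "ATGTTTTAA" + "A" * 51})
    t = _tx(seq_len=60, cds=(0, 9))
    counts, N = codon_abundance({"t": t}, genome)
    assert counts == {"ATG": 1, "TTT": 1, "TAA": 1}
    assert N == 3  # every codon here carries at least one uridine


def test_codon_abundance_coverage_qualifier():
    genome = GenomeRef(contigs={"c": "ATGTTTTAA" + "A" * 51})
    t = _tx(seq_len=60, cds=(0, 9))
    with pytest.raises(ValueError, match="no qualifying"):
        codon_abundance({"t": t}, genome, gene_coverage={"g": 3.0}, min_coverage=10)
    counts, _ = codon_abundance(
        {"t": t}, genome, gene_coverage={"g": 30.0}, min_coverage=10
    )
    assert counts["TTT"] == 1


def test_published_normalizers():
    """Summing the printed abundance columns over distinct uridine-
    containing base codons yields the study's normalizers."""
    census = load_published_census()
    for prefix, expected in (("nuclear", 3_701_347), ("mito", 1_982)):
        per_codon = census.groupby("base_codon")[f"{prefix}_abundance"].first()
        assert int(per_codon.sum()) == expected


def test_expected_counts_sum_to_total_sites():
    for cls, T in (("nuclear", T_NUCLEAR), ("mitochondrial", T_MITO)):
        df = recompute_published_table(cls)
        assert df["expected"].sum() == pytest.approx(T, abs=1e-9)


@pytest.mark.parametrize(
    "cls,codon,expected",
    [("nuclear", "GCΨ", 26), ("nuclear", "ΨUC", 20)],
)
def test_expected_count_spot_values(cls, codon, expected):
    df = recompute_published_table(cls).set_index("psi_codon")
    assert df.loc[codon, "expected_rounded"] == expected


def test_binomial_spot_values():
    df = recompute_published_table("mitochondrial").set_index("psi_codon")
    # mito UUΨ: enrichment, strict upper tail
    assert float(f"{df.loc['UUΨ', 'p_adj']:.2e}") == 3.51e-3
    dfn = recompute_published_table("nuclear").set_index("psi_codon")
    # nuclear ΨAA observed 0: adjusted p caps at 1
    assert dfn.loc["ΨAA", "p_adj"] == 1.0
    # nuclear AΨA: strong depletion (matches print to its last digit)
    assert dfn.loc["AΨA", "p_adj"] == pytest.approx(7.44e-6, rel=2e-3)


def _binom_pmf(k, n, q):
    return comb(n, k, exact=True) * q**k * (1 - q) ** (n - k)


@pytest.mark.parametrize("T", [5, 12, 20])
def test_binomial_tails_match_enumeration(T):
    """Strict/inclusive tails reduce to exhaustive enumeration."""
    rng = np.random.default_rng(T)
    for _ in range(20):
        q = rng.uniform(0.01, 0.8)
        obs = int(rng.integers(0, T + 1))
        p_raw, p_adj = codon_binomial_test(q, T, obs, n_rows=48)
        E = T * q
        if obs > E:
            expected = sum(_binom_pmf(k, T, q) for k in range(obs + 1, T + 1))
        else:
            expected = sum(_binom_pmf(k, T, q) for k in range(0, obs + 1))
        assert p_raw == pytest.approx(expected, rel=1e-9, abs=1e-300)
        assert p_adj == pytest.approx(min(1.0, 48 * expected), rel=1e-9)


def test_codon_rows_zero_abundance_row_is_null():
    rows = codon_rows({"TTT": 10, "AAA": 5}, {}, T=10)
    row = rows.set_index("psi_codon").loc["CΨC"]
    assert row["abundance"] == 0
    assert row["p_adj"] == 1.0


def test_fisher_psi_ga_published_value():
    assert psi_ga_fisher([[5, 63], [0, 3321]]) == pytest.approx(2.81e-9, rel=5e-3)


def test_fisher_degenerate_tables():
    assert psi_ga_fisher([[0, 68], [0, 3321]]) == 1.0
    # both margins 1: two equally likely tables
    assert psi_ga_fisher([[1, 0], [0, 1]]) == pytest.approx(0.5)


def test_fisher_row_swap_flips_tail():
    table = np.array([[5, 63], [1, 3321]])
    p_swapped = psi_ga_fisher(table[::-1])
    p_less = fisher_exact(table, alternative="less")[1]
    assert p_swapped == pytest.approx(p_less, rel=1e-12)


# ---------------------------------------------------------------------------
# motif flanks and gene summaries


def _siteset(rows):
    return pd.DataFrame(
        [{"contig": c, "strand": s, "psi_pos0": p} for c, s, p in rows]
    )


def test_motif_single_site_is_one_hot():
    seq = "ACGTACGTACTTACGTACGTA"  # 21 nt, Psi at centre (pos 10 = T)
    genome = GenomeRef(contigs={"c": seq})
    pfm = motif_flanks(_siteset([("c", "+", 10)]), genome)
    assert pfm.shape == (4, 21)
    for j, base in enumerate(seq):
        rna = "U" if base == "T" else base
        assert pfm.loc[rna].iloc[j] == 1.0
    assert pfm.loc["U", "0"] == 1.0


def test_motif_truncated_window_pads_with_n():
    genome = GenomeRef(contigs={"c": "AAATGGGGGGGGGGGGGGGGGGGG"})
    # site 4 nt from the 5' end -> 6 leading N columns with zero mass
    pfm = motif_flanks(_siteset([("c", "+", 3)]), genome)
    lead = pfm.iloc[:, :6].to_numpy()
    assert (lead.sum(axis=0) == 0).all()
    assert pfm.loc["U", "0"] == 1.0


def test_motif_center_always_uridine(default_dataset):
    from psiseq.calling import call_pair, aggregate_replicates

    calls = [
        call_pair(p.cmc, p.mock, default_dataset.genome, default_dataset.transcripts)[1]
        for p in default_dataset.control_pairs()[2:4]  # one pair per experiment
    ]
    sites = aggregate_replicates(calls)
    pfm = motif_flanks(sites, default_dataset.genome, default_dataset.transcripts)
    assert pfm.loc["U", "0"] == 1.0
    assert np.allclose(pfm.sum(axis=0), 1.0)


def test_motif_empty_sites_rejected():
    genome = GenomeRef(contigs={"c": "ACGT"})
    with pytest.raises(ValueError, match="empty"):
        motif_flanks(_siteset([]), genome)


def test_rpkm_definition():
    # 10 inserts on a 1,000-nt transcript out of 1e6 total -> RPKM 10
    genome = GenomeRef(contigs={"gene": "A" * 500 + "T" * 500, "rest": "A" * 100})
    t = TranscriptModel("t", "g", "mRNA", "gene", "+", ((0, 1000),))
    prof = TerminationProfile("L", "CMC", "", "", {"gene": 1000, "rest": 100})
    nt, cov = prof._ensure("gene", "+")
    cov[:] = 1  # 10 inserts of length 100 -> coverage mass 1000
    prof.insert_counts["gene"] = 10
    nt2, cov2 = prof._ensure("rest", "+")
    cov2[:] = (1_000_000 - 10) * 100 // 100  # mass keeps mean length at 100
    prof.insert_counts["rest"] = 1_000_000 - 10
    out = gene_summaries(_siteset([]), {"t": t}, genome, [prof])
    row = out.set_index("gene_id").loc["g"]
    assert row["rpkm"] == pytest.approx(10.0, rel=1e-3)
    assert row["n_psi"] == 0  # genes without sites stay in the table
    assert row["n_uridines"] == 500


def test_gene_summary_percent_modified():
    genome = GenomeRef(contigs={"gene": "T" * 100})
    t = TranscriptModel("t", "g", "mRNA", "gene", "+", ((0, 100),))
    prof = TerminationProfile("L", "CMC", "", "", {"gene": 100})
    _nt, cov = prof._ensure("gene", "+")
    cov[:] = 50
    prof.insert_counts["gene"] = 50
    sites = _siteset([("gene", "+", i) for i in (10, 20, 30, 40, 50)])
    out = gene_summaries(sites, {"t": t}, genome, [prof])
    assert out.iloc[0]["pct_u_modified"] == pytest.approx(5.0)
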