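"""Per-site termination ratios and paired CMC/mock statistics tables.

The termination ratio (TR) at a site is the fraction of covering inserts
whose RT stop falls exactly there; the termination fold change (TFC) is
log2(TR_CMC / TR_Mock).  TFC is a diagnostic — site calling uses the
two-proportion z-test in :mod:`psiseq.calling`, never a TFC threshold.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .profiles import TerminationProfile

#: column order of the per-site statistics table
SITE_STAT_COLUMNS = [
    "contig",
    "strand",
    "pos0",
    "cvg_cmc",
    "n_term_cmc",
    "tr_cmc",
    "cvg_mock",
    "n_term_mock",
    "tr_mock",
    "pooled_p",
    "z",
    "pval",
    "padj",
    "relevant",
    "tfc",
]


def termination_ratio(n_term: int, coverage: int) -> float:
    """TR = terminating inserts / covering inserts."""
    if coverage <= 0:
        raise ValueError("termination ratio undefined at zero coverage")
    if n_term > coverage:
        raise ValueError(f"n_term {n_term} > coverage {coverage}")
    return n_term / coverage


def termination_fold_change(tr_cmc: float, tr_mock: float) -> float:
    """log2(TR_CMC / TR_Mock).

    Returns +inf when TR_Mock is 0 with positive TR_CMC, and NaN
    (undefined) when TR_CMC is 0.
    """
    if tr_cmc == 0:
        return math.nan
    if tr_mock == 0:
        return math.inf
    return math.log2(tr_cmc / tr_mock)


def pair_stats(
    cmc: TerminationProfile,
    mock: TerminationProfile,
    min_term: int = 5,
    min_readthrough: int = 5,
) -> pd.DataFrame:
    """Assemble the per-site table for one CMC/mock library pair.

    One row per position with positive coverage in *both* profiles
    (zero mock coverage makes the mock proportion undefined, so such
    sites are untestable and dropped).  The relevance flag implements
    the >=min_term terminating / >=min_readthrough continuing rule on
    the CMC side.  z/pval/padj columns are filled by
    :func:`psiseq.calling.annotate_significance`.
    """
    if cmc.condition != "CMC" or mock.condition != "mock":
        raise ValueError("pair_stats expects (CMC, mock) profiles in that order")
    if cmc.contig_lengths != mock.contig_lengths:
        raise ValueError("profiles built against different references")
    frames = []
    for key in sorted(set(cmc.coverage) | set(mock.coverage)):
        if key not in cmc.coverage or key not in mock.coverage:
            continue
        contig, strand = key
        cov_c = cmc.coverage[key]
        cov_m = mock.coverage[key]
        mask = (cov_c > 0) & (cov_m > 0)
        pos = np.nonzero(mask)[0]
        if pos.size == 0:
            continue
        nt_c = cmc.n_term[key][pos]
        nt_m = mock.n_term[key][pos]
        cc = cov_c[pos]
        cm = cov_m[pos]
        tr_c = nt_c / cc
        tr_m = nt_m / cm
        with np.errstate(divide="ignore", invalid="ignore"):
            tfc = np.log2(tr_c / tr_m)
        tfc = np.where(tr_c == 0, np.nan, tfc)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "strand": strand,
                    "pos0": pos,
                    "cvg_cmc": cc,
                    "n_term_cmc": nt_c,
                    "tr_cmc": tr_c,
                    "cvg_mock": cm,
                    "n_term_mock": nt_m,
                    "tr_mock": tr_m,
                    "pooled_p": (nt_c + nt_m) / (cc + cm),
                    "z": np.nan,
                    "pval": np.nan,
                    "padj": np.nan,
                    "relevant": (nt_c >= min_term)
                    & ((cc - nt_c) >= min_readthrough),
                    "tfc": tfc,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SITE_STAT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SITE_STAT_COLUMNS]


def write_stats_tsv(stats: pd.DataFrame, path) -> None:
    out = stats.copy()
    out.insert(2, "position", out.pop("pos0") + 1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def spikein_profile(
    stats: pd.DataFrame, spike_contig: str = "spikein"
) -> pd.DataFrame:
    """Per-position TFC along the spike-in for one library pair.

    Returns a frame with 1-based ``position`` and ``tfc`` columns,
    ordered by position — the per-pair input to the spike-in QC plot.
    """
    sub = stats[stats["contig"] == spike_contig]
    if sub.empty:
        raise ValueError(f"spike-in contig {spike_contig!r} absent from stats")
    out = sub[
        ["pos0", "n_term_cmc", "cvg_cmc", "n_term_mock", "cvg_mock", "tfc"]
    ].copy().sort_values("pos0")
    # Haldane–Anscombe corrected TFC: finite even at zero mock counts,
    # used for peak ranking; the plain TFC is kept for reporting
    out["tfc_shrunk"] = np.log2(
        ((out["n_term_cmc"] + 0.5) / (out["cvg_cmc"] + 1))
        / ((out["n_term_mock"] + 0.5) / (out["cvg_mock"] + 1))
    )
    out["position"] = out.pop("pos0") + 1
    cols = ["position", "n_term_cmc", "cvg_cmc", "n_term_mock", "cvg_mock", "tfc", "tfc_shrunk"]
    return out[cols].reset_index(drop=True)


def spikein_peak(profile: pd.DataFrame) -> tuple[int, float]:
    """(position, corrected TFC) of the spike-in maximum.

    Ranking uses the Haldane–Anscombe corrected fold change, which stays
    finite when a position saw no mock terminations at all; the raw TFC
    of such positions is +inf and uninformative about effect size.
    """
    row = profile.loc[profile["tfc_shrunk"].idxmax()]
    return int(row["position"]), float(row["tfc_shrunk"])


def median_spikein_profile(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-position median TFC across library pairs (the aggregate view
    of the spike-in box plot); infinities are ignored position-wise."""
    merged = pd.concat(
        [p[["position", "tfc"]] for p in profiles], ignore_index=True
    )
    merged = merged[np.isfinite(merged["tfc"])]
    out = (
        merged.groupby("position", as_index=False)["tfc"].median()
    ).sort_values("position")
    return out.reset_index(drop=True)
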