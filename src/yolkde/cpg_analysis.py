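"""CpG-density analysis around transcription start sites.

DNA methylation targets CpG dinucleotides; genes with CpG-poor promoters are
plausibly less subject to methylation-mediated regulation.  This module
counts CpG sites in promoter/gene/CDS sequences, projects the counts of DE
genes onto the all-gene empirical cumulative distribution, compares the two
samples with a two-sided Kolmogorov-Smirnov test, and profiles CpG density
in consecutive 500-nt windows from the 5' end of each region.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import GeneSequence

DEFAULT_WINDOW_NT = 500

_VALID = set("ACGTN")


def count_cpg(sequence: str) -> int:
    """Number of CpG (5'-CG-3') dinucleotides; case-insensitive, N never
    matches.  CG cannot overlap itself, so a position scan and
    non-overlapping counting coincide."""
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq.count("CG")


def ecdf_projection(all_counts, de_counts) -> np.ndarray:
    """Evaluate the all-gene ECDF at each DE-gene count.

    F(x) = #{all_counts <= x} / |all_counts|; the returned values are what a
    rank plot of DE genes against the genome-wide background displays.
    """
    all_arr = np.sort(np.asarray(all_counts))
    if all_arr.size == 0:
        raise ValueError("background counts must be non-empty")
    de_arr = np.asarray(de_counts)
    if de_arr.size == 0:
        return np.empty(0)
    return np.searchsorted(all_arr, de_arr, side="right") / all_arr.size


def ks_compare(all_counts, de_counts) -> tuple[float, float]:
    """Two-sample two-sided KS test (asymptotic p) of DE vs background
    counts; identical degenerate samples give (0, 1)."""
    all_arr = np.asarray(all_counts, dtype=float)
    de_arr = np.asarray(de_counts, dtype=float)
    if all_arr.size < 2 or de_arr.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(de_arr, all_arr, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def window_counts(sequence: str, window: int = DEFAULT_WINDOW_NT) -> np.ndarray:
    """CpG counts in consecutive non-overlapping windows from the 5' end;
    the final partial window is dropped and a CG spanning a window boundary
    is not counted, so each window count is at most window // 2."""
    if window < 2:
        raise ValueError("window must be >= 2")
    seq = sequence.upper()
    n_win = len(seq) // window
    counts = np.empty(n_win, dtype=int)
    for w in range(n_win):
        counts[w] = count_cpg(seq[w * window: (w + 1) * window])
    return counts


def cpg_count_table(sequences: Iterable[GeneSequence],
                    window: int = DEFAULT_WINDOW_NT) -> pd.DataFrame:
    """Total and per-window CpG counts for every sequence record."""
    rows = []
    for rec in sequences:
        rows.append({
            "gene_id": rec.gene_id,
            "region": rec.region,
            "total_count": count_cpg(rec.sequence),
            "window_counts": window_counts(rec.sequence, window),
        })
    return pd.DataFrame(rows, columns=["gene_id", "region", "total_count",
                                       "window_counts"])


def windowed_cpg_profile(
    sequences: Iterable[GeneSequence] | Mapping[str, str],
    de_up: Sequence[str] = (),
    de_down: Sequence[str] = (),
    window: int = DEFAULT_WINDOW_NT,
) -> pd.DataFrame:
    """Group-wise mean CpG count per 500-nt window, with per-window KS tests.

    Rows are windows (0-based, from the 5' end); columns hold the mean CpG
    count of all genes, DE-up genes and DE-down genes whose sequence reaches
    that window, plus the KS p-value of each DE group against all genes in
    that window.  Sequences shorter than one window contribute nothing.
    """
    if isinstance(sequences, Mapping):
        sequences = [GeneSequence(g, "gene", s) for g, s in sequences.items()]
    table = cpg_count_table(sequences, window)
    if len(set(table["region"])) > 1:
        raise ValueError("profile expects sequences from a single region")

    up, down = set(de_up), set(de_down)
    n_win = max((len(w) for w in table["window_counts"]), default=0)
    rows = []
    for w in range(n_win):
        have = table[[len(c) > w for c in table["window_counts"]]]
        vals = np.array([c[w] for c in have["window_counts"]])
        in_up = have["gene_id"].isin(up).to_numpy()
        in_down = have["gene_id"].isin(down).to_numpy()
        row = {
            "window": w,
            "mean_all": vals.mean(),
            "mean_up": vals[in_up].mean() if in_up.any() else np.nan,
            "mean_down": vals[in_down].mean() if in_down.any() else np.nan,
            "ks_p_up": np.nan,
            "ks_p_down": np.nan,
        }
        if in_up.sum() >= 2:
            row["ks_p_up"] = ks_compare(vals, vals[in_up])[1]
        if in_down.sum() >= 2:
            row["ks_p_down"] = ks_compare(vals, vals[in_down])[1]
        rows.append(row)
    return pd.DataFrame(rows, columns=["window", "mean_all", "mean_up",
                                       "mean_down", "ks_p_up", "ks_p_down"])
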