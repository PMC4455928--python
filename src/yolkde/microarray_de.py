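"""Microarray differential expression via an intensity-sorted local Z-score.

Log-intensity variance on arrays depends strongly on signal intensity, so a
single global null distribution over-calls dim transcripts.  The statistic
implemented here normalizes each transcript's differential-expression score
against its local neighbourhood in intensity space:

1. keep probes flagged reliable on strictly more than 2/3 of arrays,
2. quantile-normalize the arrays,
3. average probes to transcripts,
4. per transcript: intensity score = mean of the YD and SP median
   intensities; DE score = median of the 9 pairwise YD - SP differences,
5. order transcripts by intensity score and standardize each DE score by the
   mean and sample SD of the 65 transcripts centred on it,
6. two-sided normal p-values, BH correction, selection at FDR < 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .datatypes import (
    DE_TABLE_COLUMNS,
    DesignError,
    IntensityMatrix,
    validate_de_table,
)
from .rnaseq_de import bh_adjust

DEFAULT_WINDOW = 65
DEFAULT_FDR = 0.1


def filter_pflag(m: IntensityMatrix) -> IntensityMatrix:
    """Keep probes reliable on strictly more than 2/3 of the arrays
    (5 of 6 in the default design; 4 of 6 is exactly 2/3 and is dropped)."""
    frac = m.flags.mean(axis=1)
    return m.subset_probes(m.probe_ids[frac > 2.0 / 3.0])


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Force every array onto the mean empirical distribution.

    Each array's sorted vector is replaced by the across-array mean of
    sorted vectors; tied values within an array receive the average of the
    quantile means their positions span.
    """
    vals = m.log_intensities.to_numpy(dtype=float)
    if vals.shape[0] < 1:
        raise ValueError("need at least one probe")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean")
    return m.with_intensities(
        pd.DataFrame(out, index=m.log_intensities.index,
                     columns=m.log_intensities.columns)
    )


def collapse_probes(m: IntensityMatrix) -> pd.DataFrame:
    """Transcript x array table: arithmetic mean of each transcript's probes."""
    transcripts = m.probe_map.loc[m.probe_ids]
    collapsed = m.log_intensities.groupby(transcripts.to_numpy()).mean()
    collapsed.index.name = "transcript_id"
    return collapsed


def score_transcripts(table: pd.DataFrame, array_meta: pd.DataFrame) -> pd.DataFrame:
    """Intensity and DE scores per transcript.

    intensity_score = (median over YD arrays + median over SP arrays) / 2;
    de_score = median of all 9 pairwise YD - SP differences.  Requires the
    3 + 3 design.
    """
    yd = array_meta.index[array_meta["condition"] == "YD"]
    sp = array_meta.index[array_meta["condition"] == "SP"]
    if len(yd) != 3 or len(sp) != 3:
        raise DesignError("transcript scoring expects 3 YD and 3 SP arrays")
    missing = (set(yd) | set(sp)) - set(table.columns)
    if missing:
        raise DesignError(f"arrays missing from the table: {sorted(missing)}")

    yd_vals = table[list(yd)].to_numpy()
    sp_vals = table[list(sp)].to_numpy()
    intensity = (np.median(yd_vals, axis=1) + np.median(sp_vals, axis=1)) / 2.0
    pairwise = yd_vals[:, :, None] - sp_vals[:, None, :]
    de = np.median(pairwise.reshape(len(table), -1), axis=1)
    return pd.DataFrame(
        {"transcript_id": table.index, "intensity_score": intensity, "de_score": de}
    ).reset_index(drop=True)


def sliding_window_z(scores: pd.DataFrame, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Standardize DE scores within intensity-ranked windows.

    Transcripts are sorted by descending intensity score (ties broken by
    transcript_id); each transcript's window is the ``window`` transcripts
    centred on it, clamped at both edges so it always holds exactly
    ``window`` members (the focal transcript included).  z uses the window
    mean and sample SD (n-1); a zero-SD window yields z = 0, marked in the
    ``degenerate`` column.
    """
    n = len(scores)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if n < window:
        raise ValueError(f"need at least {window} transcripts, got {n}")

    ordered = scores.sort_values(
        ["intensity_score", "transcript_id"], ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)
    de = ordered["de_score"].to_numpy(dtype=float)

    half = window // 2
    views = sliding_window_view(de, window)
    win_mean = views.mean(axis=1)
    win_sd = views.std(axis=1, ddof=1)
    start = np.clip(np.arange(n), half, n - 1 - half) - half
    mean_i, sd_i = win_mean[start], win_sd[start]

    degenerate = sd_i == 0
    z = np.zeros(n)
    np.divide(de - mean_i, sd_i, out=z, where=~degenerate)
    ordered["z"] = z
    ordered["degenerate"] = degenerate
    return ordered


def call_microarray_de(m: IntensityMatrix, fdr_threshold: float = DEFAULT_FDR,
                       window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Full microarray DE caller; returns the shared DE-table schema.

    ``score`` carries the transcript DE score (median pairwise YD - SP
    difference); direction follows its sign; ``passed`` requires BH FDR
    strictly below ``fdr_threshold``.  The local Z is returned as an extra
    ``z`` column alongside the shared schema.
    """
    kept = filter_pflag(m)
    normalized = quantile_normalize(kept)
    transcripts = collapse_probes(normalized)
    scored = score_transcripts(transcripts, m.array_meta)
    scored = sliding_window_z(scored, window=window)

    p = 2.0 * stats.norm.sf(np.abs(scored["z"].to_numpy()))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "gene_id": scored["transcript_id"],
            "score": scored["de_score"],
            "p_raw": p,
            "fdr": bh_adjust(p),
            "direction": np.where(scored["de_score"] >= 0, "up_in_YD", "down_in_YD"),
            "z": scored["z"],
        }
    )
    out["passed"] = out["fdr"] < fdr_threshold
    out = out.sort_values("gene_id", kind="stable").reset_index(drop=True)
    return validate_de_table(out[DE_TABLE_COLUMNS + ["z"]])
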