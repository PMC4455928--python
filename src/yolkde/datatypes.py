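"""Shared data containers for the yolk-depletion expression pipeline.

The two profiled conditions are yolk-depleted (``YD``) and sham-punctured
(``SP``) zebrafish embryos.  Counts, intensities and derived tables are kept
as pandas objects wrapped in light dataclasses that enforce the study design
(paired YD/SP samples per batch for RNA-seq; 3 YD + 3 SP arrays for the
microarray) at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("YD", "SP")

DE_TABLE_COLUMNS = ["gene_id", "score", "p_raw", "fdr", "direction", "passed"]


class DesignError(ValueError):
    """Raised when sample/array metadata violates the expected design."""


@dataclass
class CountMatrix:
    """Gene x sample read counts with per-sample condition and batch labels.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by gene_id with one column per sample.
    sample_meta
        DataFrame indexed by sample_id with columns ``condition`` (YD/SP)
        and ``batch``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise DesignError("count columns and sample metadata rows disagree")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise DesignError("negative counts")
        if not np.issubdtype(vals.dtype, np.integer) and not np.allclose(
            vals, np.round(vals)
        ):
            raise DesignError("counts must be integral")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise DesignError(f"unknown conditions: {sorted(bad)}")
        # paired design: each batch holds exactly one YD and one SP sample
        for batch, grp in self.sample_meta.groupby("batch"):
            conds = sorted(grp["condition"])
            if conds != ["SP", "YD"]:
                raise DesignError(
                    f"batch {batch!r} must contain exactly one YD and one SP "
                    f"sample, got {conds}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def samples_of(self, condition: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["condition"] == condition])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.sample_meta)


@dataclass
class IntensityMatrix:
    """Probe x array log-intensities with reliability flags and a probe map.

    ``flags`` mirrors Agilent's per-array "P-flag": True marks a probe whose
    signal-to-noise was acceptable on that array.  ``probe_map`` assigns each
    probe to exactly one transcript.
    """

    log_intensities: pd.DataFrame
    flags: pd.DataFrame
    probe_map: pd.Series
    array_meta: pd.DataFrame
    strict_design: bool = True

    def __post_init__(self) -> None:
        if self.log_intensities.shape != self.flags.shape:
            raise DesignError("intensity and flag matrices differ in shape")
        if not self.log_intensities.index.equals(self.flags.index):
            raise DesignError("intensity and flag probe ids differ")
        if not self.log_intensities.index.isin(self.probe_map.index).all():
            raise DesignError("probe_map does not cover all probes")
        bad = set(self.array_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise DesignError(f"unknown conditions: {sorted(bad)}")
        if self.strict_design:
            n_yd = int((self.array_meta["condition"] == "YD").sum())
            n_sp = int((self.array_meta["condition"] == "SP").sum())
            if (n_yd, n_sp) != (3, 3):
                raise DesignError(
                    f"default design expects 3 YD + 3 SP arrays, got "
                    f"{n_yd} YD + {n_sp} SP"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.log_intensities.index

    @property
    def n_arrays(self) -> int:
        return self.log_intensities.shape[1]

    def arrays_of(self, condition: str) -> list[str]:
        meta = self.array_meta
        return list(meta.index[meta["condition"] == condition])

    def subset_probes(self, probe_ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.log_intensities.loc[probe_ids],
            self.flags.loc[probe_ids],
            self.probe_map,
            self.array_meta,
            strict_design=self.strict_design,
        )

    def with_intensities(self, values: pd.DataFrame) -> "IntensityMatrix":
        return IntensityMatrix(
            values, self.flags, self.probe_map, self.array_meta,
            strict_design=self.strict_design,
        )


@dataclass
class GeneSet:
    """A named set of gene identifiers (e.g. the apolipoprotein genes)."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of the shared DE-table schema and return it.

    Every stage emits the same currency: gene_id, score (log2 YD/SP effect
    for RNA-seq, local Z DE score for the microarray), raw p, BH FDR,
    direction and a boolean pass flag.
    """
    missing = set(DE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if len(table):
        p, q = table["p_raw"].to_numpy(), table["fdr"].to_numpy()
        if np.any((p < 0) | (p > 1)) or np.any((q < 0) | (q > 1)):
            raise ValueError("p/fdr outside [0, 1]")
        if np.any(q < p - 1e-12):
            raise ValueError("BH-adjusted values must not fall below raw p")
        bad_dir = ~table["direction"].isin(["up_in_YD", "down_in_YD"])
        if bad_dir.any():
            raise ValueError("invalid direction labels")
    return table
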