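"""Gene-set enrichment: hypergeometric tests and permutation overlap tests.

Two complementary tools used on the DE gene lists:

* upper-tail hypergeometric tests against a fixed expressed-gene universe
  (apolipoprotein genes; molecular-function GO terms with BH selection), and
* empirical permutation tests that replace the DE list with random
  identifier samples of the same size and count overlaps with a target set
  (methionine-cycle enzymes), or — in the cross-species variant — keep the
  DE list fixed and resample target-sized symbol sets from the mouse
  universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet
from .rnaseq_de import bh_adjust

DEFAULT_PERMUTATIONS = 1000


@dataclass
class PermutationResult:
    """Outcome of an empirical overlap test.

    ``p`` is the fraction of the ``B`` null overlaps that is greater than or
    equal to the observed overlap; an observed overlap exceeded by no null
    draw is stored as 0.0 and rendered as ``< 1/B``.
    """

    observed_overlap: int
    null_overlaps: np.ndarray
    p: float
    B: int

    def format_p(self) -> str:
        return f"< {1.0 / self.B:g}" if self.p == 0.0 else f"{self.p:g}"


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed through the survival function in log space for numerical
    stability far in the tail.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(N, K, n) < 0:
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    with np.errstate(divide="ignore"):
        logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(np.exp(logp))


def gene_set_enrichment(de_genes, gene_set: GeneSet, universe) -> dict:
    """Hypergeometric enrichment of one named set in one DE list."""
    universe = set(universe)
    de = set(de_genes) & universe
    members = gene_set.members & universe
    k = len(de & members)
    p = hypergeom_upper_tail(len(universe), len(members), len(de), k)
    return {"set": gene_set.name, "k": k, "n": len(de), "K": len(members),
            "N": len(universe), "p_raw": p}


def go_term_enrichment(
    de_genes,
    annotation: pd.DataFrame,
    universe,
    fdr_threshold: float = 0.05,
    min_de_members: int = 2,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment over molecular-function GO terms.

    Only terms annotating at least ``min_de_members`` DE genes are tested;
    BH correction runs across the tested terms and a term is significant at
    FDR < ``fdr_threshold``.  ``annotation`` needs columns ``gene_id`` and
    ``go_terms`` (semicolon-joined).
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("DE genes must be a subset of the universe")
    if not de:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p_raw", "fdr", "significant"]
        )

    ann = annotation[annotation["gene_id"].isin(universe)]
    term_genes: dict[str, set] = {}
    for gid, terms in zip(ann["gene_id"], ann["go_terms"]):
        if isinstance(terms, str) and terms:
            for t in terms.split(";"):
                term_genes.setdefault(t, set()).add(gid)

    rows = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & de)
        if k < min_de_members:
            continue
        rows.append({
            "term": term, "k": k, "n": len(de), "K": len(genes),
            "N": len(universe),
            "p_raw": hypergeom_upper_tail(len(universe), len(genes), len(de), k),
        })
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_raw"])
    if len(result):
        result["fdr"] = bh_adjust(result["p_raw"].to_numpy())
        result["significant"] = result["fdr"] < fdr_threshold
    else:
        result["fdr"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result.reset_index(drop=True)


def _null_overlap_counts(rng: np.random.Generator, universe: np.ndarray,
                         in_target: np.ndarray, sample_size: int,
                         B: int) -> np.ndarray:
    """Overlap of B uniform without-replacement samples with a fixed mask."""
    counts = np.empty(B, dtype=np.int64)
    n_univ = len(universe)
    for b in range(B):
        idx = rng.choice(n_univ, size=sample_size, replace=False)
        counts[b] = int(in_target[idx].sum())
    return counts


def permutation_overlap_test(
    de_genes,
    target_set: GeneSet,
    universe,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Empirical test of |DE ∩ target| against random DE-sized samples.

    The DE list is replaced by ``B`` samples of the same size drawn
    uniformly without replacement from the universe of all (DE and non-DE)
    identifiers; p is the fraction of samples whose overlap with the target
    set is >= the observed overlap.
    """
    universe_arr = np.asarray(sorted(set(universe)))
    de = set(de_genes)
    target = set(target_set.members) & set(universe_arr)
    if not target:
        raise ValueError("target set does not intersect the universe")
    if len(de) > len(universe_arr):
        raise ValueError("DE list larger than the universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = len(de & set(target_set.members))
    in_target = np.isin(universe_arr, list(target))
    null = _null_overlap_counts(rng, universe_arr, in_target, len(de), B)
    p = float((null >= observed).sum() / B)
    return PermutationResult(observed, null, p, B)


def cross_species_overlap(
    mouse_de_table: pd.DataFrame,
    target_symbols=None,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Overlap of mouse DE symbols with the methionine-cycle homologues.

    Sampling direction is reversed relative to :func:`permutation_overlap_test`:
    the DE list stays fixed and ``B`` random sets of ``len(target_symbols)``
    symbols are drawn from the mouse universe; p is the fraction of draws
    whose overlap with the DE list is >= the observed target overlap.
    ``mouse_de_table`` needs columns ``symbol`` and ``is_de``.
    """
    from .synthetic_data import MOUSE_METHIONINE_SYMBOLS

    if target_symbols is None:
        target_symbols = MOUSE_METHIONINE_SYMBOLS
    universe_arr = mouse_de_table["symbol"].to_numpy()
    de_mask = mouse_de_table["is_de"].to_numpy(dtype=bool)
    target = set(target_symbols)
    present = target & set(universe_arr)
    if present != target:
        raise ValueError(f"target symbols missing from the universe: "
                         f"{sorted(target - present)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    is_target = np.isin(universe_arr, list(target))
    observed = int((de_mask & is_target).sum())
    null = _null_overlap_counts(rng, universe_arr, de_mask,
                                len(target_symbols), B)
    p = float((null >= observed).sum() / B)
    return PermutationResult(observed, null, p, B)
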