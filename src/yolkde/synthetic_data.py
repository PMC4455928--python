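"""Synthetic inputs emulating the yolk-depletion study's data structure.

Every generator here produces data with the statistical features the
downstream analysis assumes, so the whole pipeline can be exercised and
calibrated without the original ArrayExpress submissions:

* RNA-seq: negative-binomial counts for paired YD/SP samples over three
  batches, with multiplicative (log-additive) batch effects and a set of
  spiked truly-DE genes with a consistent sign in YD.
* Microarray: log-scale probe intensities over 3 YD + 3 SP arrays with
  intensity-dependent noise (low-intensity transcripts are noisier), 1-4
  probes per transcript, and i.i.d. per-probe-per-array reliability flags.
* Annotation: symbols, molecular-function GO terms, and embedded named gene
  sets sized like the study's (28 apolipoprotein-like, 20 methionine-like).
* Sequences: i.i.d. nucleotide promoter/gene/CDS regions with a controllable
  CpG depletion factor for designated genes.
* A mouse symbol-level DE table with a configurable number of the 12
  methionine-cycle homologues flagged DE.

All generators are deterministic given ``SimConfig.seed``; each uses an
independent stream derived from the seed plus a per-generator tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSet, IntensityMatrix

#: Zebrafish methionine-cycle enzymes and DNA/RNA methyltransferases used as
#: the permutation-test target set (creatine kinases deliberately excluded).
METHIONINE_CYCLE_IDS = (
    "ENSDARG00000013430",  # bhmt
    "ENSDARG00000025703",  # dmgd
    "ENSDARG00000058102",  # sardh
    "ENSDARG00000006840",  # gnmt
    "ENSDARG00000070844",  # gamt
    "ENSDARG00000036239",  # gatm
    "ENSDARG00000039134",  # mtr
    "ENSDARG00000039605",  # mat1a
    "ENSDARG00000040334",  # mat2aa
    "ENSDARG00000063665",  # mat2al
    "ENSDARG00000037121",  # mat2ab
    "ENSDARG00000012932",  # mat2b
    "ENSDARG00000030756",  # dnmt1
    "ENSDARG00000015566",  # dnmt3ab
    "ENSDARG00000057830",  # dnmt3
    "ENSDARG00000005394",  # dnmt3aa
    "ENSDARG00000052402",  # dnmt3b
    "ENSDARG00000036791",  # dnmt4
    "ENSDARG00000057863",  # dnmt5
    "ENSDARG00000034518",  # trdmt1
)

#: Mouse homologues of the deregulated methionine-cycle genes.
MOUSE_METHIONINE_SYMBOLS = (
    "Trdmt1", "Bhmt", "Dmgdh", "Sardh", "Gnmt", "Ckb",
    "Ckmt1", "Mat1a", "Mat2a", "Ckm", "Gatm", "Gamt",
)

APO_SET_SIZE = 28
METHIONINE_SET_SIZE = 20

# stream tags keep the five generators' randomness independent of each other
_TAG_RNASEQ, _TAG_ARRAY, _TAG_ANNOT, _TAG_SEQ, _TAG_MOUSE = range(101, 106)


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: ~15,000 expressed genes (the study's
    per-time-point universes span 13,170-20,709), three embryo batches each
    contributing one YD and one SP sample, and 3 + 3 microarrays.
    """

    n_genes: int = 15000
    n_batches: int = 3
    mean_dispersion: float = 0.1
    n_spiked: int = 0
    spike_log2fc: float = 2.0
    batch_sd: float = 0.1
    array_noise_sd: float = 0.25
    intensity_variance_slope: float = 1.0
    cpg_depletion_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_batches <= 0:
            raise ParameterError("n_genes and n_batches must be positive")
        if self.n_spiked < 0 or self.n_spiked > self.n_genes:
            raise ParameterError("need 0 <= n_spiked <= n_genes")
        if self.mean_dispersion < 0 or self.batch_sd < 0:
            raise ParameterError("dispersion and batch_sd must be >= 0")
        if self.array_noise_sd <= 0:
            raise ParameterError("array_noise_sd must be positive")
        if not (0 < self.cpg_depletion_factor <= 1):
            raise ParameterError("cpg_depletion_factor must lie in (0, 1]")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), tag])

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:06d}" for i in range(self.n_genes)]


def _pick_spikes(rng: np.random.Generator, config: SimConfig):
    """Choose spiked gene indices and per-gene signs (+1 = up in YD)."""
    idx = rng.choice(config.n_genes, size=config.n_spiked, replace=False)
    idx.sort()
    signs = rng.choice([-1, 1], size=config.n_spiked)
    return idx, signs


def _truth_table(gene_ids: Sequence[str], idx, signs, log2fc: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in idx],
            "direction": ["up_in_YD" if s > 0 else "down_in_YD" for s in signs],
            "log2fc": [s * abs(log2fc) for s in signs],
        }
    )


def simulate_rnaseq_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts for one time point of the paired design.

    Gene base means are log-normal; batch effects multiply the mean
    (log-additive); spiked genes have their YD mean shifted by
    ``2 ** (+-spike_log2fc)`` with the same sign in every batch.

    Returns the count matrix and a truth table (gene_id, direction, log2fc)
    of the spiked genes.
    """
    rng = config.rng(_TAG_RNASEQ)
    n, b = config.n_genes, config.n_batches
    gene_ids = config.gene_ids()

    base_mean = np.exp(rng.normal(4.0, 1.5, size=n))  # median ~55 counts
    batch_factor = np.exp(rng.normal(0.0, config.batch_sd, size=b))
    spike_idx, spike_sign = _pick_spikes(rng, config)
    fc = np.ones(n)
    fc[spike_idx] = 2.0 ** (spike_sign * abs(config.spike_log2fc))

    phi = max(config.mean_dispersion, 1e-8)
    size = 1.0 / phi

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for j in range(b):
        for cond in ("YD", "SP"):
            mu = base_mean * batch_factor[j] * (fc if cond == "YD" else 1.0)
            p = size / (size + mu)
            name = f"{cond}_b{j + 1}"
            columns[name] = rng.negative_binomial(size, p)
            sample_rows.append({"sample_id": name, "condition": cond,
                                "batch": f"b{j + 1}"})

    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = _truth_table(gene_ids, spike_idx, spike_sign, config.spike_log2fc)
    return CountMatrix(counts, meta), truth


def simulate_microarray_intensities(
    config: SimConfig,
    multi_probe_fraction: float = 0.3,
    flag_reliability: float = 0.95,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Log-intensities for 3 YD + 3 SP arrays with intensity-dependent noise.

    Each transcript carries one probe, or 2-4 probes for a
    ``multi_probe_fraction`` of transcripts.  The per-transcript noise SD
    grows linearly with (descending) intensity rank:

        sd(t) = array_noise_sd * (1 + slope * rank_frac(t))

    where ``rank_frac`` is 0 for the brightest transcript and 1 for the
    dimmest, so dim transcripts are noisier and the intensity-sorted
    sliding-window Z is exercised non-trivially.  Flags are i.i.d.
    Bernoulli(``flag_reliability``) per probe x array.
    """
    if not (0 <= multi_probe_fraction <= 1) or not (0 <= flag_reliability <= 1):
        raise ParameterError("fractions must lie in [0, 1]")
    rng = config.rng(_TAG_ARRAY)
    n = config.n_genes
    transcript_ids = config.gene_ids()
    arrays = ["YD_a1", "YD_a2", "YD_a3", "SP_a1", "SP_a2", "SP_a3"]
    conds = np.array(["YD", "YD", "YD", "SP", "SP", "SP"])

    base = rng.normal(8.0, 2.0, size=n)
    # dimmest transcript gets the largest SD
    rank_frac = np.empty(n)
    rank_frac[np.argsort(-base, kind="stable")] = np.linspace(0.0, 1.0, n)
    sd = config.array_noise_sd * (1.0 + config.intensity_variance_slope * rank_frac)

    spike_idx, spike_sign = _pick_spikes(rng, config)
    shift = np.zeros(n)
    shift[spike_idx] = spike_sign * abs(config.spike_log2fc)

    n_probes = np.ones(n, dtype=int)
    multi = rng.random(n) < multi_probe_fraction
    n_probes[multi] = rng.integers(2, 5, size=int(multi.sum()))

    t_index = np.repeat(np.arange(n), n_probes)
    probe_offset = rng.normal(0.0, 0.1, size=t_index.size)  # probe affinity
    probe_ids = [
        f"PROBE_{transcript_ids[t]}_{k}"
        for t, reps in zip(range(n), n_probes)
        for k in range(reps)
    ]

    truth_mean = base[t_index] + probe_offset
    noise = rng.normal(0.0, 1.0, size=(t_index.size, 6)) * sd[t_index][:, None]
    values = truth_mean[:, None] + noise
    values[:, conds == "YD"] += shift[t_index][:, None]

    flags = rng.random((t_index.size, 6)) < flag_reliability

    pidx = pd.Index(probe_ids, name="probe_id")
    intens = pd.DataFrame(values, index=pidx, columns=arrays)
    flag_df = pd.DataFrame(flags, index=pidx, columns=arrays)
    probe_map = pd.Series(
        [transcript_ids[t] for t in t_index], index=pidx, name="transcript_id"
    )
    array_meta = pd.DataFrame({"condition": conds}, index=pd.Index(arrays, name="array_id"))
    truth = _truth_table(transcript_ids, spike_idx, spike_sign, config.spike_log2fc)
    return IntensityMatrix(intens, flag_df, probe_map, array_meta), truth


def simulate_gene_annotation(
    config: SimConfig,
    n_terms: int = 50,
    max_terms_per_gene: int = 5,
    enrichment_strength: float = 0.0,
    spiked_genes: Sequence[str] = (),
    apo_size: int = APO_SET_SIZE,
    methionine_size: int = METHIONINE_SET_SIZE,
) -> tuple[pd.DataFrame, dict[str, GeneSet]]:
    """Annotation table plus embedded named gene sets.

    Every gene receives a symbol and 0-``max_terms_per_gene`` molecular-
    function GO terms drawn uniformly from a pool of ``n_terms``; the pool is
    then topped up so each term annotates at least two genes.  Two named sets
    are embedded: an apolipoprotein-like set (default 28 genes) and a
    methionine-cycle-like set (default 20), disjoint from each other.  With
    ``enrichment_strength > 0`` the first term in the pool is additionally
    assigned to that fraction of ``spiked_genes``, creating a
    positive-control enrichment.
    """
    rng = config.rng(_TAG_ANNOT)
    gene_ids = config.gene_ids()
    n = config.n_genes
    if apo_size + methionine_size > n:
        raise ParameterError("gene sets larger than the universe")

    terms = [f"GO:MF{t:04d}" for t in range(n_terms)]
    counts = rng.integers(0, max_terms_per_gene + 1, size=n)
    assigned: list[set[str]] = [
        set(rng.choice(terms, size=c, replace=False)) for c in counts
    ]
    if enrichment_strength > 0 and len(spiked_genes):
        pos = set(np.asarray(spiked_genes)[
            rng.random(len(spiked_genes)) < enrichment_strength
        ])
        for i, g in enumerate(gene_ids):
            if g in pos:
                assigned[i].add(terms[0])
    # guarantee every term is represented at least twice
    tally: dict[str, int] = {t: 0 for t in terms}
    for s in assigned:
        for t in s:
            tally[t] += 1
    for t, c in tally.items():
        while c < 2:
            i = int(rng.integers(0, n))
            if t not in assigned[i]:
                assigned[i].add(t)
                c += 1

    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"sym{i:06d}" for i in range(n)],
            "go_terms": [";".join(sorted(s)) for s in assigned],
        }
    )
    picks = rng.choice(n, size=apo_size + methionine_size, replace=False)
    sets = {
        "apo": GeneSet("apo", frozenset(gene_ids[i] for i in picks[:apo_size])),
        "methionine": GeneSet(
            "methionine",
            frozenset(gene_ids[i] for i in picks[apo_size:]),
        ),
    }
    return annotation, sets


@dataclass
class GeneSequence:
    """One sequence region of one gene (promoter, unspliced gene, or CDS)."""

    gene_id: str
    region: str
    sequence: str

    def __post_init__(self) -> None:
        if self.region not in ("promoter", "gene", "cds"):
            raise ValueError(f"invalid region {self.region!r}")
        if not self.sequence:
            raise ValueError("empty sequence")


DEFAULT_REGION_LENGTHS: Mapping[str, int] = {
    "promoter": 2500, "gene": 5000, "cds": 1500,
}

_NUCS = np.frombuffer(b"ACGT", dtype="S1")


def simulate_sequences(
    config: SimConfig,
    region_lengths: Mapping[str, int] | None = None,
    depleted_genes: Sequence[str] = (),
    gene_ids: Sequence[str] | None = None,
) -> list[GeneSequence]:
    """I.i.d. nucleotide sequences with a controllable CpG rate.

    Background sequences are uniform i.i.d. over ACGT (CpG rate 1/16 per
    dinucleotide position).  Genes listed in ``depleted_genes`` are thinned:
    each CG occurrence independently survives with probability
    ``cpg_depletion_factor`` (the G of a removed site is rewritten to A or
    T), so their expected CpG count is exactly ``factor`` times background.
    """
    region_lengths = dict(region_lengths or DEFAULT_REGION_LENGTHS)
    for region, length in region_lengths.items():
        if length < 500:
            raise ParameterError(f"region {region!r} shorter than 500 nt")
    rng = config.rng(_TAG_SEQ)
    ids = list(gene_ids) if gene_ids is not None else config.gene_ids()
    depleted = set(depleted_genes)
    factor = config.cpg_depletion_factor

    out: list[GeneSequence] = []
    for gid in ids:
        for region, length in region_lengths.items():
            arr = _NUCS[rng.integers(0, 4, size=length)]
            if gid in depleted and factor < 1.0:
                seq_bytes = arr.tobytes()
                pos = _find_cg(seq_bytes)
                if pos.size:
                    kill = pos[rng.random(pos.size) >= factor]
                    arr[kill + 1] = np.where(
                        rng.random(kill.size) < 0.5, b"A", b"T"
                    ).astype("S1")
            out.append(GeneSequence(gid, region, arr.tobytes().decode("ascii")))
    return out


def _find_cg(seq_bytes: bytes) -> np.ndarray:
    a = np.frombuffer(seq_bytes, dtype="S1")
    return np.flatnonzero((a[:-1] == b"C") & (a[1:] == b"G"))


def simulate_mouse_de_table(
    config: SimConfig,
    n_target_de: int = 7,
    universe_size: int = 15000,
    de_fraction: float = 0.05,
) -> pd.DataFrame:
    """Symbol-level mouse liver DE table with embedded target homologues.

    Exactly ``n_target_de`` of the 12 methionine-cycle homologue symbols are
    flagged DE; background symbols are flagged i.i.d. at ``de_fraction``.
    """
    if not 0 <= n_target_de <= len(MOUSE_METHIONINE_SYMBOLS):
        raise ParameterError("n_target_de must lie in 0..12")
    if universe_size < len(MOUSE_METHIONINE_SYMBOLS):
        raise ParameterError("universe smaller than the target set")
    rng = config.rng(_TAG_MOUSE)
    n_bg = universe_size - len(MOUSE_METHIONINE_SYMBOLS)
    symbols = list(MOUSE_METHIONINE_SYMBOLS) + [f"Mgene{i:05d}" for i in range(n_bg)]
    de = np.zeros(universe_size, dtype=bool)
    de_targets = rng.choice(len(MOUSE_METHIONINE_SYMBOLS), size=n_target_de,
                            replace=False)
    de[de_targets] = True
    de[len(MOUSE_METHIONINE_SYMBOLS):] = (
        rng.random(n_bg) < de_fraction
    )
    return pd.DataFrame({"symbol": symbols, "is_de": de})
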