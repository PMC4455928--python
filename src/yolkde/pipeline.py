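"""End-to-end orchestration of the yolk-depletion expression analysis.

``run_pipeline`` chains the stages on synthetic data (or user-supplied TSV/
FASTA files in the formats of :mod:`yolkde.io`): per-time-point RNA-seq DE
calling, microarray DE calling, gene-set/GO enrichment, the methionine-cycle
and cross-species permutation tests, and the CpG-density comparison.  Every
run writes a manifest (seed, thresholds, versions) that suffices to
reproduce it, a plain-text summary, and one TSV per result table.  The qPCR
crossing-point helper used for validation assays lives here too.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as yio
from .cpg_analysis import count_cpg, ecdf_projection, ks_compare, windowed_cpg_profile
from .datatypes import CountMatrix, GeneSet, IntensityMatrix
from .enrichment import (
    cross_species_overlap,
    gene_set_enrichment,
    go_term_enrichment,
    permutation_overlap_test,
)
from .microarray_de import call_microarray_de
from .rnaseq_de import call_rnaseq_de, filter_max_count
from .synthetic_data import (
    SimConfig,
    simulate_gene_annotation,
    simulate_microarray_intensities,
    simulate_mouse_de_table,
    simulate_rnaseq_counts,
    simulate_sequences,
)

logger = logging.getLogger("yolkde")

REFERENCE_GENE = "actb2"


@dataclass
class PipelineConfig:
    """Thresholds, seed and simulation parameters of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    rnaseq_timepoints: int = 3
    rnaseq_fdr: float = 0.05
    microarray_fdr: float = 0.1
    max_count: int = 5
    window: int = 65
    go_fdr: float = 0.05
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rnaseq_fdr", "microarray_fdr", "go_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.permutations < 1 or self.rnaseq_timepoints < 1:
            raise ValueError("permutations and rnaseq_timepoints must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def qpcr_delta_cp(
    table: pd.DataFrame, reference_gene: str = REFERENCE_GENE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-normalized qPCR crossing points and per-gene t-tests.

    Per sample, each gene's normalized value is Cp(gene) minus the mean Cp
    of the reference gene (actb2) in that sample; per gene, an unpaired
    two-sided Student's t-test (pooled variance) compares treated against
    control samples.  Identical groups give t = 0, p = 1.
    """
    required = {"sample_id", "group", "gene", "cp"}
    if not required <= set(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    ref = table[table["gene"] == reference_gene]
    ref_mean = ref.groupby("sample_id")["cp"].mean()
    missing = set(table["sample_id"]) - set(ref_mean.index)
    if missing:
        raise ValueError(f"samples without a {reference_gene} reference: "
                         f"{sorted(missing)}")

    data = table[table["gene"] != reference_gene].copy()
    data["delta_cp"] = data["cp"] - data["sample_id"].map(ref_mean)

    rows = []
    for gene, grp in data.groupby("gene"):
        treated = grp.loc[grp["group"] == "treated", "delta_cp"].to_numpy()
        control = grp.loc[grp["group"] == "control", "delta_cp"].to_numpy()
        if len(treated) < 2 or len(control) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 samples per group")
        pooled_var = (
            ((treated - treated.mean()) ** 2).sum()
            + ((control - control.mean()) ** 2).sum()
        ) / (len(treated) + len(control) - 2)
        if pooled_var == 0.0:
            t, p = (0.0, 1.0) if treated.mean() == control.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(treated, control, equal_var=True)
        rows.append({
            "gene": gene,
            "mean_delta_treated": treated.mean(),
            "mean_delta_control": control.mean(),
            "t": float(t), "p": float(p),
        })
    result = pd.DataFrame(rows, columns=["gene", "mean_delta_treated",
                                         "mean_delta_control", "t", "p"])
    return result, data[["sample_id", "group", "gene", "delta_cp"]]


@dataclass
class PipelineResult:
    """All tables produced by one run, plus the manifest."""

    rnaseq_de: list[pd.DataFrame]
    microarray_de: pd.DataFrame
    go_enrichment: pd.DataFrame
    set_enrichment: pd.DataFrame
    methionine_permutation: dict
    mouse_overlap: dict
    cpg_tests: pd.DataFrame
    cpg_profiles: dict[str, pd.DataFrame]
    manifest: dict


def _stage(name):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run every stage on synthetic data and write all result TSVs.

    Output files: rnaseq_de_tp<i>.tsv, microarray_de.tsv, go_enrichment.tsv,
    set_enrichment.tsv, permutation_methionine.tsv, permutation_mouse.tsv,
    cpg_tests.tsv, cpg_profile_<region>.tsv, manifest.json, summary.txt.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # RNA-seq time points: independent simulations from derived seeds
    rnaseq_tables, universes, truth_up = [], [], set()
    de_union: set = set()
    up_union: set = set()
    down_union: set = set()
    for tp in range(config.rnaseq_timepoints):
        _stage(f"rnaseq tp{tp}")
        sim_tp = SimConfig(**{**asdict(config.sim),
                              "seed": int(config.sim.seed) + 1000 * (tp + 1)})
        cm, truth = simulate_rnaseq_counts(sim_tp)
        de = call_rnaseq_de(cm, config.rnaseq_fdr, config.max_count)
        rnaseq_tables.append(de)
        universes.append(set(filter_max_count(cm, config.max_count).gene_ids))
        passed = de[de["passed"]]
        de_union |= set(passed["gene_id"])
        up_union |= set(passed.loc[passed["direction"] == "up_in_YD", "gene_id"])
        down_union |= set(passed.loc[passed["direction"] == "down_in_YD", "gene_id"])
        yio.write_tsv(de, out / f"rnaseq_de_tp{tp}.tsv")

    _stage("microarray")
    m, _ = simulate_microarray_intensities(config.sim)
    array_de = call_microarray_de(m, config.microarray_fdr, config.window)
    yio.write_tsv(array_de, out / "microarray_de.tsv")
    passed_arr = array_de[array_de["passed"]]
    de_union |= set(passed_arr["gene_id"])
    up_union |= set(passed_arr.loc[passed_arr["direction"] == "up_in_YD", "gene_id"])
    down_union |= set(passed_arr.loc[passed_arr["direction"] == "down_in_YD",
                                     "gene_id"])

    _stage("enrichment")
    annotation, sets = simulate_gene_annotation(config.sim)
    universe_union = set().union(*universes) | set(array_de["gene_id"])
    de_first = set(rnaseq_tables[0].loc[rnaseq_tables[0]["passed"], "gene_id"])

    go = go_term_enrichment(de_first & universes[0], annotation, universes[0],
                            config.go_fdr)
    yio.write_tsv(go, out / "go_enrichment.tsv")

    set_rows = []
    for tp, (de_tbl, universe) in enumerate(zip(rnaseq_tables, universes)):
        de_genes = set(de_tbl.loc[de_tbl["passed"], "gene_id"])
        row = gene_set_enrichment(de_genes, sets["apo"], universe)
        row["timepoint"] = tp
        set_rows.append(row)
    set_enrichment = pd.DataFrame(set_rows)
    yio.write_tsv(set_enrichment, out / "set_enrichment.tsv")

    rng = np.random.default_rng([int(config.seed), 7])
    meth = permutation_overlap_test(
        de_union & universe_union, sets["methionine"], universe_union,
        B=config.permutations, seed=rng,
    )
    meth_row = {"observed": meth.observed_overlap, "p": meth.p,
                "p_text": meth.format_p(), "B": meth.B,
                "max_null": int(meth.null_overlaps.max())}
    yio.write_tsv(pd.DataFrame([meth_row]), out / "permutation_methionine.tsv")

    mouse_table = simulate_mouse_de_table(config.sim)
    mouse = cross_species_overlap(mouse_table, B=config.permutations, seed=rng)
    mouse_row = {"observed": mouse.observed_overlap, "p": mouse.p,
                 "p_text": mouse.format_p(), "B": mouse.B,
                 "max_null": int(mouse.null_overlaps.max())}
    yio.write_tsv(pd.DataFrame([mouse_row]), out / "permutation_mouse.tsv")

    _stage("cpg")
    sequences = simulate_sequences(config.sim, depleted_genes=sorted(up_union))
    by_region: dict[str, dict[str, str]] = {}
    for rec in sequences:
        by_region.setdefault(rec.region, {})[rec.gene_id] = rec.sequence
    cpg_rows, profiles = [], {}
    for region, seqs in by_region.items():
        counts = {g: count_cpg(s) for g, s in seqs.items()}
        all_counts = np.array(list(counts.values()))
        for label, group in (("up_in_YD", up_union), ("down_in_YD", down_union)):
            gc = np.array([counts[g] for g in group if g in counts])
            if gc.size >= 2:
                d, p = ks_compare(all_counts, gc)
                cpg_rows.append({"group": label, "region": region,
                                 "n_group": gc.size, "D": d, "p": p,
                                 "mean_ecdf": float(
                                     ecdf_projection(all_counts, gc).mean())})
        if region in ("gene", "cds"):
            from .synthetic_data import GeneSequence

            recs = [GeneSequence(g, region, s) for g, s in seqs.items()]
            profiles[region] = windowed_cpg_profile(
                recs, de_up=up_union, de_down=down_union)
            yio.write_tsv(profiles[region], out / f"cpg_profile_{region}.tsv")
    cpg_tests = pd.DataFrame(cpg_rows, columns=["group", "region", "n_group",
                                                "D", "p", "mean_ecdf"])
    yio.write_tsv(cpg_tests, out / "cpg_tests.tsv")

    manifest = {
        "seed": int(config.seed),
        "config": {**asdict(config), "sim": asdict(config.sim)},
        "n_de_union": len(de_union),
        "runtime_s": round(time.perf_counter() - t0, 3),
        "package": "yolkde",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    summary = [
        f"yolkde run (seed {config.seed})",
        *(
            f"RNA-seq tp{tp}: {int(t['passed'].sum())} DE genes of {len(t)} tested"
            for tp, t in enumerate(rnaseq_tables)
        ),
        f"microarray: {int(array_de['passed'].sum())} DE transcripts of "
        f"{len(array_de)}",
        f"GO terms significant: {int(go['significant'].sum()) if len(go) else 0}",
        f"methionine overlap {meth.observed_overlap}, p {meth.format_p()}",
        f"mouse homologue overlap {mouse.observed_overlap}, p {mouse.format_p()}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    return PipelineResult(rnaseq_tables, array_de, go, set_enrichment,
                          meth_row, mouse_row, cpg_tests, profiles, manifest)
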