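"""Tab-separated and FASTA readers/writers for every pipeline artifact.

One TSV dialect throughout: tab-separated, header row, UTF-8, '.' decimal.
FASTA headers follow ``gene_id|region`` with region in {promoter, gene, cds}.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import CountMatrix, GeneSet, IntensityMatrix
from .synthetic_data import GeneSequence

_TSV = dict(sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **_TSV)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- count matrices ---------------------------------------------------------

def write_count_matrix(cm: CountMatrix, counts_path, meta_path) -> None:
    write_tsv(cm.counts.reset_index(), counts_path)
    write_tsv(cm.sample_meta.reset_index(), meta_path)


def read_count_matrix(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t").set_index("gene_id")
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    return CountMatrix(counts, meta)


# -- microarray matrices ----------------------------------------------------

def write_intensity_matrix(m: IntensityMatrix, intensity_path, flags_path,
                           probe_map_path, array_meta_path) -> None:
    write_tsv(m.log_intensities.reset_index(), intensity_path)
    write_tsv(m.flags.reset_index(), flags_path)
    write_tsv(m.probe_map.rename("transcript_id").reset_index(), probe_map_path)
    write_tsv(m.array_meta.reset_index(), array_meta_path)


def read_intensity_matrix(intensity_path, flags_path, probe_map_path,
                          array_meta_path, strict_design: bool = True) -> IntensityMatrix:
    intens = pd.read_csv(intensity_path, sep="\t").set_index("probe_id")
    flags = pd.read_csv(flags_path, sep="\t").set_index("probe_id").astype(bool)
    probe_map = pd.read_csv(probe_map_path, sep="\t").set_index("probe_id")[
        "transcript_id"
    ]
    meta = pd.read_csv(array_meta_path, sep="\t").set_index("array_id")
    return IntensityMatrix(intens, flags, probe_map, meta,
                           strict_design=strict_design)


# -- gene sets and annotation ----------------------------------------------

def write_gene_sets(sets: dict[str, GeneSet], path) -> None:
    rows = [
        {"set_name": gs.name, "gene_id": gid}
        for gs in sets.values()
        for gid in sorted(gs.members)
    ]
    write_tsv(pd.DataFrame(rows, columns=["set_name", "gene_id"]), path)


def read_gene_sets(path) -> dict[str, GeneSet]:
    df = pd.read_csv(path, sep="\t")
    return {
        name: GeneSet(name, frozenset(grp["gene_id"]))
        for name, grp in df.groupby("set_name")
    }


# -- sequences --------------------------------------------------------------

def write_fasta(sequences: Iterable[GeneSequence], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(rec.sequence), id=f"{rec.gene_id}|{rec.region}",
                  description="")
        for rec in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[GeneSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, _, region = rec.id.partition("|")
        if not region:
            raise ValueError(f"FASTA header {rec.id!r} lacks 'gene_id|region'")
        out.append(GeneSequence(gene_id, region, str(rec.seq)))
    return out
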