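"""Readers and writers for the plain-text interchange formats.

Everything is tab- or comma-separated text: probe tables and expression
matrices as TSV, sample sheets and qPCR tables as CSV, gene sets as GMT,
promoters as FASTA (via Biopython), motif and TF-map tables as two-column
TSV, and planted truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionMatrix, ProbeIntensityTable


# -- probe tables and sample sheets --------------------------------------

# %.17g round-trips float64 exactly, so a re-read stage reproduces its
# downstream files byte-identically
FLOAT_FORMAT = "%.17g"


def write_probe_table(table: ProbeIntensityTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_probe_table(path, sample_sheet_path) -> ProbeIntensityTable:
    data = pd.read_csv(path, sep="\t", float_precision="round_trip")
    samples = read_sample_sheet(sample_sheet_path)
    return ProbeIntensityTable(data=data, samples=samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.reset_index().to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    samples = pd.read_csv(path)
    return samples.set_index("sample_id")


# -- expression matrices --------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, path, sample_sheet_path=None) -> None:
    matrix.values.rename_axis("gene_id").to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT
    )
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


def read_expression_matrix(path, sample_sheet_path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id",
                         float_precision="round_trip")
    samples = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(values, samples)


# -- GMT gene sets ---------------------------------------------------------

def write_gmt(terms: dict[str, dict], path) -> None:
    """``terms``: term id -> {"description": str, "genes": iterable}."""
    with open(path, "w") as fh:
        for term_id, entry in terms.items():
            genes = "\t".join(entry["genes"])
            fh.write(f"{term_id}\t{entry['description']}\t{genes}\n")


def read_gmt(path) -> dict[str, dict]:
    terms: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            terms[parts[0]] = {"description": parts[1], "genes": list(parts[2:])}
    return terms


# -- FASTA promoters -------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- motif and TF-map tables ----------------------------------------------

def write_motif_table(motifs: dict[str, str], path) -> None:
    pd.DataFrame(
        {"motif_id": list(motifs), "consensus": list(motifs.values())}
    ).to_csv(path, sep="\t", index=False)


def read_motif_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["motif_id"], df["consensus"]))


def write_tf_map(tf_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"tf_gene_id": list(tf_map), "motif_id": list(tf_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_tf_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["tf_gene_id"], df["motif_id"]))


# -- JSON helpers ----------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
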