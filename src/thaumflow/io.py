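"""Readers and writers for the survey's standard file formats.

FASTA goes through Biopython, newick through scikit-bio; distance
matrices are exchanged as PHYLIP square or lower-triangle files or as
(id1, id2, dist) column files, OTU tables and report tables as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from .errors import ValidationError
from .otu import OTUAssignment
from .primers import DegeneratePrimer, TemplateRecord

__all__ = [
    "read_templates",
    "write_templates",
    "read_primers",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "write_list_file",
]


def read_templates(
    fasta_path, clades_path=None, clade_key: str = "clade="
) -> list[TemplateRecord]:
    """Read templates from FASTA, with clades from a sidecar TSV or the
    description (``clade=...`` key)."""
    clades: dict[str, str] = {}
    if clades_path is not None:
        tsv = pd.read_csv(clades_path, sep="\t", header=None, names=["id", "clade"])
        clades = dict(zip(tsv["id"].astype(str), tsv["clade"].astype(str)))
    records = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate template id {rec.id!r}")
        seen.add(rec.id)
        clade = clades.get(rec.id, "")
        if not clade and clade_key in rec.description:
            clade = rec.description.split(clade_key, 1)[1].split()[0]
        records.append(TemplateRecord(rec.id, str(rec.seq), clade))
    return records


def write_templates(records: Iterable[TemplateRecord], fasta_path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"clade={r.clade}" if r.clade else "")
        for r in records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")


def read_primers(config_path) -> list[DegeneratePrimer]:
    """Primer definitions from a YAML/TSV-ish config.

    YAML form: a list of {name, sequence, orientation} mappings.
    """
    import yaml

    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise ValidationError("primer config must be a list of mappings")
    return [DegeneratePrimer(d["name"], d["sequence"], d["orientation"]) for d in doc]


def read_distance_matrix(path) -> DistanceMatrix:
    """PHYLIP square/lower-triangle or 3-column (id1, id2, dist) format."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():
        n = int(first[0])
        body = [ln.split() for ln in lines[1 : n + 1]]
        ids = [row[0] for row in body]
        d = np.zeros((n, n))
        if all(len(row) == n + 1 for row in body):  # square
            for i, row in enumerate(body):
                d[i] = [float(x) for x in row[1:]]
        else:  # lower triangle
            for i, row in enumerate(body):
                vals = [float(x) for x in row[1:]]
                if len(vals) != i:
                    raise ValidationError(f"malformed PHYLIP line for {ids[i]!r}")
                d[i, :i] = vals
                d[:i, i] = vals
        return DistanceMatrix(d, ids)
    # column format
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["id1", "id2", "dist"])
    ids = sorted(set(df["id1"].astype(str)) | set(df["id2"].astype(str)))
    idx = {s: i for i, s in enumerate(ids)}
    d = np.zeros((len(ids), len(ids)))
    for _, row in df.iterrows():
        i, j = idx[str(row["id1"])], idx[str(row["id2"])]
        d[i, j] = d[j, i] = float(row["dist"])
    return DistanceMatrix(d, ids)


def write_distance_matrix(dm: DistanceMatrix, path, fmt: str = "square") -> None:
    """Write PHYLIP square format (default) or a square TSV with header."""
    n = len(dm.ids)
    with open(path, "w") as fh:
        if fmt == "square":
            fh.write(f"{n}\n")
            for i, name in enumerate(dm.ids):
                vals = "\t".join(f"{x:.6g}" for x in dm.data[i])
                fh.write(f"{name}\t{vals}\n")
        elif fmt == "tsv":
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                fh, sep="\t"
            )
        else:
            raise ValidationError(f"unknown format {fmt!r}")


def read_otu_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table < 0).any().any():
        raise ValidationError("OTU table contains negative counts")
    return table.astype(int)


def write_otu_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path))


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def write_list_file(assignment: OTUAssignment, path) -> None:
    """mothur-style list file: cutoff, #OTUs, comma-joined members per OTU."""
    members = assignment.members()
    with open(path, "w") as fh:
        cols = "\t".join(",".join(members[o]) for o in sorted(members))
        fh.write(f"{assignment.cutoff:g}\t{len(members)}\t{cols}\n")
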