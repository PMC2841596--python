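"""Readers and writers for the formats the tool touches.

Input: FASTA protein sequences (optionally run through an external
BLAST all-vs-all adapter), BLAST tabular output (outfmt 6) or a bare
3-column (query, subject, evalue) list, two-column gold-standard and
annotation TSVs.  Output: flat cluster text, XGMML for Cytoscape,
grayscale heatmap PNGs, and triplet TSVs for generated data.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import NamedTuple

import numpy as np

from specfam.graph import Partition, SimilarityGraph
from specfam.similarity import EValueRecord

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "read_blast_tab",
    "run_blast_all_vs_all",
    "write_triplet",
    "write_clusters_txt",
    "read_clusters_txt",
    "read_gold_tsv",
    "write_gold_tsv",
    "read_annotations_tsv",
    "write_xgmml",
    "write_heatmap_png",
]


class SequenceRecord(NamedTuple):
    id: str
    description: str
    residues: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file; the id is the first whitespace token of the header.

    Wrapped sequence lines are joined.  Duplicate ids and empty records
    are rejected, matching the id discipline BLAST itself applies.
    """
    from Bio import SeqIO

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dups: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if not rec.id:
            raise ValueError(f"{path}: malformed FASTA header (empty id)")
        if not residues:
            raise ValueError(f"{path}: empty sequence for id {rec.id!r}")
        if rec.id in seen:
            dups.add(rec.id)
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, desc, residues))
    if dups:
        raise ValueError(f"{path}: duplicate sequence ids: {sorted(dups)}")
    return records


def read_blast_tab(path: str | Path, dialect: str = "outfmt6") -> list[EValueRecord]:
    """Read pairwise E-values from BLAST tabular or bare-triplet files.

    ``outfmt6`` expects the standard 12-column tab-separated layout and
    uses columns 1, 2 and 11 (query, subject, evalue); ``triplet``
    expects 3 whitespace-separated columns.  Lines starting with '#'
    are skipped.
    """
    if dialect not in ("outfmt6", "triplet"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[EValueRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "outfmt6":
                fields = line.split("\t")
                if len(fields) < 12:
                    raise ValueError(
                        f"{path}:{lineno}: expected 12 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                query, subject, ev_str = fields[0], fields[1], fields[10]
            else:
                fields = line.split()
                if len(fields) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                    )
                query, subject, ev_str = fields
            try:
                evalue = float(ev_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric E-value {ev_str!r}"
                ) from None
            records.append(EValueRecord(query, subject, evalue).validate())
    return records


def run_blast_all_vs_all(
    fasta_path: str | Path,
    evalue_cutoff: float = 10.0,
    blastp: str = "blastp",
    makeblastdb: str = "makeblastdb",
) -> list[EValueRecord]:
    """All-against-all protein BLAST via external blast+ executables.

    Builds a database from the input and queries it with itself,
    returning the parsed tabular hits.  A missing executable raises a
    clear error rather than silently degrading.
    """
    for exe in (blastp, makeblastdb):
        if shutil.which(exe) is None:
            raise FileNotFoundError(
                f"required BLAST executable {exe!r} not found on PATH; "
                "install NCBI blast+ or supply E-values directly"
            )
    fasta_path = Path(fasta_path)
    with tempfile.TemporaryDirectory() as tmp:
        db = Path(tmp) / "selfdb"
        out = Path(tmp) / "hits.tsv"
        subprocess.run(
            [makeblastdb, "-in", str(fasta_path), "-dbtype", "prot",
             "-out", str(db)],
            check=True, capture_output=True,
        )
        subprocess.run(
            [blastp, "-query", str(fasta_path), "-db", str(db),
             "-outfmt", "6", "-evalue", str(evalue_cutoff), "-out", str(out)],
            check=True, capture_output=True,
        )
        return read_blast_tab(out, dialect="outfmt6")


def write_triplet(records: list[EValueRecord], path: str | Path) -> None:
    """Write (query, subject, evalue) rows; E-values in %.6e for stable diffs."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.query_id}\t{rec.subject_id}\t{rec.evalue:.6e}\n")


def write_clusters_txt(partition: Partition, path: str | Path) -> None:
    """One cluster per line, ids tab-separated, largest cluster first."""
    with open(path, "w") as fh:
        for members in partition.clusters():
            fh.write("\t".join(sorted(members)) + "\n")


def read_clusters_txt(path: str | Path) -> Partition:
    clusters = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                clusters.append(line.split("\t"))
    return Partition.from_clusters(clusters)


def read_gold_tsv(path: str | Path) -> Partition:
    """Two-column TSV (id, family label) -> Partition."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            assignment[fields[0]] = fields[1]
    labels = {lab: k for k, lab in enumerate(dict.fromkeys(assignment.values()))}
    return Partition({name: labels[lab] for name, lab in assignment.items()})


def write_gold_tsv(partition: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, label in partition.assignment.items():
            fh.write(f"{name}\t{label}\n")


def read_annotations_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (id, term), multiple rows per id -> id -> term set."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            annotations.setdefault(fields[0], set()).add(fields[1])
    return annotations


def write_xgmml(
    graph: SimilarityGraph, partition: Partition, path: str | Path,
    label: str = "specfam",
) -> None:
    """Minimal XGMML export for Cytoscape: nodes carry a cluster
    attribute, edges a weight attribute; no layout coordinates."""
    root = ET.Element(
        "graph",
        attrib={
            "label": label,
            "directed": "0",
            "xmlns": "http://www.cs.rpi.edu/XGMML",
        },
    )
    for name in graph.ids:
        node = ET.SubElement(root, "node", attrib={"id": name, "label": name})
        ET.SubElement(
            node, "att",
            attrib={"name": "cluster", "type": "integer",
                    "value": str(partition.assignment[name])},
        )
    for a, b, w in graph.edge_list():
        edge = ET.SubElement(root, "edge", attrib={"source": a, "target": b})
        ET.SubElement(
            edge, "att",
            attrib={"name": "weight", "type": "real", "value": f"{w:.6e}"},
        )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")


def write_heatmap_png(
    rearranged: np.ndarray, path: str | Path, scale: int = 1
) -> None:
    """Grayscale heatmap PNG of a rearranged similarity matrix.

    Intensity is proportional to similarity with darker = more similar;
    ``scale`` enlarges each cell to a scale x scale pixel block.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import image as mpimg

    mat = np.asarray(rearranged, dtype=float)
    if scale > 1:
        mat = np.kron(mat, np.ones((scale, scale)))
    mpimg.imsave(path, mat, cmap="gray_r", vmin=0.0, vmax=1.0)
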