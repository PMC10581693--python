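"""File round-trips for the pipeline's plain-text formats.

Newick trees, aligned FASTA (orthogroup and consensus alignments),
intron and orthogroup TSVs, and AlphaFold-style confidence JSON.  Every
table writer can prepend ``#``-comment provenance headers (tool version,
seed, input hashes) which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domains import ConfidenceData
from .introns import OrthogroupAlignment
from .phylo import PhyloTree, parse_newick

__all__ = [
    "read_tree",
    "write_tree",
    "read_orthogroup_fasta",
    "write_orthogroup_fasta",
    "read_consensus_fasta",
    "write_consensus_fasta",
    "write_confidence_json",
    "file_sha256",
    "write_table",
]


def read_tree(path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_orthogroup_fasta(alignment: OrthogroupAlignment, path) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=prot,
            description=f"species={alignment.species_of[prot]}",
        )
        for prot, seq in sorted(alignment.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_orthogroup_fasta(path, orthogroup: str | None = None) -> OrthogroupAlignment:
    """Read an aligned orthogroup FASTA; species comes from the
    ``species=`` tag in the description, defaulting to the record id."""
    path = Path(path)
    orthogroup = orthogroup or path.stem
    sequences, species_of = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
        species_of[rec.id] = rec.id
        for token in rec.description.split():
            if token.startswith("species="):
                species_of[rec.id] = token.split("=", 1)[1]
    if not sequences:
        raise ValueError(f"{path}: empty alignment")
    return OrthogroupAlignment(orthogroup, sequences, species_of)


def write_consensus_fasta(rows: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in rows.items()]
    SeqIO.write(records, str(path), "fasta")


def read_consensus_fasta(path) -> dict[str, str]:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return rows


def write_confidence_json(conf: ConfidenceData, path) -> None:
    payload = {
        "predicted_aligned_error": np.round(conf.pae, 3).tolist(),
        "plddt": np.round(conf.plddt, 2).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def write_table(df, path, provenance: dict | None = None) -> None:
    """Write a TSV with optional ``# key=value`` provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
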