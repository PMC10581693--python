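"""Genotype construction: orthogroup presence/absence and residue scores.

Two genotype flavours feed the association tests.  Orthogroup genotypes
are binary presence/absence per species, filtered to orthogroups present
in enough species and showing at least two independent Dollo loss events
(so that an association cannot be driven by a single clade).  Residue
genotypes score each ortholog residue against a consensus with BLOSUM62
and standardise per column, giving a continuous per-position measure of
divergence from the consensus.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .phylo import PhyloTree, dollo_losses

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceAbsenceTable",
    "ResidueGenotypeTable",
    "parse_orthogroups",
    "filter_orthogroups",
    "residue_genotypes",
]

CONSENSUS_ROW_ID = "CONSENSUS"
_MISSING_RESIDUES = set("-.XBZxbz*")


@dataclass
class PresenceAbsenceTable:
    """Binary orthogroup-by-species matrix with gene counts.

    ``presence`` is orthogroups x species in {0, 1}; ``counts`` holds the
    number of genes per cell (for the large-orthogroup heuristic).
    ``metadata`` gains ``n_present`` and, after filtering, ``dollo_losses``.
    """

    presence: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if not self.presence.isin([0, 1]).all().all():
            raise ValueError("presence entries must be binary")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.presence.index)
        if "n_present" not in self.metadata:
            self.metadata["n_present"] = self.presence.sum(axis=1)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.presence.index)

    def genotype_frame(self) -> pd.DataFrame:
        """Species x orthogroup design frame for the association scan."""
        return self.presence.T.astype(float)


def parse_orthogroups(path) -> PresenceAbsenceTable:
    """Read an Orthofinder-style Orthogroups.tsv into presence/absence.

    First column is the orthogroup id, remaining columns one per species
    with comma-separated gene ids (possibly empty).  Ragged rows raise
    with their line number.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or len(header) < 2:
            raise ValueError("orthogroups TSV needs a header with >= 1 species")
        species = header[1:]
        og_ids, pres_rows, count_rows = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            og_ids.append(row[0])
            genes = [[g for g in cell.split(",") if g.strip()] for cell in row[1:]]
            count_rows.append([len(g) for g in genes])
            pres_rows.append([1 if g else 0 for g in genes])
    presence = pd.DataFrame(pres_rows, index=og_ids, columns=species, dtype=np.int8)
    counts = pd.DataFrame(count_rows, index=og_ids, columns=species, dtype=int)
    return PresenceAbsenceTable(presence, counts)


def write_orthogroups(table: PresenceAbsenceTable, path) -> None:
    """Serialise back to the Orthofinder dialect (synthetic gene ids)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["Orthogroup"] + table.species)
        for og in table.orthogroups:
            row = [og]
            for sp in table.species:
                k = int(table.counts.loc[og, sp])
                row.append(", ".join(f"{og}_{sp}_g{i}" for i in range(k)))
            writer.writerow(row)


def filter_orthogroups(
    table: PresenceAbsenceTable,
    tree: PhyloTree,
    min_present: int = 5,
    min_losses: int = 2,
) -> PresenceAbsenceTable:
    """Keep orthogroups with >= min_present species and >= min_losses
    independent Dollo loss events on the species tree.

    Orthogroups present in every species have zero losses and are dropped:
    with no variation there is nothing to associate.
    """
    missing = set(table.species) - set(tree.leaf_map)
    if missing:
        raise KeyError(f"species not in tree: {', '.join(sorted(missing))}")
    keep, losses = [], []
    for og in table.orthogroups:
        pres = table.presence.loc[og]
        n_present = int(pres.sum())
        if n_present == 0:
            logger.info("%s: absent everywhere, skipped", og)
            continue
        n_losses, _ = dollo_losses(tree, pres.to_dict())
        if n_present >= min_present and n_losses >= min_losses:
            keep.append(og)
            losses.append(n_losses)
    out = PresenceAbsenceTable(
        table.presence.loc[keep].copy(), table.counts.loc[keep].copy()
    )
    out.metadata["dollo_losses"] = losses
    logger.info(
        "orthogroup filter: %d of %d kept", len(keep), len(table.orthogroups)
    )
    return out


@dataclass
class ResidueGenotypeTable:
    """Standardised per-column residue scores against a consensus.

    ``raw`` and ``z`` are species x column frames; NaN marks gaps or
    ambiguous residues.  Retained columns have mean 0 and unit SD over
    their non-missing species; invariant columns are dropped.
    """

    raw: pd.DataFrame
    z: pd.DataFrame
    consensus: str

    def genotype_frame(self) -> pd.DataFrame:
        return self.z


def residue_genotypes(
    alignment: dict[str, str],
    substitution_matrix=None,
    consensus_id: str = CONSENSUS_ROW_ID,
) -> ResidueGenotypeTable:
    """Score each species' residues against the consensus row.

    ``alignment`` maps row id to aligned sequence and must contain a
    consensus row; insertions relative to the consensus model are assumed
    already removed, so all rows share the model coordinate system.  Gaps
    and ambiguous residues (X/B/Z) are missing data: the species simply
    drops out of that column.
    """
    if consensus_id not in alignment:
        raise KeyError(f"alignment has no {consensus_id!r} row")
    if substitution_matrix is None:
        substitution_matrix = substitution_matrices.load("BLOSUM62")
    consensus = alignment[consensus_id].upper()
    n_col = len(consensus)
    species = [k for k in alignment if k != consensus_id]
    raw = np.full((len(species), n_col), np.nan)
    for i, sp in enumerate(species):
        row = alignment[sp].upper()
        if len(row) != n_col:
            raise ValueError(
                f"{sp}: row length {len(row)} != consensus length {n_col}"
            )
        for j, (aa, ref) in enumerate(zip(row, consensus)):
            if aa in _MISSING_RESIDUES or ref in _MISSING_RESIDUES:
                continue
            raw[i, j] = substitution_matrix[ref, aa]
    raw_df = pd.DataFrame(raw, index=species, columns=range(n_col))
    mean = raw_df.mean(axis=0)
    sd = raw_df.std(axis=0, ddof=0)
    informative = sd > 0
    dropped = [int(c) for c in raw_df.columns[~informative]]
    if dropped:
        logger.info("dropping %d invariant/empty columns: %s", len(dropped), dropped)
    z = (raw_df.loc[:, informative] - mean[informative]) / sd[informative]
    return ResidueGenotypeTable(raw=raw_df, z=z, consensus=consensus)
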