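"""Intron-to-alignment mapping and the conserved-intron filter.

De novo intron annotations contain many false positives that corrupt
splice-signal estimates.  Genuine introns tend to sit at the same protein
alignment column, in the same phase, in multiple species, whereas
spurious ones land at shared (column, phase) coordinates only by chance.
The filter keeps exactly the introns whose (column, phase) is shared by
at least ``min_species`` distinct species within an orthogroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IntronRecord",
    "OrthogroupAlignment",
    "map_intron_to_column",
    "filter_conserved_introns",
    "extract_intron_table",
    "read_intron_table",
    "write_intron_table",
]

DONOR_LEN = 11  # -3..-1 exon + +1..+8 intron
ACCEPTOR_LEN = 7  # -6..-1 intron + +1 exon


@dataclass(frozen=True)
class IntronRecord:
    """One annotated intron in one species' protein.

    ``residue_index`` is the 0-based index of the residue whose codon the
    intron follows (phase 0) or interrupts (phase 1/2); ``phase`` counts
    the bases of that codon lying 5' of the intron.  Windows are stored as
    DNA (U mapped to T on input).
    """

    species: str
    protein: str
    orthogroup: str
    residue_index: int
    phase: int
    donor_window: str
    acceptor_window: str = ""

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")
        dw = self.donor_window.upper().replace("U", "T")
        aw = self.acceptor_window.upper().replace("U", "T")
        if len(dw) != DONOR_LEN:
            raise ValueError(f"donor window must be {DONOR_LEN} nt, got {len(dw)}")
        if aw and len(aw) != ACCEPTOR_LEN:
            raise ValueError(f"acceptor window must be {ACCEPTOR_LEN} nt, got {len(aw)}")
        object.__setattr__(self, "donor_window", dw)
        object.__setattr__(self, "acceptor_window", aw)


@dataclass
class OrthogroupAlignment:
    """Aligned protein rows of one orthogroup, keyed by protein id."""

    orthogroup: str
    sequences: dict[str, str]
    species_of: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.orthogroup}: rows have unequal lengths {lengths}")
        missing = set(self.sequences) - set(self.species_of)
        if missing:
            raise ValueError(f"{self.orthogroup}: no species for rows {missing}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def mean_orthologs_per_species(self) -> float:
        return len(self.sequences) / max(1, len(set(self.species_of.values())))


def map_intron_to_column(
    alignment: OrthogroupAlignment, record: IntronRecord
) -> tuple[int, int]:
    """Alignment column of the intron's residue in its species' row.

    Counts non-gap characters along the row until ``residue_index`` is
    reached; the phase passes through unchanged.
    """
    row = alignment.sequences.get(record.protein)
    if row is None:
        raise KeyError(f"{record.protein} not in alignment {alignment.orthogroup}")
    seen = -1
    for col, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == record.residue_index:
                return col, record.phase
    raise IndexError(
        f"{record.protein}: residue_index {record.residue_index} beyond "
        f"ungapped length {seen + 1}"
    )


def filter_conserved_introns(
    alignments: dict[str, OrthogroupAlignment],
    records,
    min_species: int = 2,
    skip_large_orthogroups: bool = True,
    max_mean_orthologs: float = 2.0,
) -> list[IntronRecord]:
    """Keep introns whose (column, phase) is shared by >= min_species species.

    Conservation is assessed within an orthogroup only; species count is
    of distinct species, so within-species paralog duplicates do not make
    an intron "conserved".  Unmappable records are logged and skipped.
    Very large orthogroups (mean orthologs per species above
    ``max_mean_orthologs``) are skipped entirely when the flag is on.
    """
    groups: dict[tuple[str, int, int], list[IntronRecord]] = {}
    n_skipped = 0
    skipped_ogs = {
        og
        for og, aln in alignments.items()
        if skip_large_orthogroups
        and aln.mean_orthologs_per_species() > max_mean_orthologs
    }
    for rec in records:
        aln = alignments.get(rec.orthogroup)
        if aln is None or rec.orthogroup in skipped_ogs:
            n_skipped += 1
            continue
        try:
            col, phase = map_intron_to_column(aln, rec)
        except (KeyError, IndexError) as exc:
            logger.warning("skipping unmappable intron: %s", exc)
            n_skipped += 1
            continue
        groups.setdefault((rec.orthogroup, col, phase), []).append(rec)
    kept: list[IntronRecord] = []
    for members in groups.values():
        n_sp = len({m.species for m in members})
        if n_sp >= min_species:
            kept.extend(members)
    logger.info(
        "conserved-intron filter: %d kept, %d dropped, %d unmapped/skipped",
        len(kept),
        sum(len(v) for v in groups.values()) - len(kept),
        n_skipped,
    )
    # stable output order, independent of record input order (full-record
    # key: one species can host two phases at the same residue)
    kept.sort(
        key=lambda r: (
            r.orthogroup,
            r.species,
            r.protein,
            r.residue_index,
            r.phase,
            r.donor_window,
            r.acceptor_window,
        )
    )
    return kept


# ---------------------------------------------------------------------------
# Intron extraction from genome + GFF3


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _slice_padded(seq: str, start: int, end: int) -> str:
    """0-based half-open slice, padded with N beyond the contig ends."""
    left = "N" * max(0, -start)
    right = "N" * max(0, end - len(seq))
    return left + seq[max(0, start) : min(len(seq), end)] + right


def extract_intron_table(
    genome: dict[str, str],
    cds_table: pd.DataFrame,
    species: str,
    orthogroup_of: dict[str, str] | None = None,
) -> list[IntronRecord]:
    """Infer introns between consecutive CDS segments of each mRNA.

    ``genome`` maps contig name to sequence; ``cds_table`` has columns
    ``seqid, start, end, strand, protein`` with GFF3 1-based inclusive
    coordinates.  The residue index and phase derive from the cumulative
    coding length 5' of each intron; donor/acceptor windows are cut from
    the genome and reverse-complemented on the minus strand.
    """
    required = {"seqid", "start", "end", "strand", "protein"}
    if not required.issubset(cds_table.columns):
        raise ValueError(f"cds_table needs columns {sorted(required)}")
    records: list[IntronRecord] = []
    for protein, segs in cds_table.groupby("protein", sort=True):
        strand = segs["strand"].iloc[0]
        if set(segs["strand"]) != {strand} or strand not in "+-":
            raise ValueError(f"{protein}: inconsistent or unknown strand")
        seqid = segs["seqid"].iloc[0]
        contig = genome.get(seqid)
        if contig is None:
            raise KeyError(f"{protein}: contig {seqid} not in genome")
        segs = segs.sort_values("start", ascending=(strand == "+"))
        coding = 0
        rows = list(segs.itertuples())
        for a, b in zip(rows, rows[1:]):
            coding += a.end - a.start + 1
            if strand == "+":
                intron_start, intron_end = a.end + 1, b.start - 1  # 1-based incl
                donor = _slice_padded(contig, intron_start - 1 - 3, intron_start - 1 + 8)
                acceptor = _slice_padded(contig, intron_end - 6, intron_end + 1)
            else:
                intron_start, intron_end = b.end + 1, a.start - 1
                donor = _revcomp(
                    _slice_padded(contig, intron_end - 8, intron_end + 3)
                )
                acceptor = _revcomp(
                    _slice_padded(contig, intron_start - 2, intron_start + 5)
                )
            records.append(
                IntronRecord(
                    species=species,
                    protein=str(protein),
                    orthogroup=(orthogroup_of or {}).get(str(protein), ""),
                    residue_index=(coding - 1) // 3,
                    phase=coding % 3,
                    donor_window=donor,
                    acceptor_window=acceptor,
                )
            )
    return records


def extract_from_files(
    fasta_path,
    gff3_path,
    species: str,
    orthogroup_of: dict[str, str] | None = None,
) -> list[IntronRecord]:
    """File front-end to :func:`extract_intron_table` (FASTA + GFF3)."""
    import gffutils
    from Bio import SeqIO

    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        {
            "seqid": cds.seqid,
            "start": cds.start,
            "end": cds.end,
            "strand": cds.strand,
            "protein": cds.attributes.get("Parent", [cds.id])[0],
        }
        for cds in db.features_of_type("CDS")
    ]
    if not rows:
        return []
    return extract_intron_table(genome, pd.DataFrame(rows), species, orthogroup_of)


# ---------------------------------------------------------------------------
# TSV round-trip

_TSV_COLUMNS = [
    "species",
    "protein",
    "orthogroup",
    "residue_index",
    "phase",
    "donor_window",
    "acceptor_window",
]


def write_intron_table(records, path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_intron_table(path) -> list[IntronRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intron table missing columns {sorted(missing)}")
    return [
        IntronRecord(
            species=row.species,
            protein=row.protein,
            orthogroup=row.orthogroup,
            residue_index=int(row.residue_index),
            phase=int(row.phase),
            donor_window=row.donor_window,
            acceptor_window=row.acceptor_window,
        )
        for row in df.itertuples()
    ]
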