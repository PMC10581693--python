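"""End-to-end orchestration: simulate -> filter -> phenotypes -> PGLS -> ...

A run is described by a :class:`RunConfig` (deserialisable from YAML).
When input paths are omitted the synthetic generator produces them, so
``splicemap run -c config.yaml`` exercises the whole analysis without
external data.  Stages execute in dependency order, never mutate their
inputs, and stamp every output table with the tool version, seed and
input hashes; a rerun with the same config reproduces every table.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .ancestral import node_ids, node_times, round_to_grid, sankoff_fractions, traitgram_table
from .domains import read_alphafold_json, segment_confidence
from .genotypes import PresenceAbsenceTable, filter_orthogroups, parse_orthogroups, write_orthogroups
from .introns import filter_conserved_introns, read_intron_table, write_intron_table
from .phenotypes import (
    SpliceSiteMatrix,
    nucleotide_fractions,
    phenotype_vector,
    u5u6_rho,
)
from .pgls import association_scan
from .simulate import (
    SimulationConfig,
    simulate_confidence,
    simulate_dollo_genotype,
    simulate_intron_dataset,
    simulate_tree,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to one YAML file."""

    out_dir: str = "splicemap_run"
    seed: int = 0
    # input paths; any left None is synthesised by the simulate stage
    tree: str | None = None
    orthogroups: str | None = None
    introns: str | None = None
    alignments_dir: str | None = None
    confidence: str | None = None
    # generator settings (used only when inputs are missing)
    simulation: dict = field(default_factory=dict)
    # analysis settings
    position: int = 4
    num_set: str = "A"
    den_set: str = "T"
    bootstrap: int = 100
    min_species: int = 2
    min_present: int = 5
    min_losses: int = 2
    u56_bootstrap: int = 100
    sankoff_step: float = 0.05
    plddt_min: float = 70.0
    pae_max: float = 5.0
    min_domain_size: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _provenance(config: RunConfig, **extra) -> dict:
    prov = {"tool": f"splicemap {__version__}", "seed": config.seed}
    prov.update(extra)
    return prov


def simulate_inputs(config: RunConfig) -> RunConfig:
    """Generate any missing input files under ``out_dir/inputs``.

    Produces a species tree, presence/absence orthogroups (one causal
    genotype plus nulls), orthogroup alignments with intron tables whose
    +4 composition tracks the causal genotype, and a confidence JSON.
    Returns a copy of the config with the paths filled in.
    """
    sim = SimulationConfig(seed=config.seed, **config.simulation)
    rng = np.random.default_rng(sim.seed)
    indir = Path(config.out_dir) / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config)
    tree = None
    if cfg.tree is None:
        tree = simulate_tree(sim.n_species, sim.birth_rate, rng)
        cfg.tree = str(indir / "species_tree.nwk")
        io.write_tree(tree, cfg.tree)
    else:
        tree = io.read_tree(cfg.tree)
    causal = simulate_dollo_genotype(
        tree, sim.loss_rate, rng, require="filter_pass",
        min_present=cfg.min_present, min_losses=cfg.min_losses,
    )
    if cfg.orthogroups is None:
        genos = {"OG_causal": causal}
        for i in range(sim.n_null_orthogroups):
            genos[f"OG_null{i:03d}"] = simulate_dollo_genotype(
                tree, sim.loss_rate, rng, require="filter_pass",
                min_present=cfg.min_present, min_losses=cfg.min_losses,
            )
        presence = pd.DataFrame(genos).T.astype(np.int8)[tree.leaf_labels]
        table = PresenceAbsenceTable(presence, presence.astype(int))
        cfg.orthogroups = str(indir / "orthogroups.tsv")
        write_orthogroups(table, cfg.orthogroups)
    if cfg.introns is None or cfg.alignments_dir is None:
        alignments, records, _ = simulate_intron_dataset(tree, causal, sim, rng)
        cfg.introns = str(indir / "introns.tsv")
        write_intron_table(records, cfg.introns)
        adir = indir / "alignments"
        adir.mkdir(exist_ok=True)
        for og, aln in alignments.items():
            io.write_orthogroup_fasta(aln, adir / f"{og}.fasta")
        cfg.alignments_dir = str(adir)
    if cfg.confidence is None:
        conf = simulate_confidence(seed=rng)
        cfg.confidence = str(indir / "confidence.json")
        io.write_confidence_json(conf, cfg.confidence)
    return cfg


def _splice_matrices(records) -> dict[str, SpliceSiteMatrix]:
    per_species = defaultdict(list)
    for rec in records:
        per_species[rec.species].append(rec)
    return {
        sp: SpliceSiteMatrix.from_windows(
            sp,
            [r.donor_window for r in recs],
            [r.acceptor_window for r in recs] if all(r.acceptor_window for r in recs) else None,
        )
        for sp, recs in per_species.items()
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Emits conserved_introns.tsv, phenotypes.tsv, genotypes.tsv,
    associations.tsv, traitgram.tsv, ancestral_fractions.tsv, u56.tsv and
    domains.tsv, plus a copy of the effective config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = simulate_inputs(config)
    config.to_yaml(out / "config_used.yaml")
    for path in (config.tree, config.orthogroups, config.introns, config.confidence):
        if path and not Path(path).exists():
            raise StageError(f"config: input {path} does not exist")

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name} failed: {exc}") from exc

    tree = stage("tree", lambda: io.read_tree(config.tree))
    hashes = {"tree_sha": io.file_sha256(config.tree)}

    def do_introns():
        records = read_intron_table(config.introns)
        adir = Path(config.alignments_dir)
        alignments = {
            p.stem: io.read_orthogroup_fasta(p) for p in sorted(adir.glob("*.fasta"))
        }
        kept = filter_conserved_introns(alignments, records, config.min_species)
        write_intron_table(kept, out / "conserved_introns.tsv")
        logger.info("introns: %d of %d kept", len(kept), len(records))
        return kept

    conserved = stage("introns", do_introns)

    def do_phenotypes():
        mats = _splice_matrices(conserved)
        pv = phenotype_vector(
            mats,
            position=config.position,
            num_set=tuple(config.num_set),
            den_set=tuple(config.den_set),
            B=config.bootstrap,
            seed=config.seed,
        )
        io.write_table(pv.to_frame(), out / "phenotypes.tsv", _provenance(config, **hashes))
        return mats, pv

    matrices, phenotypes_vec = stage("phenotypes", do_phenotypes)

    def do_genotypes():
        table = parse_orthogroups(config.orthogroups)
        filtered = filter_orthogroups(
            table, tree, min_present=config.min_present, min_losses=config.min_losses
        )
        meta = filtered.metadata.reset_index(names="orthogroup")
        io.write_table(meta, out / "genotypes.tsv", _provenance(config, **hashes))
        logger.info(
            "genotypes: %d of %d orthogroups kept",
            len(filtered.orthogroups),
            len(table.orthogroups),
        )
        return filtered

    genotype_table = stage("genotypes", do_genotypes)

    def do_assoc():
        res = association_scan(phenotypes_vec, genotype_table, tree)
        res = res.sort_values("p").reset_index(drop=True)
        io.write_table(res, out / "associations.tsv", _provenance(config, **hashes))
        return res

    stage("assoc", do_assoc)

    def do_ancestral():
        tips = dict(zip(phenotypes_vec.species, phenotypes_vec.estimate))
        tg = traitgram_table(tree, tips)
        io.write_table(tg, out / "traitgram.tsv", _provenance(config, **hashes))
        leaf_states = {
            sp: round_to_grid(
                nucleotide_fractions(matrices[sp], config.position), config.sankoff_step
            )
            for sp in matrices
        }
        assignment, cost = sankoff_fractions(
            tree, leaf_states, step=config.sankoff_step
        )
        ids, times = node_ids(tree), node_times(tree)
        rows = [
            {
                "node": ids[n],
                "time": times[n],
                **dict(zip(["A", "C", "G", "T"], st.fractions)),
            }
            for n, st in assignment.items()
        ]
        io.write_table(
            pd.DataFrame(rows),
            out / "ancestral_fractions.tsv",
            _provenance(config, sankoff_cost=round(cost, 6), **hashes),
        )

    stage("ancestral", do_ancestral)

    def do_u56():
        rows = []
        for sp in sorted(matrices):
            rho, (lo, hi) = u5u6_rho(matrices[sp], B=config.u56_bootstrap, seed=config.seed)
            rows.append(
                {
                    "species": sp,
                    "u56_rho": rho,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_introns": matrices[sp].n_introns,
                }
            )
        io.write_table(pd.DataFrame(rows), out / "u56.tsv", _provenance(config, **hashes))

    stage("u56", do_u56)

    def do_segment():
        conf = read_alphafold_json(config.confidence)
        ds = segment_confidence(
            conf,
            plddt_min=config.plddt_min,
            pae_max=config.pae_max,
            min_size=config.min_domain_size,
        )
        io.write_table(ds.to_frame(), out / "domains.tsv", _provenance(config, **hashes))

    stage("segment", do_segment)
    logger.info("pipeline complete: %s", out)
    return out
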