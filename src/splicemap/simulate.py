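"""Synthetic study generator: every input the pipeline reads, with known truth.

The generators emulate the statistical structure the analysis assumes --
an ultrametric species tree, irreversible (Dollo) gene-loss genotypes,
Brownian phenotypes with an additive genotype effect, donor-site tables
whose +4 A/U balance depends on genotype, consensus-alignment residue
variation, and block-structured PAE/pLDDT matrices -- so every stage can
be tested for parameter recovery without any external data.  All
generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .introns import IntronRecord, OrthogroupAlignment
from .phenotypes import PhenotypeVector
from .phylo import PhyloTree, parse_newick, tree_covariance
from .domains import ConfidenceData

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_dollo_genotype",
    "simulate_bm_phenotype",
    "simulate_phenotype_replicates",
    "simulate_intron_dataset",
    "simulate_residue_alignment",
    "simulate_confidence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
LN2 = float(np.log(2.0))

# Donor-window composition away from the genotype-sensitive +4 position.
# Positions -3..-1 are exonic background; +1+2 are the invariant GT; the
# remaining intronic positions follow a loose eukaryotic donor consensus.
_DONOR_PROFILES = {
    -3: (0.3, 0.3, 0.2, 0.2),
    -2: (0.5, 0.15, 0.15, 0.2),
    -1: (0.1, 0.05, 0.75, 0.1),
    1: (0.0, 0.0, 1.0, 0.0),  # G
    2: (0.0, 0.0, 0.0, 1.0),  # T
    3: (0.5, 0.05, 0.4, 0.05),
    5: (0.1, 0.05, 0.7, 0.15),
    6: (0.2, 0.1, 0.1, 0.6),
    7: (0.3, 0.1, 0.2, 0.4),
    8: (0.25, 0.25, 0.25, 0.25),
}
_ACCEPTOR_PROFILES = [  # -6..-1 then +1
    (0.1, 0.3, 0.1, 0.5),
    (0.1, 0.3, 0.1, 0.5),
    (0.1, 0.3, 0.1, 0.5),
    (0.05, 0.5, 0.05, 0.4),  # -3: mostly C/T
    (1.0, 0.0, 0.0, 0.0),  # -2: A
    (0.0, 0.0, 1.0, 0.0),  # -1: G
    (0.3, 0.2, 0.3, 0.2),  # +1 exon
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the conditions used throughout the test-bench:
    150 species on a Yule tree, Brownian trait variance 1 per unit branch
    length, a genotype effect of 1 on the log2-ratio scale, 500 conserved
    introns per species, and 50 null orthogroups alongside any causal one.
    """

    seed: int = 0
    n_species: int = 150
    birth_rate: float = 1.0
    loss_rate: float = 0.4
    bm_sigma2: float = 1.0
    genotype_effect: float = 1.0
    intercept: float = 0.0
    phenotype_noise_sd: float = 0.03
    n_bootstrap: int = 100
    n_introns_per_species: int = 500
    donor_logit_base: float = 0.0
    donor_logit_shift: float = 1.0
    n_null_orthogroups: int = 50
    n_intron_orthogroups: int = 25
    protein_length: int = 120
    substitution_prob: float = 0.05
    deletion_prob: float = 0.03
    spurious_fraction: float = 0.2

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.birth_rate <= 0 or self.loss_rate < 0 or self.bm_sigma2 < 0:
            raise ValueError("rates must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_tree(
    n_species: int = 150,
    birth_rate: float = 1.0,
    seed=0,
    scale_height: float | None = 1.0,
) -> PhyloTree:
    """Ultrametric pure-birth (Yule) species tree with n_species leaves.

    Tip edges are extended by one extra exponential waiting time so no
    terminal branch has length zero (dendropy stops exactly at the last
    birth event, which would create an identical-species pair).  By
    default the tree is rescaled to height ``scale_height`` = 1, the
    usual convention in comparative-method simulations: branch lengths
    are then fractions of the root-to-tip time and a Brownian rate of 1
    means unit trait variance at the tips.  Pass ``scale_height=None``
    to keep the raw coalescent-time units.
    """
    from dendropy.simulate import treesim

    rng = _rng(seed)
    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=py_rng,
    )
    extra = float(rng.exponential(1.0 / (birth_rate * n_species)))
    width = len(str(n_species))
    for i, leaf in enumerate(
        sorted(dtree.leaf_node_iter(), key=lambda l: l.taxon.label)
    ):
        leaf.edge.length += extra
        leaf.taxon.label = f"s{i + 1:0{width}d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(newick)
    if scale_height is not None:
        from .phylo import node_times

        height = max(node_times(tree)[leaf] for leaf in tree.leaves)
        for node in tree.preorder():
            node.branch_length *= scale_height / height
    return tree


def simulate_dollo_genotype(
    tree: PhyloTree,
    loss_rate: float = 0.02,
    seed=0,
    require: str = "polymorphic",
    min_present: int = 5,
    min_losses: int = 2,
    max_tries: int = 1000,
) -> dict[str, int]:
    """Single-gain, irreversible-loss genotype over the tree's leaves.

    The gene is present at the root and lost on each branch with
    probability 1 - exp(-loss_rate * branch_length); all descendants of a
    loss are absent.  ``require`` controls rejection sampling: ``"none"``
    returns the first draw, ``"polymorphic"`` requires both states among
    the leaves, and ``"filter_pass"`` additionally requires at least
    ``min_present`` present species and ``min_losses`` Dollo losses (a
    genotype the orthogroup filter would keep).
    """
    from .phylo import dollo_losses

    rng = _rng(seed)
    for _ in range(max_tries):
        state: dict = {}
        genotype: dict[str, int] = {}
        for node in tree.preorder():
            if node is tree.root:
                state[node] = 1
            else:
                p_loss = 1.0 - np.exp(-loss_rate * node.branch_length)
                state[node] = state[node.parent] and int(rng.random() >= p_loss)
            if node.is_leaf:
                genotype[node.label] = state[node]
        values = set(genotype.values())
        if require == "none":
            return genotype
        if values != {0, 1}:
            continue
        if require == "polymorphic":
            return genotype
        if require == "filter_pass":
            n_present = sum(genotype.values())
            if n_present >= min_present and dollo_losses(tree, genotype)[0] >= min_losses:
                return genotype
    raise RuntimeError(
        f"no genotype satisfying {require!r} in {max_tries} draws "
        f"(loss_rate={loss_rate})"
    )


def simulate_bm_phenotype(
    tree: PhyloTree,
    genotype: dict[str, int],
    config: SimulationConfig | None = None,
    seed=0,
) -> dict[str, float]:
    """Brownian phenotype with an additive genotype effect.

    y = intercept + effect * genotype + eps with eps multivariate normal,
    covariance bm_sigma2 * Sigma(tree).  At bm_sigma2 = 0 the phenotype
    is exactly the linear predictor.
    """
    config = config or SimulationConfig()
    rng = _rng(seed)
    labels = tree.leaf_labels
    sigma = tree_covariance(tree, labels).values
    n = len(labels)
    eps = np.zeros(n)
    if config.bm_sigma2 > 0:
        L = np.linalg.cholesky(sigma + 1e-12 * np.trace(sigma) / n * np.eye(n))
        eps = np.sqrt(config.bm_sigma2) * (L @ rng.standard_normal(n))
    g = np.array([genotype[l] for l in labels], dtype=float)
    y = config.intercept + config.genotype_effect * g + eps
    return dict(zip(labels, y))


def simulate_phenotype_replicates(
    tree: PhyloTree,
    genotype: dict[str, int],
    config: SimulationConfig | None = None,
    seed=0,
) -> tuple[PhenotypeVector, dict[str, float]]:
    """Noisy phenotype measurements with bootstrap-style replicates.

    Each species' point estimate is its true Brownian value plus one
    i.i.d. measurement error (SD ``phenotype_noise_sd``, emulating finite
    intron sampling); the B replicates scatter around the estimate with
    the same SD, as intron-bootstrap replicates would.  Returns the
    vector and the underlying true values.
    """
    config = config or SimulationConfig()
    rng = _rng(seed)
    truth = simulate_bm_phenotype(tree, genotype, config, rng)
    species = sorted(truth)
    y = np.array([truth[s] for s in species])
    s = config.phenotype_noise_sd
    est = y + s * rng.standard_normal(len(y))
    reps = est[:, None] + s * rng.standard_normal((len(y), config.n_bootstrap))
    return PhenotypeVector(species, est, reps), truth


# ---------------------------------------------------------------------------
# Intron dataset


def _draw_column(rng, profile, size) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=size, p=np.asarray(profile))


def simulate_intron_dataset(
    tree: PhyloTree,
    genotype: dict[str, int],
    config: SimulationConfig | None = None,
    seed=0,
) -> tuple[dict[str, OrthogroupAlignment], list[IntronRecord], dict]:
    """Toy orthogroups with conserved and spurious introns.

    An ancestral protein per orthogroup is mutated (substitutions and
    deletions) along the species set; conserved introns sit at shared
    (alignment column, phase) coordinates in every species retaining the
    residue, while spurious introns occupy (column, phase) slots used by
    exactly one species, so the conserved/spurious ground truth is exact.
    Donor windows start GT and have P(+4 = A) =
    logistic(donor_logit_base + donor_logit_shift * genotype), the rest
    of the +4 mass going to T; the measured log2 A:U ratio therefore has
    expectation (base + shift * g) / ln 2.

    Returns (alignments, records, truth) where truth maps "conserved" and
    "spurious" to sets of (orthogroup, species, residue_index, phase).
    """
    config = config or SimulationConfig()
    rng = _rng(seed)
    species = tree.leaf_labels
    n_cons = max(1, config.n_introns_per_species // config.n_intron_orthogroups)
    alignments: dict[str, OrthogroupAlignment] = {}
    records: list[IntronRecord] = []
    truth = {"conserved": set(), "spurious": set()}
    aas = np.array(list(AMINO_ACIDS))
    for og_i in range(config.n_intron_orthogroups):
        og = f"OG{og_i:04d}"
        L = config.protein_length
        ancestor = rng.choice(aas, size=L)
        rows: dict[str, str] = {}
        species_of: dict[str, str] = {}
        deleted: dict[str, np.ndarray] = {}
        for sp in species:
            seq = ancestor.copy()
            sub = rng.random(L) < config.substitution_prob
            seq[sub] = rng.choice(aas, size=int(sub.sum()))
            dele = rng.random(L) < config.deletion_prob
            seq[dele] = "-"
            prot = f"{og}_{sp}"
            rows[prot] = "".join(seq)
            species_of[prot] = sp
            deleted[sp] = dele
        alignments[og] = OrthogroupAlignment(og, rows, species_of)
        # conserved (column, phase) slots shared by all retaining species,
        # then one private slot per spurious intron
        n_spur_per_sp = int(round(config.spurious_fraction * n_cons))
        n_slots = n_cons + n_spur_per_sp * len(species)
        slots = rng.choice(3 * L, size=min(n_slots, 3 * L), replace=False)
        cons_slots = slots[:n_cons]
        spur_slots = iter(slots[n_cons:])

        def emit(sp: str, column: int, phase: int, kind: str) -> None:
            if deleted[sp][column]:
                return
            residue_index = int(np.sum(~deleted[sp][: column + 1]) - 1)
            g = genotype.get(sp, 0)
            p_a = 1.0 / (1.0 + np.exp(-(config.donor_logit_base + config.donor_logit_shift * g)))
            window = []
            for pos in (-3, -2, -1, 1, 2, 3, 4, 5, 6, 7, 8):
                if pos == 4:
                    window.append("A" if rng.random() < p_a else "T")
                else:
                    window.append(str(_draw_column(rng, _DONOR_PROFILES[pos], None)))
            acceptor = "".join(
                str(_draw_column(rng, prof, None)) for prof in _ACCEPTOR_PROFILES
            )
            records.append(
                IntronRecord(
                    species=sp,
                    protein=f"{og}_{sp}",
                    orthogroup=og,
                    residue_index=residue_index,
                    phase=phase,
                    donor_window="".join(window),
                    acceptor_window=acceptor,
                )
            )
            truth[kind].add((og, sp, residue_index, phase))

        for slot in cons_slots:
            column, phase = int(slot) % L, int(slot) // L
            before = len(records)
            for sp in species:
                emit(sp, column, phase, "conserved")
            made = records[before:]
            if len({r.species for r in made}) < 2:
                # deletions left the site in < 2 species: it is not
                # conserved by the filter's definition, relabel it
                for r in made:
                    key = (og, r.species, r.residue_index, phase)
                    truth["conserved"].discard(key)
                    truth["spurious"].add(key)
        for sp in species:
            for _ in range(n_spur_per_sp):
                slot = next(spur_slots, None)
                if slot is None:
                    break
                emit(sp, int(slot) % L, int(slot) // L, "spurious")
    return alignments, records, truth


# ---------------------------------------------------------------------------
# Consensus residue alignment


def simulate_residue_alignment(
    n_species: int = 100,
    n_columns: int = 40,
    causal_column: int = 10,
    effect: float = 1.0,
    seed=0,
    tree: PhyloTree | None = None,
    match_prob: float = 0.85,
) -> tuple[dict[str, str], dict[str, float], dict[str, int]]:
    """Consensus-anchored alignment with one trait-linked column.

    Species rows mostly match the consensus; at the causal column a
    latent binary state decides between the consensus residue (state 1)
    and the most dissimilar residue by BLOSUM62 (state 0), and the
    returned trait is ``effect * state`` plus unit noise (Brownian along
    ``tree`` when given, i.i.d. otherwise).  With ``effect = 0`` no
    column is informative beyond chance.

    Returns (rows including the CONSENSUS row, trait, latent state).
    """
    from Bio.Align import substitution_matrices

    rng = _rng(seed)
    if tree is not None:
        species = tree.leaf_labels
        n_species = len(species)
    else:
        width = len(str(n_species))
        species = [f"s{i + 1:0{width}d}" for i in range(n_species)]
    if not 0 <= causal_column < n_columns:
        raise ValueError("causal_column out of range")
    aas = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(aas, size=n_columns)
    blosum = substitution_matrices.load("BLOSUM62")
    ref = str(consensus[causal_column])
    worst = min(AMINO_ACIDS, key=lambda a: blosum[ref, a])
    state = {sp: int(rng.random() < 0.5) for sp in species}
    rows = {"CONSENSUS": "".join(consensus)}
    for sp in species:
        seq = consensus.copy()
        mism = rng.random(n_columns) >= match_prob
        seq[mism] = rng.choice(aas, size=int(mism.sum()))
        seq[causal_column] = ref if state[sp] else worst
        rows[sp] = "".join(seq)
    if tree is not None:
        noise = simulate_bm_phenotype(
            tree,
            {sp: 0 for sp in species},
            SimulationConfig(genotype_effect=0.0, bm_sigma2=1.0),
            rng,
        )
        trait = {sp: effect * state[sp] + noise[sp] for sp in species}
    else:
        trait = {
            sp: effect * state[sp] + float(rng.standard_normal()) for sp in species
        }
    return rows, trait, state


# ---------------------------------------------------------------------------
# Structure confidence


def simulate_confidence(
    domain_sizes=(50, 50),
    intra_pae: float = 2.0,
    inter_pae: float = 12.0,
    plddt_high: float = 90.0,
    plddt_low: float = 50.0,
    n_disordered: int = 0,
    noise: float = 0.25,
    seed=0,
) -> ConfidenceData:
    """Planted-partition PAE/pLDDT matrices for segmentation tests.

    Within-block PAE is low (``intra_pae``), between-block PAE high
    (``inter_pae``), both jittered by uniform noise; an optional
    disordered tail gets low pLDDT and high PAE everywhere.
    """
    rng = _rng(seed)
    n_dom = int(np.sum(domain_sizes))
    n = n_dom + n_disordered
    pae = np.full((n, n), inter_pae)
    start = 0
    for size in domain_sizes:
        pae[start : start + size, start : start + size] = intra_pae
        start += size
    if noise > 0:
        pae = pae + rng.uniform(-noise, noise, size=(n, n))
    pae = np.clip(pae, 0.0, None)
    np.fill_diagonal(pae, 0.0)
    plddt = np.full(n, plddt_high, dtype=float)
    plddt[n_dom:] = plddt_low
    return ConfidenceData(pae=pae, plddt=plddt)
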