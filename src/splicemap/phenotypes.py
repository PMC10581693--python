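"""Splice-site composition phenotypes, PSSMs and the U5/6rho statistic.

A species' splicing-signal phenotype is summarised from the donor (5'SS)
windows of its conserved introns.  The primary trait is the +4 A:U log2
ratio; bootstrap resampling of introns propagates the (highly variable)
per-species intron counts into confidence intervals.  A per-species
position-specific scoring matrix (PSSM) over the donor consensus yields,
for each site, a U5 score (exonic -3..-1) and a U6 score (intronic
+3..+7); their per-species Spearman correlation is the U5/6rho statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DONOR_POSITIONS",
    "SpliceSiteMatrix",
    "PhenotypeVector",
    "PSSM",
    "nucleotide_fractions",
    "ratio_phenotype",
    "bootstrap_phenotype",
    "phenotype_vector",
    "ratio_sd_scan",
    "default_ratio_definitions",
    "build_pssm",
    "u5u6_scores",
    "u5u6_rho",
]

# Donor window spans -3..-1 (exon) and +1..+8 (intron); no position zero.
DONOR_POSITIONS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3, 4, 5, 6, 7, 8)
NUCLEOTIDES = "ACGT"
U5_POSITIONS = (-3, -2, -1)
U6_POSITIONS = (3, 4, 5, 6, 7)


def _pos_index(position: int) -> int:
    try:
        return DONOR_POSITIONS.index(position)
    except ValueError:
        raise ValueError(
            f"position {position} outside donor window -3..-1,+1..+8"
        ) from None


def _normalise_window(window: str) -> str:
    w = window.upper().replace("U", "T")
    if any(c not in "ACGTN" for c in w):
        raise ValueError(f"invalid nucleotide in window {window!r}")
    return w


@dataclass
class SpliceSiteMatrix:
    """Donor windows of one species' introns as an (n_introns, 11) array.

    Columns follow :data:`DONOR_POSITIONS`.  ``acceptor_minus3`` optionally
    carries the acceptor -3 nucleotide of each intron so that 3'SS
    phenotypes reuse the same ratio machinery.
    """

    species: str
    donors: np.ndarray
    acceptor_minus3: np.ndarray | None = None

    @classmethod
    def from_windows(
        cls,
        species: str,
        windows,
        acceptor_windows=None,
        gt_warn_fraction: float = 0.9,
    ) -> "SpliceSiteMatrix":
        rows = [_normalise_window(w) for w in windows]
        if not rows:
            raise ValueError(f"{species}: no donor windows")
        if any(len(w) != len(DONOR_POSITIONS) for w in rows):
            raise ValueError(f"{species}: donor windows must be 11-mers")
        donors = np.array([list(w) for w in rows], dtype="U1")
        acc = None
        if acceptor_windows is not None:
            accs = [_normalise_window(w) for w in acceptor_windows]
            if len(accs) != len(rows):
                raise ValueError("acceptor window count mismatch")
            # acceptor window spans -6..-1,+1; -3 is offset 3
            acc = np.array([w[3] for w in accs], dtype="U1")
        mat = cls(species=species, donors=donors, acceptor_minus3=acc)
        gt = np.mean((donors[:, _pos_index(1)] == "G") & (donors[:, _pos_index(2)] == "T"))
        if gt < gt_warn_fraction:
            warnings.warn(
                f"{species}: only {gt:.0%} of donors start GT at +1+2",
                stacklevel=2,
            )
        return mat

    @property
    def n_introns(self) -> int:
        return self.donors.shape[0]

    def column(self, position: int) -> np.ndarray:
        return self.donors[:, _pos_index(position)]

    def resample(self, rng: np.random.Generator) -> "SpliceSiteMatrix":
        idx = rng.integers(0, self.n_introns, size=self.n_introns)
        acc = self.acceptor_minus3[idx] if self.acceptor_minus3 is not None else None
        return SpliceSiteMatrix(self.species, self.donors[idx], acc)


def nucleotide_fractions(sites: SpliceSiteMatrix, position: int) -> np.ndarray:
    """Fractions of A, C, G, T at a donor position, ignoring Ns."""
    col = sites.column(position)
    counts = np.array([np.sum(col == nt) for nt in NUCLEOTIDES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{sites.species}: position {position} is all N")
    return counts / total


def _set_counts(col: np.ndarray, nt_set) -> float:
    nt_set = {s.upper().replace("U", "T") for s in nt_set}
    return float(np.isin(col, sorted(nt_set)).sum())


def ratio_phenotype(
    sites: SpliceSiteMatrix,
    position: int,
    num_set=("A",),
    den_set=("T",),
    pseudocount: float = 0.5,
    acceptor: bool = False,
) -> float:
    """log2 count ratio of two disjoint nucleotide sets at one position.

    The +4 A:U phenotype is ``ratio_phenotype(sites, 4, {"A"}, {"T"})``.
    Pseudocounts keep the ratio finite and make it exactly antisymmetric
    under swapping numerator and denominator.  With ``acceptor=True`` the
    acceptor -3 column is scored instead (``position`` is ignored).
    """
    num = {s.upper().replace("U", "T") for s in num_set}
    den = {s.upper().replace("U", "T") for s in den_set}
    if num & den:
        raise ValueError("numerator and denominator sets must be disjoint")
    if acceptor:
        if sites.acceptor_minus3 is None:
            raise ValueError(f"{sites.species}: no acceptor data")
        col = sites.acceptor_minus3
    else:
        col = sites.column(position)
    # computed as a difference of logs so swapping the sets negates the
    # value exactly, bit for bit
    return float(
        np.log2(_set_counts(col, num) + pseudocount)
        - np.log2(_set_counts(col, den) + pseudocount)
    )


def bootstrap_phenotype(
    sites: SpliceSiteMatrix,
    position: int,
    num_set=("A",),
    den_set=("T",),
    B: int = 100,
    seed: int | np.random.Generator = 0,
    pseudocount: float = 0.5,
    acceptor: bool = False,
) -> tuple[float, np.ndarray]:
    """Point estimate and B bootstrap replicates of a ratio phenotype.

    Each replicate resamples the species' introns with replacement,
    mirroring the uncertainty from widely varying intron counts.
    """
    rng = np.random.default_rng(seed)
    point = ratio_phenotype(sites, position, num_set, den_set, pseudocount, acceptor)
    reps = np.empty(B)
    for b in range(B):
        reps[b] = ratio_phenotype(
            sites.resample(rng), position, num_set, den_set, pseudocount, acceptor
        )
    return point, reps


@dataclass
class PhenotypeVector:
    """Per-species trait estimates with B bootstrap replicates each."""

    species: list[str]
    estimate: np.ndarray
    replicates: np.ndarray  # shape (n_species, B)

    def __post_init__(self):
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.shape[0] != len(self.species):
            raise ValueError("replicate rows must match species")
        if not np.all(np.isfinite(self.estimate)):
            raise ValueError("non-finite phenotype estimate")

    @property
    def B(self) -> int:
        return self.replicates.shape[1]

    def ci(self, level: float = 0.95) -> np.ndarray:
        lo = 100 * (1 - level) / 2
        return np.percentile(self.replicates, [lo, 100 - lo], axis=1).T

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci()
        return pd.DataFrame(
            {
                "species": self.species,
                "estimate": self.estimate,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "B": self.B,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def phenotype_vector(
    matrices: dict[str, SpliceSiteMatrix],
    position: int = 4,
    num_set=("A",),
    den_set=("T",),
    B: int = 100,
    seed: int = 0,
    pseudocount: float = 0.5,
    acceptor: bool = False,
) -> PhenotypeVector:
    """Bootstrap ratio phenotypes for every species, sorted by label."""
    species = sorted(matrices)
    root = np.random.default_rng(seed)
    est = np.empty(len(species))
    reps = np.empty((len(species), B))
    for i, sp in enumerate(species):
        est[i], reps[i] = bootstrap_phenotype(
            matrices[sp], position, num_set, den_set, B, root, pseudocount, acceptor
        )
    return PhenotypeVector(species, est, reps)


def default_ratio_definitions() -> dict[str, tuple[frozenset, frozenset]]:
    """Ratio set used for the per-position variability scan.

    All pairwise single-nucleotide ratios, each single nucleotide against
    the other three (IUPAC complement letter), and the R:Y and S:W
    two-against-two ratios.
    """
    defs: dict[str, tuple[frozenset, frozenset]] = {}
    for i, a in enumerate(NUCLEOTIDES):
        for b in NUCLEOTIDES[i + 1 :]:
            defs[f"{a}:{b}"] = (frozenset(a), frozenset(b))
    complements = {"A": "B", "C": "D", "G": "H", "T": "V"}
    for a in NUCLEOTIDES:
        rest = frozenset(NUCLEOTIDES) - frozenset(a)
        defs[f"{a}:{complements[a]}"] = (frozenset(a), rest)
    defs["R:Y"] = (frozenset("AG"), frozenset("CT"))
    defs["S:W"] = (frozenset("GC"), frozenset("AT"))
    return defs


def ratio_sd_scan(
    matrices: dict[str, SpliceSiteMatrix],
    positions=tuple(p for p in DONOR_POSITIONS if p <= 7),
    ratio_definitions: dict | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Across-species standard deviation of each ratio at each position.

    Highlights which donor positions actually vary between species: the
    invariant GT at +1+2 scores near zero while +4 stands out.
    """
    if ratio_definitions is None:
        ratio_definitions = default_ratio_definitions()
    usable = {sp: m for sp, m in matrices.items() if m.n_introns > 0}
    if len(usable) < len(matrices):
        warnings.warn("species with zero introns excluded from scan", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two species for an SD scan")
    rows = []
    for pos in positions:
        for name, (num, den) in ratio_definitions.items():
            vals = [
                ratio_phenotype(m, pos, num, den, pseudocount) for m in usable.values()
            ]
            rows.append({"position": pos, "ratio": name, "sd": float(np.std(vals, ddof=1))})
    return pd.DataFrame(rows)


@dataclass
class PSSM:
    """log2 position-specific scores over the U5 and U6 facing positions.

    ``scores[pos][nt] = log2((count + 0.5) / (n + 2))`` -- a smoothed log
    frequency with no background normalisation.  Any per-position additive
    constant cancels in downstream rank correlations.
    """

    positions: tuple[int, ...]
    matrix: np.ndarray  # (len(positions), 4), columns A C G T
    n_sites: int = 0
    nucleotides: str = field(default=NUCLEOTIDES, repr=False)

    def score(self, pos: int, nt: str) -> float:
        i = self.positions.index(pos)
        return float(self.matrix[i, NUCLEOTIDES.index(nt)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.positions, columns=list(NUCLEOTIDES))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="position")


PSSM_POSITIONS = U5_POSITIONS + U6_POSITIONS


def _scored_sites(sites: SpliceSiteMatrix) -> np.ndarray:
    """Donor rows with no N at any scored position, as an (n, 8) array."""
    cols = np.array([_pos_index(p) for p in PSSM_POSITIONS])
    sub = sites.donors[:, cols]
    keep = ~np.any(sub == "N", axis=1)
    return sub[keep]


def build_pssm(sites: SpliceSiteMatrix) -> PSSM:
    """Per-species donor PSSM over positions -3..-1 and +3..+7."""
    sub = _scored_sites(sites)
    if sub.shape[0] == 0:
        raise ValueError(f"{sites.species}: no N-free donor sites for PSSM")
    n = sub.shape[0]
    mat = np.empty((len(PSSM_POSITIONS), 4))
    for j in range(len(PSSM_POSITIONS)):
        for k, nt in enumerate(NUCLEOTIDES):
            count = np.sum(sub[:, j] == nt)
            mat[j, k] = np.log2((count + 0.5) / (n + 2.0))
    return PSSM(PSSM_POSITIONS, mat, n_sites=n)


def u5u6_scores(
    sites: SpliceSiteMatrix, pssm: PSSM | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """U5 (-3..-1) and U6 (+3..+7) match scores per N-free donor site."""
    if pssm is None:
        pssm = build_pssm(sites)
    sub = _scored_sites(sites)
    nt_index = np.zeros(sub.shape, dtype=int)
    for k, nt in enumerate(NUCLEOTIDES):
        nt_index[sub == nt] = k
    per_pos = pssm.matrix[np.arange(len(PSSM_POSITIONS))[None, :], nt_index]
    n_u5 = len(U5_POSITIONS)
    return per_pos[:, :n_u5].sum(axis=1), per_pos[:, n_u5:].sum(axis=1)


def u5u6_rho(
    sites: SpliceSiteMatrix,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Spearman correlation of per-site U5 vs U6 scores, with bootstrap CI.

    The PSSM is recomputed inside every bootstrap resample so the CI
    reflects uncertainty in the consensus itself.  Returns ``(rho,
    (ci_low, ci_high))``; rho is NaN (with a warning) when the scores are
    constant.
    """
    u5, u6 = u5u6_scores(sites)
    if len(u5) < 3:
        raise ValueError(f"{sites.species}: need >= 3 scorable sites")
    if np.all(u5 == u5[0]) or np.all(u6 == u6[0]):
        warnings.warn(f"{sites.species}: constant scores, rho undefined", stacklevel=2)
        return float("nan"), (float("nan"), float("nan"))
    rho = float(stats.spearmanr(u5, u6).statistic)
    rng = np.random.default_rng(seed)
    reps = np.full(B, np.nan)
    for b in range(B):
        rs = sites.resample(rng)
        try:
            r5, r6 = u5u6_scores(rs)
        except ValueError:
            continue
        if len(r5) >= 3 and not (np.all(r5 == r5[0]) or np.all(r6 == r6[0])):
            reps[b] = stats.spearmanr(r5, r6).statistic
    good = reps[np.isfinite(reps)]
    if len(good) == 0:
        return rho, (float("nan"), float("nan"))
    lo = 100 * (1 - ci_level) / 2
    ci = np.percentile(good, [lo, 100 - lo])
    return rho, (float(ci[0]), float(ci[1]))
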