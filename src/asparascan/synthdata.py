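"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study conditions of a pan-genomic asparaginase
survey without any downloads: bacterial genomes with planted asparaginase
ORFs of two length classes (short-chain 160-180 aa, long-chain 300-400 aa)
on both strands, mutationally diverged protein families, per-species enzyme
repertoires with localization labels, Michaelis-Menten velocity data with
optional lognormal noise, bell-shaped pH-activity profiles, and rigid-body
transformed coordinate sets.  Every generator is a pure function of its
arguments and a seed, and genome generators return a machine-readable truth
table so downstream stages can be scored against planted ground truth.

Design choices: intergenic background is i.i.d. uniform A/C/G/T (maximises
stop-codon density, keeping spurious ORFs short); reverse translation picks
uniformly among synonymous codons; family divergence substitutes i.i.d. per
site uniformly to any of the other 19 residues; planted genes are embedded
stop-to-stop with no promoter or RBS modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .kinetics import KineticModel, velocity

__all__ = [
    "AA20",
    "DEFAULT_PH_GRID",
    "LENGTH_RANGES",
    "PlantedGeneSpec",
    "GenePlan",
    "GenomePlan",
    "make_family",
    "make_genomes",
    "make_kinetic_dataset",
    "make_coords",
    "make_ph_profile",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

# Length classes of the two asparaginase families (residues).
LENGTH_RANGES = {"sc": (160, 180), "lc_typeI": (300, 400), "lc_typeII": (300, 400)}

# The 14-buffer assay grid spanning pH 4.5-11.
DEFAULT_PH_GRID = tuple(4.5 + 0.5 * i for i in range(14))

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
STOP_CODONS = tuple(sorted(_table.stop_codons))


@dataclass(frozen=True)
class PlantedGeneSpec:
    """Ground truth for one planted gene."""

    family_label: str            # 'lc_typeI' | 'lc_typeII' | 'sc'
    aa_length: int
    strand: str                  # '+' | '-'
    localization: str            # 'cytoplasmic' | 'SPI' | 'SPII'
    locus: tuple[int, int]       # forward-strand CDS, 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.locus[1] - self.locus[0] != 3 * self.aa_length:
            raise ValueError("locus must span exactly 3*aa_length nucleotides")


@dataclass(frozen=True)
class GenePlan:
    """A gene to plant: protein sequence plus annotations."""

    protein: str
    strand: str = "+"
    localization: str = "cytoplasmic"
    family: str = "sc"
    locus: tuple[int, int] | None = None   # explicit CDS placement (optional)

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError("protein must be non-empty")
        bad = set(self.protein) - set(AA20)
        if bad:
            raise ValueError(f"non-standard residues in protein: {sorted(bad)}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class GenomePlan:
    genome_id: str
    species: str
    genes: tuple[GenePlan, ...] = field(default_factory=tuple)


def make_family(
    ancestor_length: int,
    n: int,
    sub_rate: float,
    seed: int,
    ancestor: str | None = None,
) -> tuple[list[str], str]:
    """Simulate a diverged protein family.

    A random ancestor (first residue fixed to Met so planted genes begin with
    a start codon) is copied ``n`` times with i.i.d. per-site substitution at
    ``sub_rate``, each substitution drawn uniformly from the other 19
    residues.  Returns ``(members, ancestor)``.
    """
    if ancestor_length <= 0 or n <= 0:
        raise ValueError("ancestor_length and n must be positive")
    if not 0 <= sub_rate <= 1:
        raise ValueError("sub_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if ancestor is None:
        body = rng.integers(0, 20, size=ancestor_length - 1)
        ancestor = "M" + "".join(AA20[i] for i in body)
    elif len(ancestor) != ancestor_length:
        raise ValueError("ancestor length mismatch")
    anc = np.array([_AA_INDEX[a] for a in ancestor])
    members = []
    for _ in range(n):
        mutate = rng.random(len(anc)) < sub_rate
        shift = rng.integers(1, 20, size=len(anc))     # never the same residue
        child = np.where(mutate, (anc + shift) % 20, anc)
        members.append("".join(AA20[i] for i in child))
    return members, ancestor


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    )


def make_genomes(
    plans: list[GenomePlan],
    intergenic_len: int = 120,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build genomes with planted, stop-to-stop embedded genes.

    Each gene is reverse-translated, flanked by in-frame stop codons on its
    coding strand, and embedded (reverse-complemented for '-' strand genes)
    between stretches of uniform-random intergenic background.  Genes without
    an explicit locus are placed sequentially; requested loci must not
    overlap.  Returns the genomes and a truth table with columns genome_id,
    species, start, end, strand, family, localization, protein, where
    (start, end) is the forward-strand CDS whose strand-aware translation
    reproduces the protein exactly.
    """
    if not plans:
        raise ValueError("plans must be non-empty")
    if intergenic_len < 3:
        raise ValueError("intergenic_len must be >= 3 to flank genes with stops")
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    rows = []
    for plan in plans:
        placed: list[tuple[int, int, GenePlan, str]] = []  # (seg_start, seg_end, gene, segment)
        explicit = [g for g in plan.genes if g.locus is not None]
        implicit = [g for g in plan.genes if g.locus is None]

        def segment_for(gene: GenePlan) -> str:
            cds = _reverse_translate(gene.protein, rng)
            stop5 = STOP_CODONS[rng.integers(0, 3)]
            stop3 = STOP_CODONS[rng.integers(0, 3)]
            seg = stop5 + cds + stop3
            if gene.strand == "-":
                seg = str(Seq(seg).reverse_complement())
            return seg

        for gene in explicit:
            s, e = gene.locus
            seg = segment_for(gene)
            seg_start, seg_end = s - 3, e + 3
            if seg_start < 0:
                raise ValueError("explicit locus too close to genome start")
            for os, oe, _, _ in placed:
                if seg_start < oe and os < seg_end:
                    raise ValueError(
                        f"overlapping loci requested in genome {plan.genome_id}"
                    )
            placed.append((seg_start, seg_end, gene, seg))
        placed.sort(key=lambda p: p[0])

        cursor = intergenic_len
        for gene in implicit:
            seg = segment_for(gene)
            while True:
                seg_start, seg_end = cursor, cursor + len(seg)
                clash = next(
                    ((os, oe) for os, oe, _, _ in placed
                     if seg_start < oe and os < seg_end), None)
                if clash is None:
                    break
                cursor = clash[1] + intergenic_len
            placed.append((seg_start, seg_end, gene, seg))
            placed.sort(key=lambda p: p[0])
            cursor = seg_end + intergenic_len

        length = (max(e for _, e, _, _ in placed) if placed else 0) + intergenic_len
        background = rng.integers(0, 4, size=length)
        genome = np.array(list("ACGT"))[background]
        for seg_start, seg_end, _, seg in placed:
            genome[seg_start:seg_end] = list(seg)
        genome_str = "".join(genome)
        genomes[plan.genome_id] = genome_str

        for seg_start, seg_end, gene, _ in placed:
            cds = (seg_start + 3, seg_end - 3)
            rows.append({
                "genome_id": plan.genome_id,
                "species": plan.species,
                "start": cds[0],
                "end": cds[1],
                "strand": gene.strand,
                "family": gene.family,
                "localization": gene.localization,
                "protein": gene.protein,
            })
    truth = pd.DataFrame(
        rows,
        columns=["genome_id", "species", "start", "end", "strand",
                 "family", "localization", "protein"],
    )
    return genomes, truth


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and coefficient of variation cv."""
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def make_kinetic_dataset(
    model: KineticModel,
    S_grid,
    E0: float | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Velocities on a substrate grid, with optional lognormal noise.

    ``noise_cv`` is the coefficient of variation of a mean-1 multiplicative
    lognormal factor; 0 gives exact model values.  Returns a table with
    columns S_mM and v (dataset ``attrs`` carry E0 when given).
    """
    S = np.asarray(S_grid, dtype=float)
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    v = velocity(S, model)
    if noise_cv > 0:
        v = v * _lognormal_factors(np.random.default_rng(seed), noise_cv, len(S))
    df = pd.DataFrame({"S_mM": S, "v": v})
    df.attrs["E0"] = E0 if E0 is not None else model.E0
    return df


def make_coords(
    n_points: int,
    rotation: np.ndarray,
    translation: np.ndarray,
    jitter_sd: float = 0.0,
    seed: int = 0,
    reference: np.ndarray | None = None,
    spread: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A reference point cloud and its rigid-body transformed, jittered copy.

    transformed = rotation @ reference + translation + N(0, jitter_sd) per
    coordinate.  The rotation must be proper (orthonormal, det +1); fewer
    than 3 points or a collinear reference is rejected.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("improper rotation (determinant != +1) rejected")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    if reference is None:
        ref = rng.normal(0.0, spread, size=(n_points, 3))
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (n_points, 3):
            raise ValueError("reference must have shape (n_points, 3)")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry rejected")
    jitter = rng.normal(0.0, jitter_sd, size=ref.shape) if jitter_sd > 0 else 0.0
    transformed = ref @ R.T + t + jitter
    return ref, transformed


def make_ph_profile(
    optimum_pH: float,
    width: float,
    grid=DEFAULT_PH_GRID,
    noise_cv: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
) -> pd.DataFrame:
    """Bell-shaped (Gaussian in pH) activity profile on an assay grid.

    The noiseless profile peaks at the grid point nearest ``optimum_pH``; an
    infinite ``width`` yields a flat profile (downstream tie-breaking applies).
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("pH grid must be non-empty")
    if np.any((grid_arr < 0) | (grid_arr > 14)):
        raise ValueError("pH grid must lie within 0-14")
    if math.isinf(width):
        activity = np.full_like(grid_arr, amplitude)
    else:
        activity = amplitude * np.exp(-0.5 * ((grid_arr - optimum_pH) / width) ** 2)
    if noise_cv > 0:
        activity = activity * _lognormal_factors(
            np.random.default_rng(seed), noise_cv, grid_arr.size
        )
    return pd.DataFrame({"pH": grid_arr, "activity": activity})
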