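"""Translated homology search of protein queries against nucleotide genomes.

A TBLASTN-like survey stage: genomes are translated in all six reading frames,
each protein query is locally aligned (Smith-Waterman, affine gaps, BLOSUM62)
against each frame, alignment scores are converted to expectations with the
Karlin-Altschul formula E = K*m*n*exp(-lambda*S), and full-length open reading
frames are extracted around significant hits.

Coordinates are 0-based half-open internally; reverse-strand features are
always reported on forward-strand coordinates.  TSV writers in :mod:`.io`
convert to 1-based inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "AA20",
    "ScoringScheme",
    "LocalHit",
    "OpenReadingFrame",
    "six_frame_translate",
    "local_align",
    "evalue",
    "extract_orf",
    "survey",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NUC = set("ACGTN")
_QUERY_ALPHABET = set(AA20) | {"X"}
_SUBJECT_ALPHABET = _QUERY_ALPHABET | {"*"}
START_CODONS = ("ATG", "GTG", "TTG")
FRAMES = (1, 2, 3, -1, -2, -3)


@lru_cache(maxsize=1)
def _blosum62x() -> substitution_matrices.Array:
    """BLOSUM62 over the 20 amino acids plus X (scores 0 against everything)
    and the stop symbol '*' (scores -4 against everything)."""
    b62 = substitution_matrices.load("BLOSUM62")
    alphabet = AA20 + "X*"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "*" in (a, b):
                mat[a, b] = -4.0
            elif "X" in (a, b):
                mat[a, b] = 0.0
            else:
                mat[a, b] = b62[a, b]
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and Karlin-Altschul statistics.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of length k
    costs ``|gap_open| + k*|gap_extend|``.  ``lam`` (nats per score unit) and
    ``K`` are the standard ungapped BLOSUM62 Karlin-Altschul constants, used
    as documented defaults for the expectation E = K*m*n*exp(-lam*S).
    """

    matrix: substitution_matrices.Array | None = None
    gap_open: float = -11.0
    gap_extend: float = -1.0
    lam: float = 0.3176
    K: float = 0.134

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        mat = self.substitution_matrix
        if not np.allclose(np.asarray(mat), np.asarray(mat).T):
            raise ValueError("substitution matrix must be symmetric")

    @property
    def substitution_matrix(self) -> substitution_matrices.Array:
        return self.matrix if self.matrix is not None else _blosum62x()

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = self.substitution_matrix
        # Biopython charges open_gap_score for the first gapped position:
        # open -11 / extend -1 in BLAST terms is open -12 / extend -1 here.
        aligner.open_gap_score = self.gap_open + self.gap_extend
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass(frozen=True)
class LocalHit:
    """A significant local alignment of a query against one translated frame.

    ``prot_start/prot_end`` index the frame's translated protein; the
    nucleotide interval is on the forward strand regardless of frame sign.
    """

    query_id: str
    genome_id: str
    frame: int                    # +1..+3, -1..-3
    prot_start: int
    prot_end: int
    nt_start: int
    nt_end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.nt_end - self.nt_start != 3 * (self.prot_end - self.prot_start):
            raise ValueError("nucleotide interval must be 3x the protein interval")


@dataclass(frozen=True)
class OpenReadingFrame:
    """A stop-bounded coding region containing a hit.

    ``start``/``end`` delimit the full stop-to-stop ORF on the forward strand
    (flanking in-frame codons, or the sequence ends, are stops).  ``cds_start``
    /``cds_end`` delimit the start-codon-trimmed region actually translated
    into ``protein``; without trimming the two intervals coincide.
    """

    genome_id: str
    strand: str                  # '+' or '-'
    start: int
    end: int
    cds_start: int
    cds_end: int
    nt_seq: str                  # coding-strand nucleotides of the trimmed region
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 or (self.cds_end - self.cds_start) % 3:
            raise ValueError("ORF interval length must be divisible by 3")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain a stop symbol")


def _validate_nucleotides(genome: str) -> str:
    genome = genome.upper()
    bad = set(genome) - _NUC
    if bad:
        raise ValueError(f"non-nucleotide symbols in genome: {sorted(bad)}")
    return genome


def six_frame_translate(genome: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand at offsets 0..2, frames -1..-3 the
    reverse complement likewise.  Codons containing N translate to 'X',
    internal stops are retained as '*', trailing partial codons are dropped.
    """
    genome = _validate_nucleotides(genome)
    rc = str(Seq(genome).reverse_complement())
    frames: dict[int, str] = {}
    for offset in range(3):
        for sign, seq in ((1, genome), (-1, rc)):
            sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
            frames[sign * (offset + 1)] = str(Seq(sub).translate())
    return frames


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
) -> tuple[float, tuple[int, int], tuple[int, int]] | None:
    """Best Smith-Waterman local alignment of two protein sequences.

    Returns ``(score, (query_start, query_end), (subject_start, subject_end))``
    or ``None`` when the optimal local score is 0 (no hit).
    """
    scheme = scheme or ScoringScheme()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    bad = (set(query) - _QUERY_ALPHABET) | (set(subject) - _SUBJECT_ALPHABET)
    if bad:
        raise ValueError(f"residues outside the protein alphabet: {sorted(bad)}")
    aligner = scheme.aligner("local")
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    qiv = (int(qblocks[0][0]), int(qblocks[-1][1]))
    siv = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return float(score), qiv, siv


def evalue(score: float, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*score)."""
    scheme = scheme or ScoringScheme()
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def _frame_to_forward(L: int, frame: int, start_nt: int, end_nt: int) -> tuple[int, int]:
    """Map a strand-local nucleotide interval to forward-strand coordinates."""
    if frame > 0:
        return start_nt, end_nt
    return L - end_nt, L - start_nt


def extract_orf(
    hit: LocalHit,
    genome: str,
    trim_to_start: bool = True,
) -> OpenReadingFrame:
    """Extract the stop-to-stop ORF containing a hit's aligned region.

    The in-frame segment around the hit is expanded to the nearest flanking
    stop codons (or sequence ends).  With ``trim_to_start`` the translated
    protein begins at the first in-frame ATG/GTG/TTG inside the ORF when one
    exists; otherwise (and for length bookkeeping) the stop boundary is used.
    An in-frame stop inside the aligned interval triggers a warning and the
    sub-segment with the larger overlap wins.
    """
    genome = _validate_nucleotides(genome)
    L = len(genome)
    strand_seq = genome if hit.frame > 0 else str(Seq(genome).reverse_complement())
    offset = abs(hit.frame) - 1
    sub = strand_seq[offset : offset + 3 * ((L - offset) // 3)]
    prot = str(Seq(sub).translate())
    a, b = hit.prot_start, hit.prot_end
    if not (0 <= a < b <= len(prot)):
        raise ValueError("hit protein interval outside the translated frame")

    inside = [i for i in range(a, b) if prot[i] == "*"]
    if inside:
        warnings.warn(
            f"in-frame stop inside aligned interval of {hit.query_id} vs "
            f"{hit.genome_id}; resolving to the larger sub-segment"
        )
        bounds = [a - 1] + inside + [b]
        segs = [
            (bounds[k] + 1, bounds[k + 1])
            for k in range(len(bounds) - 1)
            if bounds[k + 1] > bounds[k] + 1
        ]
        a, b = max(segs, key=lambda s: s[1] - s[0])

    lo = a
    while lo > 0 and prot[lo - 1] != "*":
        lo -= 1
    hi = b
    while hi < len(prot) and prot[hi] != "*":
        hi += 1

    cds_lo = lo
    if trim_to_start:
        for k in range(lo, hi):
            if sub[3 * k : 3 * k + 3] in START_CODONS:
                cds_lo = k
                break

    start, end = _frame_to_forward(L, hit.frame, offset + 3 * lo, offset + 3 * hi)
    cds_start, cds_end = _frame_to_forward(
        L, hit.frame, offset + 3 * cds_lo, offset + 3 * hi
    )
    return OpenReadingFrame(
        genome_id=hit.genome_id,
        strand="+" if hit.frame > 0 else "-",
        start=start,
        end=end,
        cds_start=cds_start,
        cds_end=cds_end,
        nt_seq=sub[3 * cds_lo : 3 * hi],
        protein=prot[cds_lo:hi],
    )


def survey(
    genomes: dict[str, str],
    queries: dict[str, str],
    cutoff: float = 0.01,
    scheme: ScoringScheme | None = None,
    species: dict[str, str] | None = None,
    trim_to_start: bool = True,
) -> pd.DataFrame:
    """Search every query against every genome and report significant ORFs.

    The E-value search space ``n`` is the total translated length across all
    six frames of the searched genome set, matching the per-search semantics
    of the expectation cutoff.  ORFs found via multiple queries or multiple
    hits are deduplicated by (genome, strand, stop-to-stop interval), keeping
    the lowest E-value.

    Returns a table with columns genome_id, species, start, end, cds_start,
    cds_end, strand, length_aa, best_query, evalue, protein (0-based
    half-open coordinates).
    """
    if not genomes or not queries:
        raise ValueError("need at least one genome and one query")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner("local")

    frames = {gid: six_frame_translate(seq) for gid, seq in genomes.items()}
    n_space = sum(len(p) for f in frames.values() for p in f.values())

    best: dict[tuple, dict] = {}
    for gid, genome in genomes.items():
        genome = genome.upper()
        L = len(genome)
        for frame, prot in frames[gid].items():
            if not prot:
                continue
            for qid, qseq in queries.items():
                score = aligner.score(qseq, prot)
                if score <= 0:
                    continue
                E = evalue(score, len(qseq), n_space, scheme)
                if E > cutoff:
                    continue
                aln = aligner.align(qseq, prot)[0]
                _, sblocks = aln.aligned
                ps, pe = int(sblocks[0][0]), int(sblocks[-1][1])
                offset = abs(frame) - 1
                nt = _frame_to_forward(L, frame, offset + 3 * ps, offset + 3 * pe)
                hit = LocalHit(qid, gid, frame, ps, pe, nt[0], nt[1], float(score), E)
                orf = extract_orf(hit, genome, trim_to_start=trim_to_start)
                key = (gid, orf.strand, orf.start, orf.end)
                if key not in best or E < best[key]["evalue"]:
                    best[key] = {
                        "genome_id": gid,
                        "species": (species or {}).get(gid, gid),
                        "start": orf.start,
                        "end": orf.end,
                        "cds_start": orf.cds_start,
                        "cds_end": orf.cds_end,
                        "strand": orf.strand,
                        "length_aa": len(orf.protein),
                        "best_query": qid,
                        "evalue": E,
                        "protein": orf.protein,
                    }

    columns = [
        "genome_id", "species", "start", "end", "cds_start", "cds_end",
        "strand", "length_aa", "best_query", "evalue", "protein",
    ]
    if not best:
        return pd.DataFrame(columns=columns)
    records = pd.DataFrame(sorted(best.values(), key=lambda r: (r["genome_id"], r["start"])))
    return records[columns]
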