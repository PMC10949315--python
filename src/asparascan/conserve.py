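"""Conservation profiling of protein families.

Representative selection by greedy identity clustering (CD-HIT style, 0.9
default threshold), a built-in center-star multiple aligner, per-column
Shannon conservation scores (log2 20 minus the column entropy in bits, so
~4.32 marks an invariant column and 0 a uniform one), a Levenshtein
median-string consensus, and a key-residue conservation report that maps
reference residue numbers (e.g. the catalytic Thr16/Tyr21/Thr87/Asp88/Lys158
of a short-chain asparaginase) onto alignment columns.

Gaps ('-') and 'X' are excluded from column frequencies; the alphabet size is
fixed at 20, so the maximal score is log2(20) even when X occurs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .search import AA20, ScoringScheme

__all__ = [
    "GAP",
    "MAX_SCORE",
    "Alignment",
    "ConservationProfile",
    "ConsensusResult",
    "levenshtein",
    "greedy_cluster",
    "center_star_align",
    "shannon_profile",
    "median_string",
    "key_residue_report",
    "read_alignment",
    "write_alignment",
]

GAP = "-"
MAX_SCORE = math.log2(20.0)


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("all alignment rows must have equal length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    def degapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace(GAP, "")


@dataclass
class ConservationProfile:
    """Per-column frequencies, entropy and Shannon score of an alignment.

    ``table`` columns: column, n_residues, gap_fraction, entropy_bits,
    shannon_score, modal_residue.  All-gap columns carry NaN scores and are
    flagged in ``all_gap_columns``.
    """

    table: pd.DataFrame
    frequencies: np.ndarray            # (ncol, 20) over AA20
    all_gap_columns: list[int] = field(default_factory=list)


@dataclass
class ConsensusResult:
    """A (near-)median string and its summed edit distance to the inputs."""

    consensus: str
    total_distance: int
    method: str                        # 'exact' | 'medoid+refinement'


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _identity_aligner() -> PairwiseAligner:
    aligner = ScoringScheme().aligner("global")
    return aligner


def _global_identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    """Fraction of identical aligned pairs over the shorter sequence length
    (the convention of common representative-selection tools)."""
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def greedy_cluster(
    sequences: list[tuple[str, str]],
    identity_threshold: float = 0.9,
) -> tuple[list[str], dict[str, str]]:
    """Greedy representative selection by decreasing length.

    Each sequence joins the first existing representative it matches at
    ``identity_threshold`` or better, else founds a new cluster.  Returns
    (representative ids, member id -> representative id).
    """
    if not sequences:
        raise ValueError("empty input")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = _identity_aligner()
    ordered = sorted(sequences, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []
    membership: dict[str, str] = {}
    for rid, seq in ordered:
        for rep_id, rep_seq in reps:
            if _global_identity(seq, rep_seq, aligner) >= identity_threshold:
                membership[rid] = rep_id
                break
        else:
            reps.append((rid, seq))
            membership[rid] = rid
    return [r for r, _ in reps], membership


def _merge_into_master(master: str, center_aln: str, other_aln: str
                       ) -> tuple[str, list[int], str]:
    """Merge a pairwise (center, other) alignment into the master center row.

    Returns the new master, the positions at which gaps were inserted into
    the old master (to be propagated to previously merged rows), and the
    other sequence re-gapped to the new master ("once a gap, always a gap").
    """
    i = j = 0
    new_master: list[str] = []
    new_other: list[str] = []
    insertions: list[int] = []
    while i < len(master) or j < len(center_aln):
        mc = master[i] if i < len(master) else None
        cc = center_aln[j] if j < len(center_aln) else None
        if mc == GAP and (cc != GAP or cc is None):
            new_master.append(GAP)
            new_other.append(GAP)
            i += 1
        elif cc == GAP and (mc != GAP or mc is None):
            insertions.append(i)
            new_master.append(GAP)
            new_other.append(other_aln[j])
            j += 1
        else:                          # both gap, or same residue of the center
            new_master.append(mc if mc is not None else GAP)
            new_other.append(other_aln[j] if cc is not None else GAP)
            i += 1
            j += 1
    return "".join(new_master), insertions, "".join(new_other)


def _apply_insertions(row: str, insertions: list[int]) -> str:
    out = list(row)
    for pos in reversed(insertions):
        out.insert(pos, GAP)
    return "".join(out)


def center_star_align(sequences: list[tuple[str, str]]) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence minimising total edit distance to the others;
    every other sequence is merged through its pairwise global alignment to
    the center under the "once a gap, always a gap" rule.  De-gapping any row
    reproduces its input sequence.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [i for i, _ in sequences]
    seqs = [s for _, s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    totals = [
        sum(levenshtein(a, b) for b in seqs) for a in seqs
    ]
    center_idx = min(range(len(seqs)), key=lambda k: (totals[k], ids[k]))
    center = seqs[center_idx]
    aligner = _identity_aligner()

    master = center
    merged_ids = [ids[center_idx]]
    merged_rows = [center]
    for k, (rid, seq) in enumerate(sequences):
        if k == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        center_aln, other_aln = str(aln[0]), str(aln[1])
        master, insertions, new_row = _merge_into_master(master, center_aln, other_aln)
        merged_rows = [_apply_insertions(r, insertions) for r in merged_rows]
        merged_ids.append(rid)
        merged_rows.append(new_row)
    order = [merged_ids.index(i) for i in ids]
    return Alignment([merged_ids[k] for k in order], [merged_rows[k] for k in order])


def shannon_profile(alignment: Alignment) -> ConservationProfile:
    """Per-column Shannon conservation scores.

    For each column, amino-acid frequencies p_a are computed over the 20
    standard residues with gaps (and X) excluded; H = -sum p_a log2 p_a and
    score = log2(20) - H.  Columns with no countable residue are flagged
    all-gap with an undefined (NaN) score.
    """
    ncol = alignment.ncol
    nrow = len(alignment.rows)
    aa_index = {a: i for i, a in enumerate(AA20)}
    freqs = np.zeros((ncol, 20))
    rows_out = []
    all_gap = []
    for c in range(ncol):
        column = [r[c] for r in alignment.rows]
        counts = np.zeros(20)
        for ch in column:
            if ch in aa_index:
                counts[aa_index[ch]] += 1
        n_res = int(counts.sum())
        gap_fraction = column.count(GAP) / nrow
        if n_res == 0:
            all_gap.append(c)
            rows_out.append({
                "column": c, "n_residues": 0, "gap_fraction": gap_fraction,
                "entropy_bits": np.nan, "shannon_score": np.nan,
                "modal_residue": None,
            })
            continue
        p = counts / n_res
        freqs[c] = p
        nz = p[p > 0]
        H = float(-(nz * np.log2(nz)).sum())
        rows_out.append({
            "column": c,
            "n_residues": n_res,
            "gap_fraction": gap_fraction,
            "entropy_bits": H,
            "shannon_score": MAX_SCORE - H,
            "modal_residue": AA20[int(np.argmax(counts))],
        })
    return ConservationProfile(pd.DataFrame(rows_out), freqs, all_gap)


def _total_distance(candidate: str, seqs: list[str]) -> int:
    return sum(levenshtein(candidate, s) for s in seqs)


def median_string(
    sequences: list[str],
    mode: str = "heuristic",
    max_candidates: int = 2_000_000,
) -> ConsensusResult:
    """String minimising (exactly or approximately) the summed edit distance.

    Exact mode enumerates every string over the observed alphabet with length
    between the shortest and longest input (a global minimiser exists in that
    range) and is rejected beyond ``max_candidates`` candidates.  Heuristic
    mode starts from the set medoid and hill-climbs over single-symbol
    substitutions, deletions and insertions until no single edit lowers the
    total distance; its result is never worse than the best input string.
    """
    if not sequences:
        raise ValueError("need at least 1 sequence")
    seqs = list(sequences)
    alphabet = sorted(set("".join(seqs))) or ["A"]
    lo, hi = min(map(len, seqs)), max(map(len, seqs))

    if mode == "exact":
        n_cand = sum(len(alphabet) ** L for L in range(lo, hi + 1))
        if n_cand > max_candidates:
            raise ValueError(
                f"exact search over {n_cand} candidates exceeds the limit "
                f"({max_candidates}); use mode='heuristic'"
            )
        best, best_total = None, math.inf
        for L in range(lo, hi + 1):
            for tup in itertools.product(alphabet, repeat=L):
                cand = "".join(tup)
                total = _total_distance(cand, seqs)
                if total < best_total:
                    best, best_total = cand, total
        return ConsensusResult(best, int(best_total), "exact")

    if mode != "heuristic":
        raise ValueError("mode must be 'exact' or 'heuristic'")

    totals = [_total_distance(s, seqs) for s in seqs]
    order = sorted(range(len(seqs)), key=lambda k: (totals[k], seqs[k]))
    current, current_total = seqs[order[0]], totals[order[0]]
    improved = True
    while improved:
        improved = False
        for cand in _single_edits(current, alphabet):
            total = _total_distance(cand, seqs)
            if total < current_total:
                current, current_total = cand, total
                improved = True
                break
    return ConsensusResult(current, int(current_total), "medoid+refinement")


def _single_edits(s: str, alphabet: list[str]):
    for i in range(len(s)):
        for a in alphabet:
            if a != s[i]:
                yield s[:i] + a + s[i + 1:]
    for i in range(len(s)):
        yield s[:i] + s[i + 1:]
    for i in range(len(s) + 1):
        for a in alphabet:
            yield s[:i] + a + s[i:]


def key_residue_report(
    alignment: Alignment,
    profile: ConservationProfile,
    reference_id: str,
    reference_positions: list[int],
) -> pd.DataFrame:
    """Conservation report for selected residues of a reference sequence.

    ``reference_positions`` use 1-based residue numbering of the ungapped
    reference row; each is mapped to its alignment column via the cumulative
    non-gap count.  For each position the Shannon score, modal residue, and
    the rows deviating from the modal residue (id, residue) are listed.
    """
    if reference_id not in alignment.ids:
        raise ValueError(f"reference id {reference_id!r} not in alignment")
    ref_row = alignment.rows[alignment.ids.index(reference_id)]
    ref_len = len(ref_row) - ref_row.count(GAP)
    pos_to_col = {}
    count = 0
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            count += 1
            pos_to_col[count] = col
    rows = []
    for pos in reference_positions:
        if not 1 <= pos <= ref_len:
            raise ValueError(
                f"position {pos} beyond reference length {ref_len}")
        col = pos_to_col[pos]
        prow = profile.table.iloc[col]
        modal = prow["modal_residue"]
        exceptions = [
            (rid, row[col])
            for rid, row in zip(alignment.ids, alignment.rows)
            if row[col] != modal
        ]
        rows.append({
            "position": pos,
            "ref_residue": ref_row[col],
            "column": col,
            "shannon_score": prow["shannon_score"],
            "modal_residue": modal,
            "n_exceptions": len(exceptions),
            "exceptions": exceptions,
        })
    return pd.DataFrame(rows)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment([r.id for r in records], [str(r.seq).upper() for r in records])


def write_alignment(alignment: Alignment, path) -> None:
    """Write an alignment as aligned FASTA."""
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")
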