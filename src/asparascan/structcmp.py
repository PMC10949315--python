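"""C-alpha superposition and rmsd reporting for structure comparison.

Reads protein chains from PDB/mmCIF files (via gemmi), extracts one Calpha
per residue (highest-occupancy altloc, first model), pairs residues between
two traces, and computes the least-squares optimal rigid superposition with
the Kabsch algorithm (SVD with reflection correction).  Same-protein chains
are paired by residue number; cross-protein comparisons are paired through a
sequence alignment, optionally with iterative outlier trimming.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "ChainTrace",
    "SuperpositionResult",
    "read_calpha",
    "pair_common_residues",
    "pair_by_alignment",
    "kabsch_superpose",
    "iterative_trim_superpose",
    "sequence_identity",
]


@dataclass
class ChainTrace:
    """Ordered Calpha trace of one chain: (residue number, name, coordinate)."""

    structure_id: str
    chain_id: str
    residues: list[tuple[int, str, np.ndarray]]

    def __post_init__(self) -> None:
        nums = [n for n, _, _ in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        for _, _, xyz in self.residues:
            if not np.all(np.isfinite(xyz)):
                raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def numbers(self) -> list[int]:
        return [n for n, _, _ in self.residues]

    @property
    def coords(self) -> np.ndarray:
        return np.array([xyz for _, _, xyz in self.residues])

    @property
    def sequence(self) -> str:
        """One-letter sequence of the traced residues ('X' for non-standard)."""
        out = []
        for _, name, _ in self.residues:
            info = gemmi.find_tabulated_residue(name)
            code = info.one_letter_code.upper() if info else "X"
            out.append(code if code.isalpha() else "X")
        return "".join(out)


@dataclass
class SuperpositionResult:
    """Optimal rigid transform of set B onto set A and the resulting rmsd."""

    rotation: np.ndarray       # 3x3 proper rotation
    translation: np.ndarray    # 3-vector; x' = R @ x + t
    rmsd: float                # Angstrom
    n_pairs: int
    residue_numbers: list[int] | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def read_calpha(path, chain_id: str) -> ChainTrace:
    """Read the Calpha trace of one chain from a PDB or mmCIF file.

    Keeps the highest-occupancy alternate location, uses the first model
    only, and skips residues without a Calpha atom.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read structure file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"no models in {path}")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [c.name for c in model]
        raise ValueError(
            f"chain {chain_id!r} not found in {path} (available: {available})")
    residues: list[tuple[int, str, np.ndarray]] = []
    seen: set[int] = set()
    for res in chain:
        cas = [a for a in res if a.name == "CA" and a.element != gemmi.Element("Ca")]
        if not cas:
            continue
        num = res.seqid.num
        if num in seen:
            continue
        seen.add(num)
        atom = max(cas, key=lambda a: a.occ)
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        residues.append((num, res.name, pos))
    residues.sort(key=lambda r: r[0])
    return ChainTrace(structure.name or str(path), chain_id, residues)


def pair_common_residues(
    a: ChainTrace, b: ChainTrace
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pair residues present in both traces by equal residue number."""
    coords_a = {n: xyz for n, _, xyz in a.residues}
    coords_b = {n: xyz for n, _, xyz in b.residues}
    common = sorted(set(coords_a) & set(coords_b))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} residue pairs in common; superposition "
            "underdetermined (need >= 3)")
    A = np.array([coords_a[n] for n in common])
    B = np.array([coords_b[n] for n in common])
    return A, B, common


def pair_by_alignment(
    a: ChainTrace, b: ChainTrace, aligned_a: str, aligned_b: str
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pair residues of two different proteins through a sequence alignment.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings whose
    de-gapped forms match the trace sequences; gap-free columns define the
    pairs.  Returned residue numbers are those of trace ``a``.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    if aligned_a.replace("-", "") != a.sequence or \
       aligned_b.replace("-", "") != b.sequence:
        raise ValueError("aligned strings do not match the trace sequences")
    ia = ib = 0
    idx_pairs = []
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            idx_pairs.append((ia, ib))
        ia += ca != "-"
        ib += cb != "-"
    if len(idx_pairs) < 3:
        raise ValueError("fewer than 3 aligned residue pairs")
    A = np.array([a.residues[i][2] for i, _ in idx_pairs])
    B = np.array([b.residues[j][2] for _, j in idx_pairs])
    nums = [a.residues[i][0] for i, _ in idx_pairs]
    return A, B, nums


def kabsch_superpose(
    A: np.ndarray,
    B: np.ndarray,
    residue_numbers: list[int] | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of point set B onto A.

    Kabsch algorithm: SVD of the cross-covariance of the centred sets, with
    the reflection corrected so the returned rotation is proper
    (determinant +1).  Degenerate (collinear) inputs are rejected.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    cent_a, cent_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - cent_a, B - cent_b
    H = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cent_a - R @ cent_b
    diff = Ac - Bc @ R.T
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(R, t, rmsd, n, residue_numbers)


def iterative_trim_superpose(
    A: np.ndarray,
    B: np.ndarray,
    residue_numbers: list[int] | None = None,
    max_cycles: int = 5,
    factor: float = 2.0,
) -> SuperpositionResult:
    """Superposition with iterative outlier trimming.

    After each superposition, pairs deviating by more than ``factor`` times
    the current rmsd are dropped and the fit repeated, for at most
    ``max_cycles`` cycles or until no pair is dropped (used for cross-protein
    comparisons where some aligned pairs are structurally non-equivalent).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    nums = list(residue_numbers) if residue_numbers is not None else None
    result = kabsch_superpose(A, B, nums)
    for _ in range(max_cycles):
        dev = np.linalg.norm(A - result.apply(B), axis=1)
        keep = dev <= factor * result.rmsd
        if keep.all() or keep.sum() < 3:
            break
        A, B = A[keep], B[keep]
        if nums is not None:
            nums = [n for n, k in zip(nums, keep) if k]
        result = kabsch_superpose(A, B, nums)
    return result


def sequence_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity of two aligned (equal-length, gapped) sequences.

    Denominator: aligned columns containing no gap in either row; numerator:
    identical such columns.  Fully gapped columns contribute to neither.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    pairs = [
        (x, y) for x, y in zip(aligned_a.upper(), aligned_b.upper())
        if x != "-" and y != "-"
    ]
    if not pairs:
        raise ValueError("no gap-free aligned columns")
    matches = sum(x == y for x, y in pairs)
    return 100.0 * matches / len(pairs)
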