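"""Family partition and similarity-graph clustering of surveyed asparaginases.

Surveyed proteins are split into long (typical class 1, 300-400 aa) and short
(scASNase, 160-180 aa) groups at a configurable cutoff, compared pairwise on
their N-terminal 150 residues (to avoid clustering by sequence length), laid
out with a force-directed embedding of the -log10 E-value similarity graph,
and clustered by thresholded connected components.  Localization classes
(cytoplasmic / SPI-secreted / SPII-lipoprotein) are attached from external
signal-peptide predictor labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .search import ScoringScheme, evalue, local_align

__all__ = [
    "SimilarityMatrix",
    "Embedding2D",
    "partition_by_length",
    "length_histogram",
    "truncate_n_terminal",
    "similarity_graph",
    "layout_2d",
    "cluster_graph",
    "protein_mass",
    "classify_localization",
    "read_label_table",
    "plot_embedding",
    "LOCALIZATIONS",
    "LABEL_DIALECT",
    "DEFAULT_CLUSTER_THRESHOLD",
]

LOCALIZATIONS = ("cytoplasmic", "SPI", "SPII")

# Default edge-significance threshold for cluster_graph, in -log10 E units.
# Chance local-alignment scores of unrelated 150-mers reach weights of ~5-7
# under the pairwise-search-space E-value, while homologous family members
# sit at weights of 60+; 10 (E <= 1e-10) separates the two regimes with a
# negligible graph-wide false-edge probability at desk scale.
DEFAULT_CLUSTER_THRESHOLD = 10.0

# Label dialect of common signal-peptide predictors -> localization class.
LABEL_DIALECT = {
    "OTHER": "cytoplasmic",
    "SP": "SPI",
    "LIPO": "SPII",
    "cytoplasmic": "cytoplasmic",
    "SPI": "SPI",
    "SPII": "SPII",
}


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity weights (capped -log10 E-values)."""

    ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("weights must be square over ids")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w


@dataclass
class Embedding2D:
    """Force-directed 2-D coordinates of the similarity graph."""

    ids: list[str]
    coords: np.ndarray            # (n, 2)
    iterations: int
    seed: int
    converged: bool = True


def partition_by_length(records: pd.DataFrame, cutoff: int = 250) -> pd.DataFrame:
    """Assign length_class: 'short' iff length < cutoff, else 'long'.

    The 250-residue default sits in the gap of the bimodal length
    distribution (160-180 vs 300-400 aa).  Returns a copy.
    """
    out = records.copy()
    if "length_aa" in out.columns:
        lengths = out["length_aa"].astype(int)
    else:
        lengths = out["protein"].str.len()
    if (lengths <= 0).any():
        raise ValueError("record lengths must be positive")
    out["length_class"] = np.where(lengths < cutoff, "short", "long")
    return out


def length_histogram(records: pd.DataFrame, bin_width: int = 10) -> pd.Series:
    """Histogram of protein lengths for bimodality inspection."""
    lengths = (records["length_aa"] if "length_aa" in records.columns
               else records["protein"].str.len()).astype(int)
    bins = (lengths // bin_width) * bin_width
    return bins.value_counts().sort_index()


def truncate_n_terminal(sequences, n: int = 150) -> list[str]:
    """First min(n, length) residues of each sequence; inputs untouched."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [s[:n] for s in sequences]


def similarity_graph(
    ids: list[str],
    sequences: list[str],
    scheme: ScoringScheme | None = None,
    cap: float = 200.0,
) -> SimilarityMatrix:
    """Pairwise similarity weights w(i,j) = min(cap, max(0, -log10 E(i,j))).

    E-values use the local alignment score of the (typically N-terminally
    truncated) sequence pair with m, n the two sequence lengths.
    """
    if len(ids) != len(sequences):
        raise ValueError("ids and sequences must have equal length")
    if len(ids) < 2:
        raise ValueError("need at least 2 records")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner("local")
    n = len(ids)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            score = aligner.score(sequences[i], sequences[j])
            if score <= 0:
                continue
            E = evalue(score, len(sequences[i]), len(sequences[j]), scheme)
            if E <= 0:
                w = cap
            else:
                w = min(cap, max(0.0, -math.log10(E)))
            W[i, j] = W[j, i] = w
    return SimilarityMatrix(list(ids), W)


def layout_2d(
    matrix: SimilarityMatrix,
    iterations: int = 1000,
    seed: int = 0,
    tol: float = 1e-4,
) -> Embedding2D:
    """Force-directed (CLANS-style) layout of the similarity graph.

    Attractive forces act along edges proportionally to their weight,
    uniform repulsion acts between all node pairs; positions start random in
    the unit square and cool linearly.  Deterministic given the seed.  If the
    maximal displacement never drops below ``tol`` the final coordinates are
    returned with ``converged=False`` rather than raising.
    """
    n = len(matrix.ids)
    rng = np.random.default_rng(seed)
    if n == 1:
        return Embedding2D(matrix.ids, np.zeros((1, 2)), 0, seed, True)
    pos = rng.random((n, 2))
    W = matrix.weights / max(matrix.weights.max(), 1e-12)
    k = 1.0 / math.sqrt(n)
    converged = False
    it = 0
    for it in range(1, iterations + 1):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        unit = delta / dist[..., None]
        rep = (k * k / dist)[..., None] * unit
        att = (W * dist / k)[..., None] * unit
        disp = rep.sum(axis=1) - att.sum(axis=1)
        step = np.linalg.norm(disp, axis=1)
        temp = 0.1 * (1.0 - it / iterations) + 1e-3
        scale = np.minimum(step, temp) / np.maximum(step, 1e-12)
        move = disp * scale[:, None]
        pos = pos + move
        if np.abs(move).max() < tol:
            converged = True
            break
    return Embedding2D(matrix.ids, pos - pos.mean(axis=0), it, seed, converged)


def cluster_graph(
    matrix: SimilarityMatrix,
    weight_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> dict[str, int]:
    """Connected-component cluster labels of the thresholded similarity graph.

    Edges with weight >= threshold are kept; components are labelled
    0..k-1 by decreasing size, ties by smallest member id, making the
    labelling invariant to record input order.
    """
    if weight_threshold < 0:
        raise ValueError("threshold must be non-negative")
    G = nx.Graph()
    G.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.weights[i, j] >= weight_threshold:
                G.add_edge(matrix.ids[i], matrix.ids[j])
    components = sorted(
        (sorted(c) for c in nx.connected_components(G)),
        key=lambda c: (-len(c), c[0]),
    )
    return {rid: label for label, comp in enumerate(components) for rid in comp}


def protein_mass(sequence: str, oligomer: int = 1) -> float:
    """Average molecular mass in kDa (residue masses plus one water).

    ``oligomer`` multiplies the protomer mass (non-covalent assembly:
    tetramer = 4 x monomer).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if oligomer < 1:
        raise ValueError("oligomer count must be >= 1")
    bad = set(sequence) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
    return oligomer * molecular_weight(sequence, seq_type="protein") / 1000.0


def read_label_table(path) -> pd.DataFrame:
    """Read a two-column (id, label) TSV of signal-peptide predictions.

    Malformed rows raise with their 1-based line number.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("id", "record_id"):
                continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed label row at line {lineno}: {line!r}")
            rows.append({"id": parts[0], "label": parts[1]})
    return pd.DataFrame(rows, columns=["id", "label"])


def classify_localization(
    records: pd.DataFrame,
    label_table: pd.DataFrame,
    id_column: str = "id",
    default: str = "cytoplasmic",
) -> pd.DataFrame:
    """Attach localization classes from a predictor label table.

    Labels follow the common predictor dialect (OTHER/SP/LIPO) or the class
    names themselves.  Records absent from the table get ``default`` --
    proteins without a predicted signal peptide are presumed cytoplasmic.
    Unknown label strings are rejected.
    """
    if default not in LOCALIZATIONS:
        raise ValueError(f"default must be one of {LOCALIZATIONS}")
    unknown = set(label_table["label"]) - set(LABEL_DIALECT)
    if unknown:
        raise ValueError(f"unknown localization label(s): {sorted(unknown)}")
    mapping = {
        rid: LABEL_DIALECT[lab]
        for rid, lab in zip(label_table["id"], label_table["label"])
    }
    out = records.copy()
    ids = out[id_column] if id_column in out.columns else out.index
    out["localization"] = [mapping.get(r, default) for r in ids]
    return out


def plot_embedding(embedding: Embedding2D, labels: dict[str, int] | None = None,
                   path=None):
    """Scatter plot of a 2-D embedding, optionally coloured by cluster label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    colors = ([labels.get(i, -1) for i in embedding.ids]
              if labels else None)
    ax.scatter(embedding.coords[:, 0], embedding.coords[:, 1],
               c=colors, cmap="tab10", s=12)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
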