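"""Translated search tests: frame translation, local alignment vs a
dynamic-programming oracle, E-value arithmetic, and ORF extraction checked
against planted truth and an independent stop-scanning oracle."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from asparascan import synthdata as sd
from asparascan.search import (
    LocalHit,
    ScoringScheme,
    evalue,
    extract_orf,
    local_align,
    six_frame_translate,
    survey,
)

SCHEME = ScoringScheme()


# -------------------------------------------------------- six_frame_translate

@pytest.mark.parametrize("genome, frame, expected", [
    ("ATGAAA", 1, "MK"),
    ("TTTCAT", -1, "MK"),          # reverse complement is ATGAAA
    ("ATGTAAATG", 1, "M*M"),       # internal stop retained
    ("ATGNAA", 1, "MX"),           # N-containing codon -> X
    ("ATGAAAC", 1, "MK"),          # trailing partial codon dropped
    ("ATGAAAC", 2, "*N"),          # frame +2 reads TGA AAC
])
def test_six_frame_translate_examples(genome, frame, expected):
    frames = six_frame_translate(genome)
    assert frames[frame] == expected


def test_six_frame_translate_rejects_non_nucleotides():
    with pytest.raises(ValueError, match="non-nucleotide"):
        six_frame_translate("ATGQ")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=60))
def test_six_frame_strand_symmetry(genome):
    """The six translations of a genome and of its reverse complement are
    the same multiset."""
    fwd = sorted(six_frame_translate(genome).values())
    rev = sorted(six_frame_translate(str(Seq(genome).reverse_complement())).values())
    assert fwd == rev


# ---------------------------------------------------------------- local_align

def _gotoh_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Independent affine-gap local alignment oracle (Gotoh recurrences)."""
    mat = scheme.substitution_matrix
    go = scheme.gap_open + scheme.gap_extend      # first gapped residue
    ge = scheme.gap_extend
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + go, Ix[i - 1][j] + ge)
            Iy[i][j] = max(M[i][j - 1] + go, Iy[i][j - 1] + ge)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + mat[a[i - 1], b[j - 1]])
            best = max(best, M[i][j])
    return best


def test_exact_match_score_is_blosum_diagonal_sum():
    score, qiv, siv = local_align("MKT", "MKT", SCHEME)
    assert score == 15.0                      # M:5 + K:5 + T:5
    assert qiv == (0, 3) and siv == (0, 3)


def test_all_mismatch_pair_reports_no_hit():
    assert local_align("AAA", "WWW", SCHEME) is None


def test_local_align_score_symmetry(rng):
    for _ in range(20):
        a = "".join(rng.choice(list(sd.AA20), 30))
        b = "".join(rng.choice(list(sd.AA20), 25))
        ra, rb = local_align(a, b, SCHEME), local_align(b, a, SCHEME)
        sa = ra[0] if ra else 0.0
        sb = rb[0] if rb else 0.0
        assert sa == sb


def test_local_align_matches_gotoh_oracle_on_random_pairs(rng):
    for _ in range(100):
        a = "".join(rng.choice(list("ARND"), rng.integers(1, 7)))
        b = "".join(rng.choice(list("ARND"), rng.integers(1, 7)))
        res = local_align(a, b, SCHEME)
        got = res[0] if res else 0.0
        assert got == _gotoh_local_score(a, b, SCHEME)


def test_local_align_rejects_bad_input():
    with pytest.raises(ValueError):
        local_align("", "MKT", SCHEME)
    with pytest.raises(ValueError, match="alphabet"):
        local_align("MKJ", "MKT", SCHEME)


# --------------------------------------------------------------------- evalue

def test_evalue_closed_form_inversion():
    m, n = 120, 50_000
    score = math.log(SCHEME.K * m * n) / SCHEME.lam
    assert evalue(score, m, n, SCHEME) == pytest.approx(1.0)


def test_evalue_linear_in_search_space():
    e1 = evalue(40.0, 100, 1000, SCHEME)
    e2 = evalue(40.0, 100, 2000, SCHEME)
    assert e2 == pytest.approx(2.0 * e1)


def test_evalue_arithmetic_example():
    # direct formula evaluation: 0.134 * 100 * 1e5 * exp(-0.3176 * 50)
    expected = 0.134 * 100 * 1e5 * math.exp(-0.3176 * 50)
    assert evalue(50.0, 100, 100_000, SCHEME) == pytest.approx(expected)


def test_evalue_monotone_decreasing_in_score():
    es = [evalue(s, 100, 1000, SCHEME) for s in range(0, 200, 10)]
    assert all(b < a for a, b in zip(es, es[1:]))


def test_evalue_rejects_empty_search_space():
    with pytest.raises(ValueError):
        evalue(10.0, 0, 100, SCHEME)


# ---------------------------------------------------------------- extract_orf

def _planted_setup(seed, sub_rate=0.0, strand="+"):
    members, anc = sd.make_family(172, 1, sub_rate, seed=seed)
    plans = [sd.GenomePlan("g", "sp", (sd.GenePlan(members[0], strand=strand),))]
    genomes, truth = sd.make_genomes(plans, seed=seed + 1)
    return genomes["g"], truth.iloc[0], anc


def test_orf_from_planted_gene_reproduces_truth_protein():
    genome, row, anc = _planted_setup(seed=21)
    records = survey({"g": genome}, {"q": anc})
    assert len(records) == 1
    rec = records.iloc[0]
    assert rec.protein == row.protein
    assert rec.length_aa == 172
    assert (rec.start, rec.end) == (row.start, row.end)


def test_orf_from_minus_strand_gene_reports_forward_coordinates():
    genome, row, anc = _planted_setup(seed=33, strand="-")
    records = survey({"g": genome}, {"q": anc})
    rec = records.iloc[0]
    assert rec.strand == "-"
    assert (rec.start, rec.end) == (row.start, row.end)
    assert rec.protein == row.protein


def test_orf_internal_stop_resolves_to_larger_segment():
    # codons: M  K  T  *  M  K  K  K
    genome = "ATGAAAACTTAAATGAAAAAGAAA"
    hit = LocalHit("q", "g", 1, 0, 8, 0, 24, 50.0, 1e-5)
    with pytest.warns(UserWarning, match="in-frame stop"):
        orf = extract_orf(hit, genome)
    assert orf.protein == "MKKK"
    assert (orf.start, orf.end) == (12, 24)


def test_orf_boundaries_match_independent_stop_scan(rng):
    """On random backgrounds, extract_orf must return exactly the segment
    between the in-frame stops flanking the hit (oracle: direct string scan
    of the translated frame)."""
    for _ in range(50):
        genome = "".join(rng.choice(list("ACGT"), 903))
        frame = int(rng.choice([1, 2, 3, -1, -2, -3]))
        offset = abs(frame) - 1
        strand_seq = (genome if frame > 0
                      else str(Seq(genome).reverse_complement()))
        usable = (len(genome) - offset) // 3
        prot = str(Seq(strand_seq[offset:offset + 3 * usable]).translate())
        # pick a random non-stop codon position as a one-residue "hit"
        non_stop = [i for i, c in enumerate(prot) if c != "*"]
        pos = int(rng.choice(non_stop))
        hit = LocalHit("q", "g", frame, pos, pos + 1, 0, 3, 10.0, 1e-3)
        orf = extract_orf(hit, genome, trim_to_start=False)
        # oracle: scan left and right for '*'
        left = prot.rfind("*", 0, pos) + 1
        right = prot.find("*", pos)
        right = right if right != -1 else len(prot)
        s_nt, e_nt = offset + 3 * left, offset + 3 * right
        if frame < 0:
            s_nt, e_nt = len(genome) - e_nt, len(genome) - s_nt
        assert (orf.start, orf.end) == (s_nt, e_nt)
        assert orf.protein == prot[left:right]


# --------------------------------------------------------------------- survey

def _ten_gene_setup(seed):
    ancestors, queries = {}, {}
    for k, (label, length) in enumerate(
            (("sc", 172), ("lc_typeI", 350), ("lc_typeII", 330))):
        _, anc = sd.make_family(length, 1, 0.0, seed=seed + 90 + k)
        ancestors[label] = anc
        queries[label] = anc
    rng = np.random.default_rng(seed)
    plans = []
    count = 0
    for g in range(4):
        genes = []
        while count < 10 and len(genes) < 3:
            label = ("sc", "lc_typeI", "lc_typeII")[count % 3]
            member = sd.make_family(
                len(ancestors[label]), 1, 0.1, seed=seed + 40 + count,
                ancestor=ancestors[label])[0][0]
            genes.append(sd.GenePlan(
                member, strand="+-"[count % 2], family=label))
            count += 1
        plans.append(sd.GenomePlan(f"g{g}", f"sp{g}", tuple(genes)))
    genomes, truth = sd.make_genomes(plans, seed=seed + 7)
    return genomes, queries, truth


def test_survey_recovers_exactly_the_planted_genes():
    genomes, queries, truth = _ten_gene_setup(seed=60)
    assert len(truth) == 10
    records = survey(genomes, queries, cutoff=0.01)
    got = set(map(tuple, records[["genome_id", "start", "end", "strand"]].values))
    want = set(map(tuple, truth[["genome_id", "start", "end", "strand"]].values))
    assert got == want


def test_survey_impossible_cutoff_returns_nothing():
    genomes, queries, _ = _ten_gene_setup(seed=61)
    assert len(survey(genomes, queries, cutoff=0.0)) == 0


def test_survey_deduplicates_across_queries():
    members, anc = sd.make_family(172, 2, 0.05, seed=70)
    plans = [sd.GenomePlan("g", "sp", (sd.GenePlan(anc),))]
    genomes, _ = sd.make_genomes(plans, seed=71)
    records = survey(genomes, {"q1": members[0], "q2": members[1]})
    assert len(records) == 1


def test_survey_strand_symmetry():
    """Surveying a genome and its reverse complement yields the same ORF
    protein set."""
    genomes, queries, _ = _ten_gene_setup(seed=62)
    rc = {g: str(Seq(s).reverse_complement()) for g, s in genomes.items()}
    p1 = sorted(survey(genomes, queries)["protein"])
    p2 = sorted(survey(rc, queries)["protein"])
    assert p1 == p2


def test_survey_rejects_empty_inputs():
    with pytest.raises(ValueError):
        survey({}, {"q": "MKT"})
    with pytest.raises(ValueError):
        survey({"g": "ATG"}, {})
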