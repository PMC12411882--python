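import subprocess
import textwrap
from itertools import combinations

import numpy as np
import pytest

from ratiotax import (
    LocusAlignment,
    collapse_haplotypes,
    concatenate,
    deletion_mask,
    k2p_distance,
    k2p_matrix,
    group_summary,
    read_alignment,
    trim_alignment,
    write_alignment,
)


def aln(locus, mapping):
    ids = list(mapping)
    return LocusAlignment(locus, ids, [mapping[i] for i in ids])


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

def test_fasta_roundtrip_uppercases(tmp_path):
    path = tmp_path / "in.fasta"
    path.write_text(">s1\nacgtacgtac\n>s2\nACGTACGTAC\n")
    a = read_alignment(path, "COI")
    assert a.length == 10 and a.n_sequences == 2
    assert a["s1"] == "ACGTACGTAC"
    # the two sequences collapse to one haplotype despite case difference
    assert collapse_haplotypes(a).n_haplotypes == 1
    out = tmp_path / "out.fasta"
    write_alignment(a, out)
    assert read_alignment(out, "COI").seqs == a.seqs


def test_ragged_and_duplicate_and_alphabet_errors(tmp_path):
    with pytest.raises(ValueError, match="ragged"):
        aln("COI", {"s1": "ACGTACGTAC", "s2": "ACGTACGTA"})
    with pytest.raises(ValueError, match="duplicate"):
        LocusAlignment("COI", ["s1", "s1"], ["ACGT", "ACGT"])
    with pytest.raises(ValueError, match="alphabet"):
        aln("COI", {"s1": "ACXT"})
    path = tmp_path / "empty.fasta"
    path.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        read_alignment(path, "COI")


def test_trim_half_open_semantics():
    a = aln("COI", {"s1": "A" * 700, "s2": "C" * 700})
    assert trim_alignment(a, 40, 655).length == 615
    assert trim_alignment(a, 0, 700).seqs == a.seqs
    with pytest.raises(ValueError):
        trim_alignment(a, 5, 5)
    with pytest.raises(ValueError):
        trim_alignment(a, -1, 10)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def test_collapse_counts_and_first_occurrence_labels():
    a = aln("COI", {"s1": "ACGT", "s2": "ACGT", "s3": "ACGA"})
    h = collapse_haplotypes(a)
    assert h.n_haplotypes == 2
    assert h.assignments == {"s1": "COI 1", "s2": "COI 1", "s3": "COI 2"}
    assert h.counts == {"COI 1": 2, "COI 2": 1}


def test_collapse_population_pattern():
    # six specimens with haplotype pattern (1, 1, 2, 3, 3, 3) -> 3 classes
    seqs = {
        "Ben1": "AAAA", "Ben2": "AAAA", "Ben3": "AACA",
        "Ben4": "AAAT", "Ben5": "AAAT", "Ben6": "AAAT",
    }
    h = collapse_haplotypes(aln("COI", seqs))
    assert h.n_haplotypes == 3
    assert [h.assignments[f"Ben{i}"] for i in range(1, 7)] == [
        "COI 1", "COI 1", "COI 2", "COI 3", "COI 3", "COI 3",
    ]


def test_n_and_gap_are_ordinary_characters_for_identity():
    a = aln("COI", {"s1": "ACNT", "s2": "ACAT", "s3": "AC-T"})
    assert collapse_haplotypes(a).n_haplotypes == 3


def test_collapse_is_a_partition_and_idempotent(rng):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, size=20)]) for _ in range(12)]
    seqs = [seqs[rng.integers(0, 12)] for _ in range(12)]  # force duplicates
    a = LocusAlignment("16S", [f"s{i}" for i in range(12)], seqs)
    h = collapse_haplotypes(a)
    assert set(h.assignments) == set(a.ids)                  # covers all
    assert sum(h.counts.values()) == a.n_sequences           # disjoint classes
    again = collapse_haplotypes(h.representatives())
    assert again.n_haplotypes == h.n_haplotypes              # identity on reps


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def _three_loci():
    coi = aln("COI", {"x": "AAAA", "y": "AAAA", "z": "CCCC"})
    s16 = aln("16S", {"x": "GGG", "y": "GGG", "z": "GGG"})
    its = aln("ITS2", {"x": "TT", "y": "TA", "z": "TT"})
    return coi, s16, its


def test_concatenation_scheme_and_length_additivity():
    coi, s16, its = _three_loci()
    ledger, cat = concatenate([coi, s16, its])
    assert ledger.total_length == cat.length == 9
    assert ledger.scheme == [
        ("COI", 4, (0, 4)), ("16S", 3, (4, 7)), ("ITS2", 2, (7, 9)),
    ]
    assert cat["x"] == "AAAAGGGTT"


def test_concatenated_partition_refines_per_locus_partitions():
    coi, s16, its = _three_loci()
    two, _ = concatenate([coi, s16])
    three, _ = concatenate([coi, s16, its])
    rows2 = two.rows.set_index("specimen_id")
    rows3 = three.rows.set_index("specimen_id")
    # x and y share COI+16S but differ in ITS2: same 2-locus label,
    # different 3-locus labels
    assert (
        rows2.loc["x", "concatenated_haplotype"]
        == rows2.loc["y", "concatenated_haplotype"]
    )
    assert (
        rows3.loc["x", "concatenated_haplotype"]
        != rows3.loc["y", "concatenated_haplotype"]
    )
    # refinement: equal 3-locus labels imply equal 2-locus labels
    for a in rows3.index:
        for b in rows3.index:
            if rows3.loc[a, "concatenated_haplotype"] == rows3.loc[b, "concatenated_haplotype"]:
                assert (
                    rows2.loc[a, "concatenated_haplotype"]
                    == rows2.loc[b, "concatenated_haplotype"]
                )


def test_concatenation_missing_specimen_policy():
    coi = aln("COI", {"x": "AAAA", "y": "AAAA"})
    s16 = aln("16S", {"x": "GGG"})
    with pytest.warns(UserWarning, match="excluding 1 specimen"):
        ledger, cat = concatenate([coi, s16])
    assert cat.ids == ["x"]
    with pytest.raises(ValueError, match="missing"):
        concatenate([coi, s16], strict=True)


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

def test_k2p_identity_and_hand_value():
    s = "ACGT" * 10
    c = k2p_distance(s, s)
    assert c.P == c.Q == 0.0 and c.d == 0.0
    # length 10, one transition (A->G) and one transversion (C->A):
    # P = Q = 0.1, d = -1/2 ln(0.7 * sqrt(0.8)) = 0.2341
    s1 = "AAAAACCCCC"
    s2 = "GAAAAACCCC"
    c = k2p_distance(s1, s2)
    assert (c.P, c.Q) == (0.1, 0.1)
    assert c.d == pytest.approx(0.2341, abs=1e-4)
    assert c.pct == pytest.approx(23.41, abs=1e-2)


def test_k2p_saturation_sentinel():
    # P = 0.3, Q = 0.4 on length 10: 1 - 2P - Q = 0
    s1 = "AAAAAAAAAA"
    s2 = "GGG" + "CCCC" + "AAA"
    c = k2p_distance(s1, s2)
    assert (c.P, c.Q) == (0.3, 0.4)
    assert c.saturated and np.isnan(c.d)


def test_k2p_symmetry_mask_and_errors(rng):
    bases = np.array(list("ACGT"))
    anc = bases[rng.integers(0, 4, 50)]
    mut = anc.copy()
    hit = rng.random(50) < 0.15
    mut[hit] = bases[rng.integers(0, 4, int(hit.sum()))]
    a, b = "".join(anc), "".join(mut)
    assert k2p_distance(a, b).d == k2p_distance(b, a).d
    mask = np.zeros(50, dtype=bool)
    mask[:10] = True
    assert k2p_distance(a, b, mask).n_sites == 10
    with pytest.raises(ValueError, match="equal length"):
        k2p_distance("ACGT", "ACG")
    with pytest.raises(ValueError, match="no comparable sites"):
        k2p_distance("NNNN", "ACGT")


def test_k2p_monotone_in_p_and_q():
    def d(P, Q):
        return -0.5 * np.log((1 - 2 * P - Q) * np.sqrt(1 - 2 * Q))

    grid = np.linspace(0.0, 0.15, 8)
    for q in grid:
        vals = [d(p, q) for p in grid]
        assert np.all(np.diff(vals) > 0)
    for p in grid:
        vals = [d(p, q) for q in grid]
        assert np.all(np.diff(vals) > 0)


def test_deletion_mask_complete_vs_pairwise():
    a = aln("COI", {"s1": "ACGTA", "s2": "ACG-A", "s3": "ACGTA"})
    complete = deletion_mask(a, "complete")
    assert list(complete) == [True, True, True, False, True]
    valid = deletion_mask(a, "pairwise")
    assert list(valid[0] & valid[2]) == [True] * 5       # pair without the gap
    assert list(valid[0] & valid[1]) == list(complete)   # pair with the gap
    with pytest.raises(ValueError, match="unknown deletion"):
        deletion_mask(a, "nope")


def test_distance_matrix_permutation_equivariance(rng):
    bases = np.array(list("ACGT"))
    ids = [f"s{i}" for i in range(5)]
    seqs = ["".join(bases[rng.integers(0, 4, 40)]) for _ in ids]
    a = LocusAlignment("COI", ids, seqs)
    perm = [3, 1, 4, 0, 2]
    b = LocusAlignment("COI", [ids[i] for i in perm], [seqs[i] for i in perm])
    m1 = k2p_matrix(a)
    m2 = k2p_matrix(b)
    assert np.allclose(m1.loc[b.ids, b.ids].to_numpy(), m2.to_numpy(), equal_nan=True)


def test_k2p_agrees_with_r_ape(tmp_path, rng):
    """Independent oracle: ape::dist.dna(model='K80') on a random alignment."""
    bases = np.array(list("ACGT"))
    ids = [f"s{i}" for i in range(6)]
    seqs = []
    anc = bases[rng.integers(0, 4, 120)]
    for _ in ids:
        s = anc.copy()
        hit = rng.random(120) < 0.08
        s[hit] = bases[rng.integers(0, 4, int(hit.sum()))]
        seqs.append("".join(s))
    a = LocusAlignment("COI", ids, seqs)
    fas = tmp_path / "a.fasta"
    write_alignment(a, fas)
    script = tmp_path / "k2p.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(ape))
            a <- read.dna("{fas}", format = "fasta")
            d <- dist.dna(a, model = "K80", pairwise.deletion = TRUE)
            write.csv(as.matrix(d), "{tmp_path}/d.csv")
            """
        )
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    import pandas as pd

    ref = pd.read_csv(tmp_path / "d.csv", index_col=0)
    ours = k2p_matrix(a, deletion="pairwise")
    assert np.allclose(ours.to_numpy(), ref.to_numpy(), atol=1e-9)


def test_group_summary_shapes_and_degenerate_rows():
    a = aln(
        "COI",
        {
            "a1": "AAAAAAAAAA", "a2": "AAAAAAAAAA",
            "b1": "GGAAAAAAAA", "b2": "GGAAAAAAAC",
            "lone": "CAAAAAAAAA",
        },
    )
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "lone": "C"}
    out = group_summary(a, groups)
    within = out[out.kind == "within"].set_index("group_1")
    assert "C" not in within.index  # singleton group omitted
    assert within.loc["A", ["min", "max", "mean"]].tolist() == [0.0, 0.0, 0.0]
    assert (out["min"] <= out["mean"]).all() and (out["mean"] <= out["max"]).all()
    between = out[out.kind == "between"]
    assert len(between) == 3
    with pytest.raises(ValueError, match="without a group"):
        group_summary(a, {"a1": "A"})
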