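"""Multilocus sequence workflow: haplotypes, concatenation and K2P distances.

Covers the molecular side of an integrative-taxonomy study: ingest
pre-aligned per-locus FASTA files, trim alignment ends, collapse
identical sequences to haplotypes, concatenate loci with a bookkeeping
ledger, and summarise pairwise Kimura two-parameter (K2P) distances
within and between groups of specimens.

The K2P distance distinguishes transitions (A<->G, C<->T; proportion P)
from transversions (proportion Q) among compared sites:

.. math:: d = -\\tfrac12 \\ln\\bigl((1 - 2P - Q)\\sqrt{1 - 2Q}\\bigr)

Sites are compared only where both sequences have an unambiguous base;
under the default *complete deletion* policy every column containing a
gap or ``N`` in any sequence is removed before any pair is compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusAlignment",
    "HaplotypeTable",
    "ConcatenationLedger",
    "K2pComponents",
    "read_alignment",
    "write_alignment",
    "trim_alignment",
    "collapse_haplotypes",
    "concatenate",
    "deletion_mask",
    "k2p_distance",
    "k2p_matrix",
    "group_summary",
    "read_population_map",
]

DEFAULT_ALPHABET = frozenset("ACGTN-")
_BASES = frozenset("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class LocusAlignment:
    """Equal-length aligned sequences over ``{A, C, G, T, N, -}`` at one locus."""

    locus: str
    ids: list[str]
    seqs: list[str]
    alphabet: frozenset = DEFAULT_ALPHABET

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.seqs = [s.upper() for s in self.seqs]
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dup = next(i for i in self.ids if self.ids.count(i) > 1)
            raise ValueError(f"duplicate specimen id {dup!r}")
        if self.seqs:
            lengths = {len(s) for s in self.seqs}
            if len(lengths) > 1:
                raise ValueError(
                    f"ragged alignment: sequence lengths {sorted(lengths)}"
                )
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - self.alphabet
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains symbols outside the alphabet: "
                    f"{sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    def __getitem__(self, specimen_id: str) -> str:
        try:
            return self.seqs[self.ids.index(specimen_id)]
        except ValueError:
            raise KeyError(specimen_id) from None

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self.ids

    def subset(self, specimen_ids) -> "LocusAlignment":
        return LocusAlignment(
            self.locus,
            list(specimen_ids),
            [self[i] for i in specimen_ids],
            self.alphabet,
        )


def read_alignment(path, locus: str, alphabet=DEFAULT_ALPHABET) -> LocusAlignment:
    """Read an aligned FASTA file; sequences are uppercased and validated."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return LocusAlignment(locus, ids, seqs, frozenset(alphabet))


def write_alignment(aln: LocusAlignment, path) -> None:
    """Write FASTA wrapped at 70 columns."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def trim_alignment(aln: LocusAlignment, start: int, end: int) -> LocusAlignment:
    """Column slice ``[start, end)`` (0-based half-open)."""
    if not 0 <= start < end <= aln.length:
        raise ValueError(
            f"invalid trim interval [{start}, {end}) for alignment of "
            f"length {aln.length}"
        )
    return LocusAlignment(
        aln.locus, list(aln.ids), [s[start:end] for s in aln.seqs], aln.alphabet
    )


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Specimens collapsed to exact-identity haplotype classes.

    Labels are ``"<locus> <k>"`` numbered by first occurrence in input
    order.  Gaps and ``N`` count as ordinary characters: two sequences
    differing only at an ``N``-bearing column are distinct haplotypes.
    """

    locus: str
    sequences: dict[str, str]        # label -> canonical sequence
    assignments: dict[str, str]      # specimen_id -> label
    counts: dict[str, int] = field(init=False)

    def __post_init__(self):
        counts: dict[str, int] = {}
        for lab in self.assignments.values():
            counts[lab] = counts.get(lab, 0) + 1
        self.counts = counts

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def representatives(self) -> LocusAlignment:
        """One sequence per haplotype, in label order."""
        labels = list(self.sequences)
        return LocusAlignment(self.locus, labels, [self.sequences[l] for l in labels])


def collapse_haplotypes(aln: LocusAlignment) -> HaplotypeTable:
    """Group identical sequences (exact string match) into haplotypes."""
    if aln.n_sequences == 0:
        raise ValueError("cannot collapse an empty alignment")
    seq_to_label: dict[str, str] = {}
    sequences: dict[str, str] = {}
    assignments: dict[str, str] = {}
    for sid, s in zip(aln.ids, aln.seqs):
        if s not in seq_to_label:
            label = f"{aln.locus} {len(seq_to_label) + 1}"
            seq_to_label[s] = label
            sequences[label] = s
        assignments[sid] = seq_to_label[s]
    return HaplotypeTable(aln.locus, sequences, assignments)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

@dataclass
class ConcatenationLedger:
    """Bookkeeping for a multilocus concatenation.

    ``scheme`` lists ``(locus, length, (start, end))`` with 0-based
    half-open column intervals in the concatenated alignment; ``rows``
    maps each specimen to its per-locus haplotype labels and its
    concatenated haplotype label.  Two specimens share a concatenated
    label iff they share every per-locus label, so the concatenated
    partition refines each single-locus partition.
    """

    name: str
    scheme: list[tuple[str, int, tuple[int, int]]]
    rows: pd.DataFrame

    @property
    def total_length(self) -> int:
        return sum(length for _, length, _ in self.scheme)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def concatenate(
    loci: list[LocusAlignment],
    specimens: list[str] | None = None,
    strict: bool = False,
    name: str | None = None,
) -> tuple[ConcatenationLedger, LocusAlignment]:
    """Concatenate loci in the given order, tracking haplotype composition.

    Specimens missing from any locus are excluded with a warning
    (default) or rejected (``strict=True``).
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    if name is None:
        name = "+".join(a.locus for a in loci)
    if specimens is None:
        specimens = list(loci[0].ids)
    missing = [s for s in specimens if any(s not in a for a in loci)]
    if missing:
        if strict:
            raise ValueError(f"specimens missing from some locus: {missing}")
        warnings.warn(
            f"excluding {len(missing)} specimen(s) missing from at least one "
            f"locus: {missing}",
            stacklevel=2,
        )
    kept = [s for s in specimens if s not in set(missing)]
    if not kept:
        raise ValueError("no specimen is present in every locus")

    scheme = []
    offset = 0
    for a in loci:
        scheme.append((a.locus, a.length, (offset, offset + a.length)))
        offset += a.length

    per_locus = [collapse_haplotypes(a.subset(kept)) for a in loci]
    tuple_to_label: dict[tuple[str, ...], str] = {}
    records = []
    cat_ids, cat_seqs = [], []
    for s in kept:
        tup = tuple(h.assignments[s] for h in per_locus)
        if tup not in tuple_to_label:
            tuple_to_label[tup] = f"{name} {len(tuple_to_label) + 1}"
        rec = {"specimen_id": s, "concatenated_haplotype": tuple_to_label[tup]}
        rec.update({f"{a.locus}_haplotype": lab for a, lab in zip(loci, tup)})
        records.append(rec)
        cat_ids.append(s)
        cat_seqs.append("".join(a[s] for a in loci))

    ledger = ConcatenationLedger(name, scheme, pd.DataFrame(records))
    return ledger, LocusAlignment(name, cat_ids, cat_seqs)


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

@dataclass
class K2pComponents:
    """Transition/transversion proportions and the derived K2P distance.

    ``d`` is NaN and ``saturated`` is True when the distance is undefined
    (``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``).
    """

    P: float
    Q: float
    n_sites: int
    d: float
    saturated: bool = False

    @property
    def pct(self) -> float:
        return 100.0 * self.d


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


_A, _C, _G, _T = (np.bytes_(b) for b in (b"A", b"C", b"G", b"T"))


def k2p_distance(seq1: str, seq2: str, mask: np.ndarray | None = None) -> K2pComponents:
    """Kimura two-parameter distance between two equal-length sequences.

    Only columns where both characters are in ``{A, C, G, T}`` (and, if
    given, where ``mask`` is True) are compared.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    a = _encode(seq1.upper())
    b = _encode(seq2.upper())
    valid = np.isin(a, (_A, _C, _G, _T)) & np.isin(b, (_A, _C, _G, _T))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != a.size:
            raise ValueError("mask length mismatch")
        valid &= mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites; K2P distance undefined")
    av, bv = a[valid], b[valid]
    diff = av != bv
    purine_a = (av == _A) | (av == _G)
    purine_b = (bv == _A) | (bv == _G)
    transitions = int((diff & (purine_a == purine_b)).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2pComponents(P, Q, n, float("nan"), saturated=True)
    d = -0.5 * np.log(w1 * np.sqrt(w2))
    return K2pComponents(P, Q, n, float(d))


def deletion_mask(aln: LocusAlignment, policy: str = "complete") -> np.ndarray:
    """Columns retained under a deletion policy.

    ``complete``: one boolean vector, True where *no* sequence has a gap,
    ``N`` or other ambiguity.  ``pairwise``: an ``(n_sequences, length)``
    boolean matrix of per-sequence validity; the mask for a pair is the
    AND of its two rows.
    """
    arr = np.array([_encode(s) for s in aln.seqs])
    valid = np.isin(arr, (_A, _C, _G, _T))
    if policy == "complete":
        return valid.all(axis=0)
    if policy == "pairwise":
        return valid
    raise ValueError(f"unknown deletion policy {policy!r}")


def k2p_matrix(aln: LocusAlignment, deletion: str = "complete") -> pd.DataFrame:
    """Symmetric matrix of pairwise K2P distances (substitutions/site).

    Saturated pairs get NaN entries.
    """
    if deletion == "complete":
        mask = deletion_mask(aln, "complete")
        masks = {(i, j): mask for i, j in combinations(range(aln.n_sequences), 2)}
    elif deletion == "pairwise":
        valid = deletion_mask(aln, "pairwise")
        masks = {
            (i, j): valid[i] & valid[j]
            for i, j in combinations(range(aln.n_sequences), 2)
        }
    else:
        raise ValueError(f"unknown deletion policy {deletion!r}")
    n = aln.n_sequences
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        comp = k2p_distance(aln.seqs[i], aln.seqs[j], masks[(i, j)])
        mat[i, j] = mat[j, i] = comp.d
    return pd.DataFrame(mat, index=aln.ids, columns=aln.ids)


def read_population_map(path) -> pd.DataFrame:
    """Read a ``specimen_id<TAB>population<TAB>species_group`` TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "specimen_id" not in frame.columns:
        raise ValueError("population map must have a 'specimen_id' column")
    return frame


def group_summary(
    aln: LocusAlignment,
    population_map,
    deletion: str = "complete",
) -> pd.DataFrame:
    """Within- and between-group min/max/mean pairwise K2P distances (%).

    ``population_map`` maps specimen_id -> group name (a dict or Series).
    Saturated pairs are excluded from the summaries and counted in
    ``n_saturated``; within-group rows need >= 2 members (otherwise the
    row is omitted).  Percentages are full precision; round at the
    reporting layer.
    """
    groups = dict(population_map)
    unassigned = [s for s in aln.ids if s not in groups]
    if unassigned:
        raise ValueError(f"specimens without a group assignment: {unassigned}")
    dmat = k2p_matrix(aln, deletion=deletion)
    by_group: dict[str, list[str]] = {}
    for s in aln.ids:
        by_group.setdefault(groups[s], []).append(s)
    names = list(by_group)

    def summarise(pairs):
        vals = np.array([dmat.at[x, y] for x, y in pairs]) * 100.0
        sat = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return None, sat
        return (float(vals.min()), float(vals.max()), float(vals.mean())), sat

    rows = []
    for g in names:
        members = by_group[g]
        if len(members) < 2:
            continue
        stats_, sat = summarise(list(combinations(members, 2)))
        if stats_ is None:
            continue
        mn, mx, mean = stats_
        rows.append(
            {
                "comparison": f"Within {g}",
                "kind": "within",
                "group_1": g,
                "group_2": g,
                "n_pairs": len(members) * (len(members) - 1) // 2,
                "min": mn,
                "max": mx,
                "mean": mean,
                "n_saturated": sat,
            }
        )
    for g1, g2 in combinations(names, 2):
        pairs = [(x, y) for x in by_group[g1] for y in by_group[g2]]
        stats_, sat = summarise(pairs)
        if stats_ is None:
            continue
        mn, mx, mean = stats_
        rows.append(
            {
                "comparison": f"Between {g1} and {g2}",
                "kind": "between",
                "group_1": g1,
                "group_2": g2,
                "n_pairs": len(pairs),
                "min": mn,
                "max": mx,
                "mean": mean,
                "n_saturated": sat,
            }
        )
    return pd.DataFrame(rows)
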