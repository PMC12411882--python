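"""Accession/haplotype ledgers for multilocus sequencing studies.

An :class:`AccessionLedger` records, per specimen, the population, the
species group, and for each locus the haplotype label and database
accession of any newly deposited sequence.  ``stats()`` recovers the
per-locus bookkeeping a study reports: how many sequences were deposited
(cross-checked by accession-range arithmetic) and how many distinct
haplotypes they collapse to.

A transcription of the study ledger for three loci (COI, 16S, ITS2 with
flanking rDNA) ships with the package as ``data/table1_ledger.tsv``; it
is test/reference data, not a runtime dependency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["AccessionLedger", "accession_range_count", "LOCI"]

#: Loci covered by the packaged ledger, mapped to their column prefixes.
LOCI: dict[str, str] = {"COI": "coi", "16S": "s16", "ITS2": "its2"}

_ACCESSION_RE = re.compile(r"^([A-Z]+)(\d+)$")


def _parse_accession(acc: str) -> tuple[str, int, int]:
    m = _ACCESSION_RE.match(acc.strip())
    if not m:
        raise ValueError(f"malformed accession {acc!r}")
    return m.group(1), int(m.group(2)), len(m.group(2))


def accession_range_count(first: str, last: str) -> int:
    """Number of accessions in an inclusive dense range, e.g. PP947873-PP947923 -> 51."""
    p1, n1, w1 = _parse_accession(first)
    p2, n2, w2 = _parse_accession(last)
    if p1 != p2 or w1 != w2:
        raise ValueError(f"accession range endpoints disagree: {first!r}..{last!r}")
    if n2 < n1:
        raise ValueError(f"accession range runs backwards: {first!r}..{last!r}")
    return n2 - n1 + 1


@dataclass
class AccessionLedger:
    """Per-specimen ledger of populations, haplotype labels and accessions."""

    frame: pd.DataFrame

    REQUIRED = ("specimen_id", "population", "species_group")

    def __post_init__(self):
        for c in self.REQUIRED:
            if c not in self.frame.columns:
                raise ValueError(f"ledger is missing required column {c!r}")
        accession_cols = [c for c in self.frame.columns if c.endswith("_accession")]
        accs = (
            self.frame[accession_cols].stack().dropna().astype(str).str.strip()
        )
        accs = accs[accs != ""]
        if not accs.is_unique:
            dup = accs[accs.duplicated()].iloc[0]
            raise ValueError(f"duplicate accession {dup!r} in ledger")

    @classmethod
    def from_tsv(cls, path) -> "AccessionLedger":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def packaged(cls) -> "AccessionLedger":
        """The ledger transcription shipped with the package."""
        ref = resources.files("ratiotax") / "data" / "table1_ledger.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def stats(self) -> pd.DataFrame:
        """Per-locus sequence and haplotype counts.

        ``n_sequences`` counts rows carrying a (new) haplotype label for
        the locus; ``range_count`` is the inclusive span of the lowest
        and highest accession among those rows, which equals
        ``n_sequences`` when the deposited accessions form a dense run.
        """
        rows = []
        for locus, prefix in LOCI.items():
            hap_col = f"{prefix}_haplotype"
            acc_col = f"{prefix}_accession"
            if hap_col not in self.frame.columns:
                continue
            haps = self.frame[hap_col].dropna().astype(str).str.strip()
            haps = haps[haps != ""]
            mask = self.frame[hap_col].notna() & (
                self.frame[hap_col].astype(str).str.strip() != ""
            )
            accs = (
                self.frame.loc[mask, acc_col].dropna().astype(str).str.strip()
                if acc_col in self.frame.columns
                else pd.Series(dtype=str)
            )
            accs = accs[accs != ""]
            if len(accs):
                keyed = sorted(accs, key=lambda a: _parse_accession(a)[1])
                first, last = keyed[0], keyed[-1]
                range_count = accession_range_count(first, last)
            else:
                first = last = None
                range_count = 0
            rows.append(
                {
                    "locus": locus,
                    "n_sequences": int(len(haps)),
                    "n_haplotypes": int(haps.nunique()),
                    "accession_first": first,
                    "accession_last": last,
                    "range_count": range_count,
                    "dense": range_count == len(accs),
                }
            )
        columns = [
            "locus", "n_sequences", "n_haplotypes", "accession_first",
            "accession_last", "range_count", "dense",
        ]
        return pd.DataFrame(rows, columns=columns).set_index("locus")
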