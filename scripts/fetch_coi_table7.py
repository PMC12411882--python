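#!/usr/bin/env python
"""Download, align and cache the deposited COI dataset (network required).

Fetches the 50 COI sequences behind the study's distance analysis from
NCBI (25 newly deposited haplotypes plus the comparative GenBank
sequences and the outgroup), aligns them with mafft, and caches

    data/external/coi_table7.fasta
    data/external/coi_table7_groups.tsv

which `tests/test_acceptance.py::test_table7_regimes_on_deposited_coi`
consumes.  Runs in minutes; everything here is an optional convenience
separated from the tested core, which never touches the network.
"""

from __future__ import annotations

import subprocess
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

OUTDIR = Path(__file__).resolve().parent.parent / "data" / "external"
EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# accession -> species group (one representative accession per COI haplotype
# for the newly deposited sequences, plus the comparative GenBank set)
GROUPS = {
    # M. claustralis: new haplotypes COI 1-9 and 22, plus the Georgian record
    "PP947873": "CLA", "PP947875": "CLA", "PP947876": "CLA", "PP947879": "CLA",
    "PP947880": "CLA", "PP947881": "CLA", "PP947882": "CLA", "PP947883": "CLA",
    "PP947886": "CLA", "PP947917": "CLA", "KX507199": "CLA",
    # Corfu M. parumcincta: haplotypes COI 10-17
    "PP947890": "PAR-K", "PP947891": "PAR-K", "PP947895": "PAR-K",
    "PP947896": "PAR-K", "PP947897": "PAR-K", "PP947900": "PAR-K",
    "PP947901": "PAR-K", "PP947902": "PAR-K",
    # Italian M. parumcincta
    "MG208944": "PAR-I", "MG208947": "PAR-I", "MG208949": "PAR-I",
    "MG208950": "PAR-I", "MG208956": "PAR-I", "MG208959": "PAR-I",
    # M. cartusiana: new haplotypes COI 18-21, 23-25 plus GenBank records
    "PP947906": "CAR", "PP947907": "CAR", "PP947910": "CAR", "PP947914": "CAR",
    "PP947919": "CAR", "PP947920": "CAR", "PP947923": "CAR",
    "KX507189": "CAR", "KX507235": "CAR", "ON332653": "CAR", "ON332655": "CAR",
    # M. cantiana s.l. lineages
    "MG208905": "CAN-1", "MG208910": "CAN-1",
    "MG208925": "CAN-2", "MG208928": "CAN-2",
    "MG208938": "CAN-3",
    "MG208939": "CAN-4", "MG208940": "CAN-4",
    "MK066938": "CAN-5",
    "MK066943": "CAN-6", "MK066944": "CAN-6",
    # M. pantanellii
    "MT380015": "PAN",
    # Trochulus hispidus outgroup (kept for alignment, excluded from summaries)
    "KX507209": "OUT", "KY818415": "OUT", "MG585398": "OUT",
}


def fetch(accessions: list[str]) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(accessions), "rettype": "fasta",
         "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=120) as fh:
        return fh.read().decode()


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    accs = list(GROUPS)
    chunks = [accs[i:i + 20] for i in range(0, len(accs), 20)]
    raw = []
    for chunk in chunks:
        raw.append(fetch(chunk))
        time.sleep(0.4)  # NCBI rate limit
    unaligned = OUTDIR / "coi_table7_raw.fasta"
    # strip record descriptions down to the bare accession (drop version)
    lines = []
    for block in raw:
        for line in block.splitlines():
            if line.startswith(">"):
                acc = line[1:].split()[0].split(".")[0]
                lines.append(f">{acc}")
            elif line.strip():
                lines.append(line.strip())
    unaligned.write_text("\n".join(lines) + "\n")

    aligned = OUTDIR / "coi_table7.fasta"
    with aligned.open("w") as out:
        subprocess.run(
            ["mafft", "--auto", str(unaligned)], stdout=out, check=True
        )
    with (OUTDIR / "coi_table7_groups.tsv").open("w") as fh:
        fh.write("specimen_id\tpopulation\tspecies_group\n")
        for acc, grp in GROUPS.items():
            fh.write(f"{acc}\t{grp}\t{grp}\n")
    print(f"cached {len(accs)} aligned sequences under {OUTDIR}")


if __name__ == "__main__":
    sys.exit(main())
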