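"""Report emission: TSV/JSON artifacts mirroring the study-table layouts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lda_ratio import LDARatioResults
from .mra import RatioSpectrum, ShapePCAResults
from .sequences import ConcatenationLedger, HaplotypeTable

__all__ = [
    "lda_report_frame",
    "write_lda_report",
    "write_spectrum_json",
    "format_group_summary",
    "write_group_summary",
    "write_haplotype_table",
    "write_json",
    "write_manifest",
]


def _fmt_range(r, nd: int = 2) -> str:
    return f"{r[0]:.{nd}f}-{r[1]:.{nd}f}"


def lda_report_frame(results: LDARatioResults, nd: int = 2) -> pd.DataFrame:
    """Two-row frame in the published comparison-table layout.

    Columns: comparison, best_ratio, range_group1, range_group2,
    standard_distance, delta, key_suitable.  Ranges, D and delta are
    rounded to ``nd`` decimals.
    """
    comparison = f"{results.group_a}-{results.group_b}"
    rows = []
    for pair, d in (
        (results.ratio_best, results.D_best),
        (results.ratio_second, results.D_second),
    ):
        rr = results.ranges[pair]
        rows.append(
            {
                "comparison": comparison,
                "best_ratio": f"{pair[0]}/{pair[1]}",
                "range_group1": _fmt_range(rr[results.group_a], nd),
                "range_group2": _fmt_range(rr[results.group_b], nd),
                "standard_distance": round(d, nd),
                "delta": None if np.isnan(results.delta) else round(results.delta, nd),
                "key_suitable": results.key_suitable(pair),
            }
        )
    return pd.DataFrame(rows)


def write_lda_report(results: LDARatioResults, path) -> None:
    lda_report_frame(results).to_csv(path, sep="\t", index=False)


def write_spectrum_json(spectrum: RatioSpectrum, path) -> None:
    payload = {
        "axis_kind": spectrum.axis_kind,
        "n_boot": spectrum.n_boot,
        "level": spectrum.level,
        "n_skipped": spectrum.n_skipped,
        "coordinates": spectrum.to_records(),
    }
    write_json(payload, path)


def format_group_summary(summary: pd.DataFrame, nd: int = 1) -> pd.DataFrame:
    """Distance summary in ``comparison, range, mean`` layout, ``nd`` decimals."""
    return pd.DataFrame(
        {
            "comparison": summary["comparison"],
            "range": [
                f"{mn:.{nd}f}-{mx:.{nd}f}"
                for mn, mx in zip(summary["min"], summary["max"])
            ],
            "mean": summary["mean"].round(nd),
        }
    )


def write_group_summary(summary: pd.DataFrame, path, nd: int = 1) -> None:
    format_group_summary(summary, nd).to_csv(path, sep="\t", index=False)


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    frame = pd.DataFrame(
        {
            "specimen_id": list(table.assignments),
            "haplotype": [table.assignments[s] for s in table.assignments],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_json(payload, path) -> None:
    """Deterministic JSON: sorted keys, no timestamps."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_manifest(path, command: str, params: dict, inputs: list[str], seed=None) -> None:
    """Run manifest: everything needed to reproduce the report bundle."""
    params = {k: params[k] for k in sorted(params)}
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()
    write_json(
        {
            "tool": "ratiotax",
            "version": __version__,
            "command": command,
            "seed": seed,
            "inputs": sorted(str(i) for i in inputs),
            "parameters": params,
            "parameter_hash": digest,
        },
        path,
    )
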