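"""Dataset TSV reading/writing and result serialization.

The QTL table format is a tab-separated file with header
``locus_id<TAB>effect<TAB>direction``; effects are positive magnitudes and
directions one of ``+1, -1, +, -``.  Comment lines start with ``#``.  Datasets
are oriented on read, so a table written entirely with ``-`` directions comes
back as all ``+`` (relabelling which line is "high").  Floats in results are
serialized with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import pandas as pd

from .effects import QTLDataset, orient_dataset

__all__ = [
    "read_qtl_table",
    "write_qtl_table",
    "write_results",
    "RunManifest",
]

_COLUMNS = ("locus_id", "effect", "direction")
_DIRECTION_MAP = {"+1": 1, "-1": -1, "+": 1, "-": -1, "1": 1}


def read_qtl_table(path) -> QTLDataset:
    """Read and validate a QTL dataset TSV; returns an oriented dataset."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(table) == 0:
        raise ValueError(f"{path}: table contains no loci")
    effects, directions = [], []
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        try:
            eff = float(row.effect)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} row {row_number}: unparseable effect {row.effect!r}"
            ) from None
        if not eff > 0:
            raise ValueError(
                f"{path} row {row_number}: effect must be a positive magnitude, "
                f"got {row.effect!r}"
            )
        key = str(row.direction).strip()
        if key not in _DIRECTION_MAP:
            raise ValueError(
                f"{path} row {row_number}: unparseable direction {row.direction!r} "
                "(use +1, -1, + or -)"
            )
        effects.append(eff)
        directions.append(_DIRECTION_MAP[key])
    return orient_dataset(effects, directions, locus_ids=tuple(table["locus_id"]))


def write_qtl_table(dataset: QTLDataset, path, comment: str = None) -> None:
    """Write an oriented dataset as TSV; an optional comment line records provenance."""
    path = Path(path)
    ids = dataset.locus_ids or tuple(f"L{i + 1}" for i in range(dataset.n))
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("\t".join(_COLUMNS))
    for lid, eff, d in zip(ids, dataset.magnitudes, dataset.directions):
        lines.append(f"{lid}\t{float(eff)!r}\t{'+1' if d == 1 else '-1'}")
    path.write_text("\n".join(lines) + "\n")


def _format_float(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_results(results, path, format: str = None) -> None:
    """Serialize a results DataFrame (TSV) or mapping (JSON) with stable order.

    Floats are written with 6 significant digits; a round-trip read recovers
    the values to that precision.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format == "tsv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        if hasattr(results, "to_dict"):
            results = results.to_dict()
        payload = {k: _format_float(v) for k, v in dict(results).items()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'json'")


@dataclasses.dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    command: str
    config: dict
    seed: int
    version: str
    timestamp: str = None

    def __post_init__(self) -> None:
        if self.timestamp is None:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
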