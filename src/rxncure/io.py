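"""Reading and writing reaction files.

Supported inputs: plain text (one reaction SMILES per line, ids are
1-based line numbers) and CSV/TSV with configurable reaction and id column
names. Curated outputs carry ``id, original_reaction, curated_reaction,
status`` columns.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ReactionParseError
from .reactions import MappedReaction, parse_reaction

logger = logging.getLogger("rxncure")


def read_reaction_records(path, reaction_col: str = "reaction",
                          id_col: str = "id") -> list[tuple[str, str]]:
    """Read ``(record_id, reaction_smiles)`` pairs from a file.

    Format is inferred from the extension: .csv / .tsv are tabular (the id
    column is optional — row numbers are used when absent), anything else
    is plain text with one reaction per line.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv"):
        df = pd.read_csv(path, sep="," if suffix == ".csv" else "\t",
                         dtype=str)
        if reaction_col not in df.columns:
            raise ValueError(
                f"{path}: no column {reaction_col!r} (found {list(df.columns)})")
        if id_col in df.columns:
            ids = df[id_col].astype(str)
        else:
            ids = [str(i + 1) for i in range(len(df))]
        return list(zip(ids, df[reaction_col].astype(str)))
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if line and not line.startswith("#"):
                records.append((str(i), line))
    return records


def parse_records(records: list[tuple[str, str]]
                  ) -> tuple[list[MappedReaction], dict[str, str]]:
    """Parse records, dropping and logging unparsable ones.

    Returns the parsed reactions and a map record_id -> error message.
    """
    parsed: list[MappedReaction] = []
    errors: dict[str, str] = {}
    for rid, text in records:
        try:
            parsed.append(parse_reaction(text, rid))
        except ReactionParseError as exc:
            errors[rid] = str(exc)
            logger.warning("dropped record %s: %s", rid, exc)
    return parsed, errors


def write_curated_csv(path, rows: list[dict]) -> None:
    """Write curation results (id, original_reaction, curated_reaction,
    status) as CSV."""
    df = pd.DataFrame(rows, columns=["id", "original_reaction",
                                     "curated_reaction", "status"])
    df.to_csv(path, index=False)
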