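"""Plain-text I/O for modification sequences and result tables.

Sequences are stored one per line as strings over '0'/'1' (binary marks)
or '0'/'1'/'2' (two antagonistic marks).  Result tables are written as
TSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .markov import as_sequence

__all__ = ["read_sequences", "write_sequences", "write_table"]


def read_sequences(path, alphabet: int = 2) -> list[np.ndarray]:
    """Read one sequence per line; blank lines are skipped."""
    path = Path(path)
    sequences = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            sequences.append(as_sequence([int(c) for c in line], alphabet=alphabet))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sequences


def write_sequences(path, sequences) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write("".join(str(int(v)) for v in np.asarray(seq)) + "\n")


def write_table(path, table: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
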