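"""Reading edge-list files and writing ranked prediction tables.

Input files are two-column delimited text (TSV/CSV autodetected by
extension, otherwise any whitespace), one association per line; lines
starting with ``#`` are comments.  Duplicate pairs are dropped with a log
message.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AssociationTable, EntityIndex

logger = logging.getLogger(__name__)


def _delimiter_for(path: Path) -> str | None:
    # None => split on any whitespace
    return "," if path.suffix.lower() == ".csv" else None


def load_association_table(
    path: str | Path,
    left_role: str,
    right_role: str,
    skip_header: bool = False,
) -> AssociationTable:
    """Load one bipartite layer from a two-column delimited text file.

    Parameters
    ----------
    path
        File of ``left right`` name pairs, one per line.
    left_role, right_role
        Roles of the two columns, each one of {"miRNA", "disease", "lncRNA"}.
    skip_header
        Skip the first non-comment line (set when the file has a header row).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"association file not found: {path}")
    delim = _delimiter_for(path)

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    first_data_line = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if first_data_line and skip_header:
                first_data_line = False
                continue
            first_data_line = False
            fields = [f.strip() for f in (line.split(delim) if delim else line.split())]
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 delimited fields, "
                    f"got {len(fields)}: {line!r}"
                )
            pair = (fields[0], fields[1])
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)

    if not pairs:
        raise ValueError(f"{path}: no associations")
    if n_dup:
        logger.info("%s: removed %d duplicate pairs (%d kept)", path, n_dup, len(pairs))
    return AssociationTable(
        pairs=pairs, left_role=left_role, right_role=right_role, n_duplicates=n_dup
    )


def ranked_table(
    scores: np.ndarray,
    disease: str,
    mirnas: EntityIndex,
    diseases: EntityIndex,
    known_mask: np.ndarray,
) -> pd.DataFrame:
    """Rank all miRNAs for one disease by descending final score.

    Ties are broken by miRNA index order (stable sort), so output is fully
    deterministic.  Known associations are kept in the table and flagged in
    the ``known_before`` column; a disease with no known miRNA still yields a
    full ranking.
    """
    j = diseases.position(disease)
    col = np.asarray(scores)[:, j]
    order = np.argsort(-col, kind="stable")
    return pd.DataFrame(
        {
            "miRNA": [mirnas.names[i] for i in order],
            "rank": np.arange(1, len(order) + 1),
            "Rscore_final": col[order],
            "known_before": np.asarray(known_mask)[:, j][order].astype(int),
        }
    )


def write_ranked_list(
    scores: np.ndarray,
    disease: str,
    mirnas: EntityIndex,
    diseases: EntityIndex,
    known_mask: np.ndarray,
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-disease ranking as TSV and return it."""
    table = ranked_table(scores, disease, mirnas, diseases, known_mask)
    table.to_csv(path, sep="\t", index=False)
    return table


def write_matrix(mat: np.ndarray, row_names, col_names, path: str | Path) -> None:
    """Dump a named matrix as dense TSV (debugging aid)."""
    pd.DataFrame(np.asarray(mat), index=list(row_names), columns=list(col_names)).to_csv(
        path, sep="\t"
    )
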