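"""Tab-separated table contracts shared by all pipeline stages.

All tables are UTF-8 TSV with a header row; optional metadata lines are
``#``-prefixed above the header.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


class ContractError(ValueError):
    """A table is missing a required column for a pipeline stage."""


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, required: Sequence[str] = (),
               stage: str = "") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ContractError(
            f"stage '{stage}': file {path} is missing required "
            f"column(s) {missing}")
    return df


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
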