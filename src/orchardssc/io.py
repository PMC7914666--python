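"""CSV I/O helpers shared by the CLI and the pipeline.

Dialect: UTF-8, comma separated, "." decimal, mandatory header row.  Unicode
minus signs (U+2212), as produced by some spreadsheet exports, are normalised
to ASCII hyphens on read.  Report tables round % SSC columns to 2 decimals on
write; full precision is kept internally.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_csv", "write_csv"]


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8").replace("−", "-")
    from io import StringIO

    return pd.read_csv(StringIO(text), **kwargs)


def write_csv(
    df: pd.DataFrame, path: str | Path, round2: tuple[str, ...] = ()
) -> None:
    out = df.copy()
    for col in round2:
        if col in out.columns:
            out[col] = out[col].astype(float).round(2)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, encoding="utf-8")
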