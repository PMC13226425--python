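"""Shared delimited-text I/O.

All tables in this package are tab-separated UTF-8 with '#' comment lines and
'.' decimals.  Writers prepend a comment header recording the package version,
the command line (or calling context) and the seed, so every output file is
self-describing and reproducible.
"""

from __future__ import annotations

import io
import sys
from pathlib import Path

import pandas as pd


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    command: str | None = None,
    seed: int | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write *df* as TSV with a provenance comment header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# igdyn {__version__}\n")
        fh.write(f"# command: {command if command is not None else ' '.join(sys.argv)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path, line_comments_only: bool = False, **kwargs) -> pd.DataFrame:
    """Read a TSV written by this package (or any '#'-commented TSV).

    With ``line_comments_only`` a '#' is a comment only at the start of a
    line, so fields may contain '#' (pseudo-atom wildcards like HB#).
    """
    if line_comments_only:
        text = "\n".join(
            line for line in Path(path).read_text(encoding="utf-8").splitlines()
            if not line.lstrip().startswith("#")
        )
        return pd.read_csv(io.StringIO(text), sep="\t", **kwargs)
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
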