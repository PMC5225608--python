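"""Result-table writers: TSV with a version/config header, written atomically."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    *,
    config: Mapping | None = None,
) -> None:
    """Write records as TSV, atomically, with a provenance comment line."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# cetevol v{__version__}"
    if config is not None:
        header += f" config={config_hash(config)}"
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
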