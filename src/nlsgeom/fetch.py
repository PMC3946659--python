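"""One-time download of the surveyed PDB entries.

Network access is never required by the analysis itself: every stage runs
on local files or synthetic structures.  This helper exists solely to
populate a local cache with the crystal structures listed in the packaged
survey table so the accession-based conservation analysis can be re-run.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .positions import load_table1

__all__ = ["RCSB_URL", "fetch_pdb", "fetch_table1", "table1_ids"]

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def table1_ids(categories: list[str] | None = None) -> list[str]:
    records = load_table1()
    if categories is not None:
        records = [r for r in records if r.category in categories]
    return [r.pdb_id for r in records]


def fetch_pdb(pdb_id: str, dest_dir: str | Path, timeout: float = 30.0,
              overwrite: bool = False) -> Path:
    """Download one entry into ``dest_dir`` (skipped if already cached)."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id.upper()}.pdb"
    if dest.exists() and not overwrite:
        return dest
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest


def fetch_table1(dest_dir: str | Path,
                 categories: list[str] | None = None,
                 timeout: float = 30.0) -> dict[str, Path]:
    """Fetch every surveyed entry (optionally restricted by category)."""
    return {pdb_id: fetch_pdb(pdb_id, dest_dir, timeout=timeout)
            for pdb_id in table1_ids(categories)}
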