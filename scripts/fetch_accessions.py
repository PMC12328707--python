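#!/usr/bin/env python
"""Download the deposited crystal structures used by the accession-dependent
tests into data/accessions/ (requires network access to files.rcsb.org).

Usage:  python scripts/fetch_accessions.py [id ...]
"""

from __future__ import annotations

import gzip
import sys
import urllib.request
from pathlib import Path

# dehydrogenase depositions plus the halophilic comparison structures
DEFAULT_IDS = ["9ibe", "8qzb", "8qza", "5mh5", "5mh6", "5mha", "2b5w", "3oyz", "7q3x", "1doi"]

DEST = Path(__file__).resolve().parent.parent / "data" / "accessions"


def fetch(pdb_id: str) -> Path:
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif.gz"
    out = DEST / f"{pdb_id.lower()}.cif"
    if out.exists():
        print(f"{out} already present")
        return out
    DEST.mkdir(parents=True, exist_ok=True)
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        data = gzip.decompress(resp.read())
    out.write_bytes(data)
    print(f"wrote {out} ({len(data) // 1024} KiB)")
    return out


if __name__ == "__main__":
    ids = sys.argv[1:] or DEFAULT_IDS
    failures = []
    for pdb_id in ids:
        try:
            fetch(pdb_id)
        except Exception as exc:  # noqa: BLE001 - report and continue
            failures.append(pdb_id)
            print(f"FAILED {pdb_id}: {exc}", file=sys.stderr)
    sys.exit(1 if failures else 0)
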