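#!/usr/bin/env python
"""Download the public reference data the reference analyses consume.

Fetches the three UniProt sequences (ABCG2_HUMAN, ABCG5_HUMAN,
ABCG8_HUMAN) and the template heterodimer structure (PDB 5DO7) into
``src/sitescan/data/``.  Requires network access; everything else in the
package runs offline.  Files already present are kept unless --force.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

URLS = {
    "abcg2_human.fasta": "https://rest.uniprot.org/uniprotkb/Q9UNQ0.fasta",
    "abcg5_human.fasta": "https://rest.uniprot.org/uniprotkb/Q9H222.fasta",
    "abcg8_human.fasta": "https://rest.uniprot.org/uniprotkb/Q9H221.fasta",
    "5do7.pdb": "https://files.rcsb.org/download/5DO7.pdb",
}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--force", action="store_true", help="re-download existing files")
    parser.add_argument(
        "--dest",
        default=Path(__file__).resolve().parent.parent / "src" / "sitescan" / "data",
        type=Path,
    )
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for name, url in URLS.items():
        target = args.dest / name
        if target.exists() and not args.force:
            print(f"{name}: already present, skipping")
            continue
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                data = resp.read()
        except OSError as exc:
            print(f"{name}: FAILED ({exc})", file=sys.stderr)
            failures += 1
            continue
        target.write_bytes(data)
        print(f"{name}: {len(data)} bytes from {url}")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
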