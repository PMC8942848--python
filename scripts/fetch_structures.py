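#!/usr/bin/env python
"""Fetch the deposited coordinate files used by the printed-measurement
acceptance targets into data/structures/ (requires network access).

Usage: python scripts/fetch_structures.py [--dest data/structures]
"""

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["7qb9", "7qa8", "7qbc", "7qbi", "7ad3"]
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--dest",
        default=Path(__file__).resolve().parents[1] / "data" / "structures",
        type=Path,
    )
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for acc in ACCESSIONS:
        target = args.dest / f"{acc}.pdb"
        if target.exists():
            print(f"{acc}: already present")
            continue
        url = URL.format(acc.upper())
        try:
            urllib.request.urlretrieve(url, target)
            print(f"{acc}: fetched -> {target}")
        except Exception as exc:
            failures += 1
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
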