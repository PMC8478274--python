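"""Download the experimental multi-pressure structures (network required).

Fetches the X-ray depositions of hen egg-white lysozyme (4WLD, 4WLT,
4WLY, 4WM2: 0.001-6.0 kbar) and E. coli dihydrofolate reductase (5Z6F,
5Z6J, 5Z6K, 5Z6M: 0.001-8.0 kbar), plus the NMR lysozyme entries 1GXV
(30 bar) and 1GXX (2 kbar), into data/pdb/.  The experimental-structure
acceptance test and the full-scale reproduction scripts read them from
there.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ENTRIES = ["4WLD", "4WLT", "4WLY", "4WM2", "5Z6F", "5Z6J", "5Z6K", "5Z6M", "1GXV", "1GXX"]
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    out = Path(__file__).resolve().parent.parent / "data" / "pdb"
    out.mkdir(parents=True, exist_ok=True)
    failed = []
    for pdb_id in ENTRIES:
        dest = out / f"{pdb_id}.pdb"
        if dest.exists():
            print(f"{pdb_id}: already present")
            continue
        try:
            with urllib.request.urlopen(URL.format(pdb_id), timeout=60) as r:
                dest.write_bytes(r.read())
            print(f"{pdb_id}: fetched ({dest.stat().st_size // 1024} kB)")
        except Exception as exc:  # noqa: BLE001 - report and continue
            failed.append(pdb_id)
            print(f"{pdb_id}: FAILED ({exc})", file=sys.stderr)
    if failed:
        print(f"could not fetch: {', '.join(failed)}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
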