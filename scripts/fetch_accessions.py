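#!/usr/bin/env python
"""Download the study's GenBank records into data/accessions/.

Requires network access to NCBI E-utilities; the library itself never
fetches anything.  Run once to enable the accession-based acceptance
checks:

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import time
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "KX786285", "KY129954", "JF801955", "KX495488", "KP316404",
    "AY875213", "KJ815009", "KR024406", "KP749836", "KR349344",
    "KT827824", "KM000130", "JX844628",
]

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=gb&retmode=text&id={acc}"
)


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "accessions"
    out_dir.mkdir(parents=True, exist_ok=True)
    failures = []
    for acc in ACCESSIONS:
        dest = out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        try:
            with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as r:
                text = r.read().decode()
            if not text.startswith("LOCUS"):
                raise ValueError("response is not a GenBank flat file")
            dest.write_text(text)
            print(f"{acc}: {len(text)} bytes")
            time.sleep(0.4)  # NCBI rate limit
        except Exception as exc:
            failures.append(acc)
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
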