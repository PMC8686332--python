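#!/usr/bin/env python
"""Optionally download the Cobetia sp. MC34 PhaC2 protein (WP_213113863.1).

Network-dependent convenience script: fetches the accession from NCBI
efetch and writes ``data/WP_213113863.1.fasta`` so the full published
profile (105.4 kDa, pI 4.63 / 10.34, SYCIG box) can be reproduced with

    phakit profile-phac data/WP_213113863.1.fasta

Nothing in the library or the test suite requires this file.
"""

import sys
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSION = "WP_213113863.1"


def main() -> int:
    out = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).resolve().parent.parent / "data" / f"{ACCESSION}.fasta")
    query = urllib.parse.urlencode({
        "db": "protein", "id": ACCESSION, "rettype": "fasta",
        "retmode": "text"})
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        sys.stderr.write("unexpected response from NCBI efetch\n")
        return 1
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(text)
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
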