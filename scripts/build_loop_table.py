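"""Regenerate the shipped loop-entropy table by exact lattice enumeration.

Deterministic: rebuilding with the same caps is byte-identical.  Takes a
few minutes (the largest hairpin sizes dominate).

Usage:  python scripts/build_loop_table.py [out_path]
"""

import pathlib
import sys
import time

from rnamelt.entropy import build_table

out = pathlib.Path(
    sys.argv[1]
    if len(sys.argv) > 1
    else pathlib.Path(__file__).resolve().parents[1] / "src/rnamelt/data/loop_entropy.tsv"
)
t0 = time.time()
table = build_table()
out.parent.mkdir(parents=True, exist_ok=True)
out.write_text(table.to_tsv())
print(f"wrote {len(table.entries)} entries to {out} in {time.time() - t0:.1f}s")
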