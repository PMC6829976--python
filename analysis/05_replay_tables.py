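#!/usr/bin/env python
"""Replay the published-table analysis from the packaged fixtures.

Rebuilds per-subtype up/down sets from the packaged 20-gene regulation
table, reconstructs the regulation matrix, recomputes every published
summary count (overlap genes, up/down-in-any, per-subtype counts, the
13-gene resistance signature, its exclusivity partition, cell-death
flags, supplemental-gene overlap) and verifies each against the published
value.  Exits non-zero naming the failed check on any mismatch.
"""

import argparse
import sys
from pathlib import Path

from consig.pipeline import ReplayMismatchError, run_table_replay


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/replay"))
    args = ap.parse_args()

    try:
        report = run_table_replay(strict=True)
    except ReplayMismatchError as exc:
        print(f"replay mismatch: {exc}", file=sys.stderr)
        sys.exit(3)

    report.write(args.outdir)
    for key in sorted(report.counts):
        print(f"{key}: {report.counts[key]}")
    print(f"signature genes: {', '.join(report.signature.signature_genes)}")
    print("all published counts reproduced")


if __name__ == "__main__":
    main()
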