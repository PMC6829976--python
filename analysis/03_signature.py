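#!/usr/bin/env python
"""Cross the conserved set with the subtype DE sets and extract the
resistance signature.

Builds the gene x subtype regulation matrix restricted to the conserved
genes, prints the per-subtype summary counts, extracts the genes whose
regulation in the resistant subtypes (LAR, M) differs from every
sensitive subtype (BL1, BL2), and compares the result to the planted
truth from 01_simulate.py.
"""

import argparse
import json
from pathlib import Path

from consig.genesets import read_gmt
from consig.regulation import build_regulation_matrix, resistant_signature, summarize_counts


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--conserved", type=Path, default=Path("results/conserved/conserved.gmt"))
    ap.add_argument("--outdir", type=Path, default=Path("results/signature"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    conserved = read_gmt(args.conserved)[0]
    up = {gs.set_id.removesuffix("_up"): gs for gs in read_gmt(args.indir / "subtype_up.gmt")}
    down = {gs.set_id.removesuffix("_down"): gs for gs in read_gmt(args.indir / "subtype_down.gmt")}

    matrix = build_regulation_matrix(up, down, conserved)
    matrix.to_csv(args.outdir / "regulation_matrix.csv")
    summary = summarize_counts(matrix)
    sig = resistant_signature(matrix, ("LAR", "M"), ("BL1", "BL2"))
    (args.outdir / "signature.json").write_text(sig.to_json() + "\n")

    print(f"conserved genes with a DE call: {len(matrix.genes)}")
    print(f"up in any subtype: {summary.genes_up_in_any}; "
          f"down in any: {summary.genes_down_in_any}")
    for st in matrix.subtypes:
        print(f"  {st}: {summary.up[st]} up, {summary.down[st]} down")
    print(f"resistance signature: {len(sig.signature_genes)} genes")
    for key, genes in sig.exclusivity.items():
        print(f"  {key}: {len(genes)} ({', '.join(genes)})")

    truth = json.loads((args.indir / "truth.json").read_text())
    planted = set(truth["intended_signature"])
    found = set(sig.signature_genes)
    print(f"planted signature recovered: {len(found & planted)}/{len(planted)}")


if __name__ == "__main__":
    main()
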