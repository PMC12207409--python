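#!/usr/bin/env python
"""Aggregate loop analyses on the simulated depletion conditions.

Builds primary loops from adjacent convergent barrier pairs, recombines
their anchors into putative extended loops, and compares pileup enrichment
across conditions; stratifies barrier-region pairs by motif orientation
(convergent / tandem / divergent) under WAPL loss.

Findings: extended-loop enrichment rises when cohesin is stabilised, and
convergent pairs interact more strongly than divergent pairs, with tandem
pairs intermediate — the "illegal loop" signature.
"""

import os

import pandas as pd

import fountainscope as fs

HERE = os.path.dirname(__file__)
OUT = os.path.join(HERE, "..", "results")
SCRATCH = os.path.join(HERE, "..", "scratch", "sim")


def main() -> None:
    params = fs.preset_params("untreated", seed=3)
    bs = params.binsize
    barrier_bins = sorted(p for p, _o, _s in params.barriers)
    primary = pd.DataFrame(
        [("chrSim", b1 * bs, (b1 + 1) * bs, "chrSim", b2 * bs, (b2 + 1) * bs)
         for b1, b2 in zip(barrier_bins, barrier_bins[1:])],
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )
    extended = fs.make_extended_loops(primary, min_dist=6e5, max_dist=1.2e6)

    rows = []
    for name in ("untreated", "wapl_off", "wapl_ctcf_off"):
        cm = fs.load_matrix(os.path.join(SCRATCH, f"{name}.cool"), 10_000)
        for kind, loops in (("primary", primary), ("extended", extended)):
            pu = fs.aggregate_loop_pileup(cm, loops, pad_bp=5 * bs)
            rows.append({"condition": name, "loops": kind,
                         "n_used": pu.n_loops_used,
                         "enrichment": round(pu.enrichment, 2)})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "loop_pileups.tsv"), sep="\t", index=False)
    print(df.to_string(index=False))

    cm = fs.load_matrix(os.path.join(SCRATCH, "wapl_off.cool"), 10_000)
    regions = pd.DataFrame(
        [{"chrom": "chrSim", "start": p * bs, "end": (p + 1) * bs}
         for p, _o, _s in params.barriers]
    )
    motifs = pd.DataFrame(
        [{"chrom": "chrSim", "start": p * bs, "end": (p + 1) * bs, "strand": o}
         for p, o, _s in params.barriers]
    )
    classes = fs.pair_regions_by_orientation(regions, motifs, 15 * bs, 60 * bs)
    rows = []
    for cls, loops in classes.items():
        pu = fs.aggregate_loop_pileup(cm, loops, pad_bp=5 * bs)
        rows.append({"class": cls, "n_pairs": len(loops),
                     "enrichment": round(pu.enrichment, 2)})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "orientation_pileups.tsv"), sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
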