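#!/usr/bin/env python
"""Screen W primer windows against the Z gametologue.

Enforces the assay's specificity rule — every accepted W primer must
mismatch the aligned Z gametologue in at least two positions — and pairs
surviving forward/reverse windows into ~550 bp products.
"""

from pathlib import Path

from lowdetect.io import write_tsv
from lowdetect.primers import pairs_to_frame, screen_w_primers
from lowdetect.simulate import make_reference

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for design in ("booby", "frigatebird"):
        panel = make_reference(design, seed=1)
        w = panel.by_class("W")
        z = panel.by_class("Z")
        pairs = screen_w_primers(
            w.sequence, z.sequence, primer_len=20, min_mismatches=2,
            target_product=550, tolerance=50, locus=w.name,
        )
        df = pairs_to_frame(pairs)
        write_tsv(df, OUT / design / "primer_pairs.tsv")
        worst = df.mismatches_vs_Z.min() if len(df) else None
        print(
            f"{design}: {len(pairs)} primer pairs for {w.name} vs {z.name} "
            f"(min mismatches among accepted primers: {worst})"
        )


if __name__ == "__main__":
    main()
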