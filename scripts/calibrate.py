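#!/usr/bin/env python
"""Width-calibration scan for the free dimensions of the full model.

The baseline topology is fixed by its published scaling; the gated-fusion
neck width and the per-stage star expansion ratios are the free widths of
the redesigned model.  This scan prints the complexity ladder for a grid of
candidate settings so the shipped defaults (neck width 64, expansions
4/4/2/1 through the backbone and 4 in the neck) can be re-derived:

    python scripts/calibrate.py
"""

import argparse
import itertools

from edgebcs import ModelConfig, build_model, complexity_report


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--imgsz", type=int, default=640)
    ap.add_argument("--widths", type=int, nargs="+", default=[56, 64, 72])
    args = ap.parse_args()

    base = complexity_report(
        build_model(ModelConfig(variant="baseline", scale="n", nc=5)),
        args.imgsz)
    print(f"baseline        : {base.gflops:6.3f} GFLOPs  "
          f"{base.fp16_size_mb:4.1f} MB  {base.params:,} params")

    expansions = [(2, 2, 2, 2, 2), (3, 3, 3, 3, 3), (4, 4, 2, 1, 4)]
    for w, exp in itertools.product(args.widths, expansions):
        rep = complexity_report(
            build_model(ModelConfig(variant="full", scale="n", nc=5,
                                    neck_width=w, star_expansion=exp)),
            args.imgsz)
        print(f"full w={w:3d} e={exp}: {rep.gflops:6.3f} GFLOPs  "
              f"{rep.fp16_size_mb:4.1f} MB  {rep.params:,} params")


if __name__ == "__main__":
    main()
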