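#!/usr/bin/env python
"""Score the despeckling protocol on user-supplied grayscale images.

The standard gray-level test images (Lena, peppers, cameraman, ...) are not
distributed with this package.  If you have copies, point this script at
them to get the full noisy/filtered PSNR-SSIM table at several speckle
levels, side by side for the proposed method (per pass) and the
Gaussian/median baselines.

Usage:
    python scripts/external_images_benchmark.py lena.png peppers.png \
        --sigmas 0.1 0.3 0.5 --passes 3 --out table.csv
"""

from __future__ import annotations

import argparse
from pathlib import Path

from ultraspeckle import read_gray, run_benchmark


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("images", nargs="+", type=Path)
    parser.add_argument("--sigmas", nargs="+", type=float,
                        default=[0.1, 0.2, 0.3, 0.4, 0.5])
    parser.add_argument("--passes", type=int, default=3)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=None,
                        help="optional CSV output path")
    args = parser.parse_args()

    images = [(p.stem, read_gray(p)) for p in args.images]
    df = run_benchmark(images, args.sigmas,
                       ["identity", "gaussian", "median", "proposed"],
                       passes=args.passes, seed=args.seed)
    wide = df.pivot_table(index=["image", "sigma"],
                          columns=["method", "pass"],
                          values=["psnr_db", "ssim"])
    print(wide.round(3).to_string())
    if args.out:
        df.to_csv(args.out, index=False)
        print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
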