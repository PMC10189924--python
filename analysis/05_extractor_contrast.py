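#!/usr/bin/env python
"""Plain handcrafted extractor vs a site-cue oracle on rendered patches.

On the same rendered cohort (weak stain/noise site effect), features from a
descriptor that explicitly encodes each site's fingerprint make the site far
easier to decode than the plain descriptor — the synthetic analogue of a
feature extractor whose training has absorbed site-identifying signal.
"""

from pathlib import Path

import pandas as pd

from sitebias.studies import CONTRAST_ALPHA, run_extractor_contrast

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    con = run_extractor_contrast(SEED, n_repeats=5)
    pd.DataFrame([{"alpha": CONTRAST_ALPHA, **con}]).to_csv(
        RESULTS / "extractor_contrast.tsv", sep="\t", index=False
    )
    print(f"rendered cohort at alpha={CONTRAST_ALPHA}:")
    print(f"  plain baseline  patch accuracy {con['plain_patch_accuracy']:.3f} "
          f"(slide {con['plain_slide_accuracy']:.3f})")
    print(f"  site-cue oracle patch accuracy {con['aware_patch_accuracy']:.3f} "
          f"(slide {con['aware_slide_accuracy']:.3f})")
    print(f"  gain: {con['gain']:.3f} — a site-aware representation decodes the "
          "acquisition site far better than the plain descriptor on identical images")


if __name__ == "__main__":
    main()
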