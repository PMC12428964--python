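#!/usr/bin/env python
"""Convert the simulated peak areas into nmol/mg-protein concentrations.

Internal-standard ratio quantification with the study's IS assignment,
followed by the ceramide-anchor whitelist filter.  Writes
results/cohort/quant.csv and reports any QC-failed samples.
"""

import argparse
from pathlib import Path

from neurogg.io import read_peak_areas, read_protein, write_table
from neurogg.quantify import default_is_map, quantify, validate_anchors


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", default="results/cohort")
    args = ap.parse_args()

    base = Path(args.in_dir)
    areas = read_peak_areas(str(base / "peak_areas.csv"))
    protein = read_protein(str(base / "protein.csv"))

    quant, failures = quantify(areas, default_is_map(), protein)
    quant, warnings_ = validate_anchors(quant)
    write_table(quant, str(base / "quant.csv"))

    print(f"quantified {quant['sample_id'].nunique()} samples, "
          f"{len(quant)} species/anchor rows -> {base / 'quant.csv'}")
    for f in failures:
        print(f"QC fail: {f.sample_id} ({f.reason})")
    for w in warnings_:
        print(f"warning: {w}")


if __name__ == "__main__":
    main()
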