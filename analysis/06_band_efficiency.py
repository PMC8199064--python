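#!/usr/bin/env python
"""Band-efficiency comparison of published brain-HSI classifiers.

Normalizing each published overall accuracy by its camera's spectral band
count (OACC per band) makes systems with 25, 128 and 826 bands comparable
on accuracy contributed per band.  Writes results/band_efficiency.csv and
reports the snapshot camera's advantage ratio over the strongest
higher-band comparator.
"""

from pathlib import Path

import pandas as pd

import hsibrain as hb
from hsibrain.datasets import BAND_EFFICIENCY_REFERENCE
from hsibrain.labeling import round_half_up

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    rows = [{"approach": name, "oacc_percent": oacc_pct, "bands": bands,
             "oacc_per_band": hb.oacc_per_band(oacc_pct, bands)}
            for name, oacc_pct, bands in BAND_EFFICIENCY_REFERENCE]
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "band_efficiency.csv", index=False)
    print(df.to_string(index=False))

    snapshot_best = df[df.bands == 25].oacc_per_band.max()
    comparator_best = df[df.bands > 25].oacc_per_band.max()
    ratio = round_half_up(snapshot_best / comparator_best)
    print(f"\nbest 25-band result: {snapshot_best}% per band; best "
          f"higher-band comparator: {comparator_best}% per band; "
          f"advantage ratio {ratio}x")


if __name__ == "__main__":
    main()
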