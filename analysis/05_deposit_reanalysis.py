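#!/usr/bin/env python
"""Re-analysis of deposited experimental discharge times (opt-in).

The published dataset of motor-unit discharge times (figshare DOI
10.6084/m9.figshare.28324253) is not bundled here; download it manually
and point this script at the directory.  Force signals are not part of
the deposit, so force-dependent analyses (trial selection, component-force
correlation) are unavailable; everything else (KMO, parallel analysis,
PCA/FA variance shares, consistency, MI networks) runs from discharge
times alone.

Usage:
    python analysis/05_deposit_reanalysis.py <deposit_dir> [layout.yaml]

The layout file maps container variables to (participant, muscle, trial)
entries; see mupool.recordings_io.read_deposit for the schema.  A minimal
example layout for a single-participant file:

    fs_key: fsamp
    index_base: 1
    entries:
      - {participant: P01, muscle: TA, trial: 1, key: MUPulses_t1}
      - {participant: P01, muscle: TA, trial: 2, key: MUPulses_t2}
      - {participant: P01, muscle: TA, trial: 3, key: MUPulses_t3}
"""

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mupool import lowdim, munet, preprocess, recordings_io  # noqa: E402

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    if len(sys.argv) < 3:
        print(__doc__)
        sys.exit(1)
    deposit_dir, layout_path = Path(sys.argv[1]), Path(sys.argv[2])
    layout = yaml.safe_load(layout_path.read_text())
    for mat in sorted(deposit_dir.glob("*.mat")):
        cohort = recordings_io.read_deposit(mat, layout, allow_unmatched=True)
        for (participant, muscle), trials in cohort.groups().items():
            print(f"{mat.name} {participant}/{muscle}: "
                  f"{len(trials[0].trains)} matched units")
            for tr in trials:
                end = max(t.discharge_samples[-1] for t in tr.trains) / tr.fs
                spikes = preprocess.binarize(tr.trains, 0.0, end)
                Z = preprocess.detrend_standardize(
                    preprocess.smooth_rates(spikes)
                )
                cs = lowdim.extract_components(Z, "PCA")
                kmo = lowdim.kmo(Z).kmo_overall
                adj = munet.mi_matrix(Z)
                net = munet.build_network(adj, munet.percolation_threshold(adj))
                print(
                    f"  trial {tr.trial_index}: KMO {kmo:.2f}, "
                    f"PC1 {cs.variance_explained_pct[0]:.1f}%, "
                    f"PC2 {cs.variance_explained_pct[1]:.1f}%, "
                    f"density {net.density:.2f}"
                )


if __name__ == "__main__":
    main()
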