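#!/usr/bin/env python
"""Generate the synthetic study region and all point data.

Emulates the case-study conditions at desk scale: a 24x24 lattice of 0.01
degree cells partitioned into 115 contiguous municipalities with
demographic, financial and land-use covariates; OHCA counts drawn from the
zero-inflated Poisson + BYM generative model; 719 AEDs and 5000 candidate
buildings scattered over the region.  Writes the five pipeline input files
under results/data/.
"""

import argparse

from _common import DATA, DEFAULT_SEED

from aedplace.pipeline import write_synthetic_bundle
from aedplace.synthetic import SyntheticRegionConfig, generate_study_bundle, study_params


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()

    config = SyntheticRegionConfig(seed=args.seed)
    params = study_params()
    bundle = generate_study_bundle(config, params)
    paths = write_synthetic_bundle(bundle, DATA)

    n_cells = len(bundle.cells)
    zero_share = (bundle.cells["y"] == 0).mean()
    urban = bundle.municipalities["urban_rural"].eq("urban").mean()
    print(f"region: {config.lattice_rows}x{config.lattice_cols} cells "
          f"({n_cells}), {config.n_municipalities} municipalities "
          f"({urban:.0%} urban)")
    print(f"OHCA events: {len(bundle.events)} "
          f"({zero_share:.1%} of cells have zero events)")
    print(f"AEDs: {len(bundle.aeds)}, candidate buildings: {len(bundle.buildings)}")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
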