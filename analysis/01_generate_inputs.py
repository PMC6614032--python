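"""Generate the study's inputs: a stratified city sample, a land-sea mask,
and the synthetic-truth parameters, all written under results/inputs/.

The city table stands in for a globally representative sample of cities
over 15,000 population, stratified by GNI band, Bailey ecoregion domain,
and WHO region; the mask and truth parameters define the synthetic
climate whose injected warming the rest of the analysis must recover.
"""
import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS, study_config

import urbheat as uh
from urbheat import io as ncio
from urbheat.pipeline import build_truth

import numpy as np


def main():
    cfg = study_config()
    INPUTS.mkdir(parents=True, exist_ok=True)

    cities = uh.generate_city_table(cfg.n_cities, seed=np.random.SeedSequence([cfg.seed, 1]))
    cities.to_csv(INPUTS / "cities.csv", index=False)
    print(f"wrote {cfg.n_cities} cities; stratum counts:")
    for axis in ("ecoregion_domain", "who_region", "gni_stratum"):
        print(f"  {axis}: {cities[axis].value_counts().to_dict()}")

    target = cfg.target_grid()
    mask = uh.make_land_mask(
        target, cfg.mask_mode, seed=np.random.SeedSequence([cfg.seed, 2]),
        land_fraction=cfg.land_fraction,
    )
    ncio.write_land_mask(mask, INPUTS / "mask.nc")
    print(f"land mask on {target.n_lat}x{target.n_lon} grid, "
          f"land fraction {mask.land_fraction:.3f}")

    truth = build_truth(cfg)
    with open(INPUTS / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)
    cfg.to_yaml(INPUTS / "run.yaml")
    print(f"injected end-of-century warming scale: {truth.delta_2100} degC (equator)")
    print(f"inputs -> {INPUTS}")


if __name__ == "__main__":
    main()
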