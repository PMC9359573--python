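#!/usr/bin/env python
"""Generate the synthetic survey cohort used by the downstream steps.

Emulates the field study's conditions: 1377 specimens across three Culex
species with the published per-species genotype mixes, split over the
bayside/inland regions and four land-use classes, plus the dual-probe
qPCR plate readout with per-species ΔCT cluster structure.
Writes plate.csv and truth.csv under results/cohort/.
"""

from pathlib import Path

from culexkdr import io, synthetic

SEED = 2019  # collection year of the survey; fixed for reproducibility
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synthetic.default_cohort_spec(seed=SEED)
    specimens = synthetic.simulate_specimens(spec)
    plate = synthetic.simulate_plate(specimens, seed=SEED + 1)

    io.write_plate_csv(OUT / "plate.csv", plate)
    specimens.to_csv(OUT / "truth.csv", index=False)

    n_by_species = specimens["species"].value_counts()
    print(f"simulated {len(specimens)} specimens "
          f"({', '.join(f'{sp}: {n}' for sp, n in n_by_species.items())})")
    no_amp = plate[plate[["ct_fam", "ct_hex"]].isna().all(axis=1)]
    print(f"{len(no_amp)} specimens ({100 * len(no_amp) / len(plate):.1f}%) "
          f"failed to amplify either probe")
    print(f"wrote {OUT / 'plate.csv'} and {OUT / 'truth.csv'}")


if __name__ == "__main__":
    main()
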